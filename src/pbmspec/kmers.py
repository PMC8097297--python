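"""Rank-based 8-mer statistics for one PBM assay.

For each of the 32,896 canonical 8-mer classes (an 8-mer and its reverse
complement collapsed), probes containing the class form the foreground and
all other probes the background.  The E-score is a "halved" Wilcoxon/
Mann-Whitney statistic: rank every probe by intensity (descending), keep the
top half of foreground and the top half of background, and compare the two
truncated samples:

    E = U / (|fg'| * |bg'|) - 0.5,   U = #{(f, b) : f ranked above b},
                                         ties counting 1/2

so E lies in [-0.5, +0.5] and is invariant to any strictly monotone
transform of the intensities.  Z-scores standardize log median foreground
intensity across classes and serve as weights in motif construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _dna

__all__ = [
    "KmerClass", "KmerStatTable", "index_kmers", "compute_escore",
    "compute_kmer_table", "enriched_kmers", "N_CANONICAL_8MERS",
]

N_CANONICAL_8MERS = 32896


@dataclass(frozen=True)
class KmerClass:
    """A canonical 8-mer class (reverse-complement pair collapsed)."""

    canonical: str

    def __post_init__(self):
        canon = _dna.canonicalize(self.canonical.upper())
        if canon != self.canonical:
            object.__setattr__(self, "canonical", canon)

    @property
    def is_palindrome(self) -> bool:
        return _dna.is_palindrome(self.canonical)

    def __str__(self):
        return self.canonical


@dataclass
class KmerStatTable:
    """Per-class E/Z/median statistics for one assay.

    ``df`` is indexed by canonical 8-mer with columns E, Z,
    median_intensity, n_fg_probes.  Classes with fewer foreground probes
    than the minimum count are present but flagged missing (NaN E and Z),
    keeping matrices rectangular downstream.
    """

    assay_id: str
    design_id: str
    df: pd.DataFrame

    def __post_init__(self):
        required = {"E", "Z", "median_intensity", "n_fg_probes"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"k-mer table missing columns: {sorted(missing)}")
        e = self.df["E"].dropna()
        if ((e < -0.5 - 1e-12) | (e > 0.5 + 1e-12)).any():
            raise ValueError("E-scores outside [-0.5, 0.5]")

    def to_tsv(self, path):
        out = self.df.rename_axis("canonical_8mer")
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, assay_id: str = "", design_id: str = "") -> "KmerStatTable":
        df = pd.read_csv(path, sep="\t", index_col="canonical_8mer", na_values=["NA"],
                         float_precision="round_trip")
        return cls(assay_id, design_id, df)


def index_kmers(probes, k: int = 8) -> dict:
    """Map each canonical k-mer class to the set of probe ids containing it.

    A probe belongs to a class if the canonical k-mer or its reverse
    complement occurs anywhere in its variable region; multiple occurrences
    count once.
    """
    if k > probes.variable_len:
        raise ValueError(f"k={k} exceeds probe length {probes.variable_len}")
    probe_idx, class_idx = _dna.class_memberships(probes.sequences, k)
    strings = _dna.canonical_kmer_strings(k)
    out: dict[str, set] = {}
    for p, c in zip(probe_idx, class_idx):
        out.setdefault(strings[c], set()).add(probes.ids[p])
    return out


def _halved_sets(values: np.ndarray, ids: list, members: list):
    """Top-ceil(n/2) of ``members`` ranked by intensity descending, ties
    broken by probe-id order."""
    members = sorted(members, key=lambda i: (-values[i], ids[i]))
    return members[:math.ceil(len(members) / 2)]


def compute_escore(intensities, fg, bg) -> float:
    """E-score comparing foreground vs background probe sets.

    ``intensities`` is a mapping/Series probe_id -> intensity; ``fg`` and
    ``bg`` are disjoint probe-id collections.  Returns NaN when either set
    is empty.  This is the definitional implementation; the table builder
    uses an equivalent vectorized path.
    """
    fg, bg = list(fg), list(bg)
    if not fg or not bg:
        return math.nan
    if set(fg) & set(bg):
        raise ValueError("fg and bg must be disjoint")
    values = {pid: float(intensities[pid]) for pid in fg + bg}
    idx = {pid: i for i, pid in enumerate(values)}
    vals = np.array(list(values.values()))
    ids = list(values)
    fg_top = _halved_sets(vals, ids, [idx[p] for p in fg])
    bg_top = _halved_sets(vals, ids, [idx[p] for p in bg])
    fg_vals = vals[fg_top]
    bg_vals = np.sort(vals[bg_top])
    # f ranked above b  <=>  intensity(f) > intensity(b); equal -> 1/2
    lt = np.searchsorted(bg_vals, fg_vals, side="left")
    le = np.searchsorted(bg_vals, fg_vals, side="right")
    U = float(lt.sum()) + 0.5 * float((le - lt).sum())
    return U / (len(fg_top) * len(bg_top)) - 0.5


def _escore_all_classes_fast(values: np.ndarray, id_rank: np.ndarray,
                             mem_probe: np.ndarray, mem_class: np.ndarray,
                             n_classes: int):
    """Vectorized per-class E over all classes at once.

    Requires tie-free intensities: with distinct values, position order
    (sorted by intensity descending, probe id ascending) coincides with the
    rank order used by the definition and no half-ties arise.
    """
    n = values.size
    order = np.lexsort((id_rank, -values))
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)

    mem_pos = pos[mem_probe]
    srt = np.lexsort((mem_pos, mem_class))
    mc = mem_class[srt]
    mp = mem_pos[srt]
    sz = np.bincount(mc, minlength=n_classes)
    offsets = np.concatenate(([0], np.cumsum(sz)[:-1]))
    within = np.arange(mc.size, dtype=np.int64) - offsets[mc]

    nf2 = (sz + 1) // 2
    nb2 = (n - sz + 1) // 2
    sel = within < nf2[mc]
    # bg probes ranked above f = pos - within; those beyond nb2 fall outside bg'
    bg_above = np.minimum(mp[sel] - within[sel], nb2[mc[sel]])
    contrib = nb2[mc[sel]] - bg_above  # = #bg' ranked below f
    U = np.bincount(mc[sel], weights=contrib, minlength=n_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        E = U / (nf2 * nb2) - 0.5
    E[sz == 0] = np.nan
    E[sz == n] = np.nan  # empty background
    return E, sz


def compute_kmer_table(probes, intensities, min_fg: int = 10, k: int = 8) -> KmerStatTable:
    """Full per-class statistics table for one assay.

    Per class: E (background = all probes not in the foreground), median
    foreground intensity, foreground probe count, and Z = standardized log
    median (natural log, population sd, over non-missing classes).  Classes
    with fewer than ``min_fg`` foreground probes are flagged missing.
    """
    ids = list(probes.ids)
    values = intensities.values.reindex(ids)
    if values.isna().any():
        missing = values.index[values.isna()][:3].tolist()
        raise ValueError(f"intensities missing for probes {missing}...")
    vals = values.to_numpy(dtype=float)
    n = vals.size
    strings = _dna.canonical_kmer_strings(k)
    n_classes = len(strings)
    probe_idx, class_idx = _dna.class_memberships(probes.sequences, k)

    tie_free = np.unique(vals).size == n
    if tie_free:
        id_rank = np.empty(n, dtype=np.int64)
        id_rank[np.argsort(np.asarray(ids, dtype=object))] = np.arange(n)
        E, sz = _escore_all_classes_fast(vals, id_rank, probe_idx, class_idx, n_classes)
    else:
        # exact path honouring the tie-counts-1/2 rule
        sz = np.bincount(class_idx, minlength=n_classes)
        series = pd.Series(vals, index=ids)
        members: dict[int, list] = {}
        for p, c in zip(probe_idx, class_idx):
            members.setdefault(int(c), []).append(ids[p])
        all_ids = set(ids)
        E = np.full(n_classes, np.nan)
        for c, fg_ids in members.items():
            E[c] = compute_escore(series, fg_ids, all_ids - set(fg_ids))

    med = np.full(n_classes, np.nan)
    grouped = pd.Series(vals[probe_idx]).groupby(class_idx).median()
    med[grouped.index.to_numpy()] = grouped.to_numpy()

    present = sz >= max(min_fg, 1)
    E = np.where(present, E, np.nan)

    Z = np.full(n_classes, np.nan)
    ok = present & np.isfinite(med) & (med > 0)
    if ok.sum() >= 2:
        logm = np.log(med[ok])
        sd = logm.std()
        Z[ok] = (logm - logm.mean()) / sd if sd > 0 else 0.0
    elif ok.sum() == 1:
        Z[ok] = 0.0

    df = pd.DataFrame({"E": E, "Z": Z, "median_intensity": med,
                       "n_fg_probes": sz}, index=pd.Index(strings, name="canonical_8mer"))
    return KmerStatTable(intensities.assay_id, intensities.design_id or probes.design_id, df)


def enriched_kmers(table: KmerStatTable, threshold: float = 0.45) -> set:
    """Canonical 8-mer classes with non-missing E >= threshold."""
    e = table.df["E"]
    return set(e.index[e.notna() & (e >= threshold)])
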