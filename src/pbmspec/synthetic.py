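"""Synthetic universal protein-binding microarray data.

Universal PBM designs place every k-mer on the array, each embedded in
multiple distinct probe contexts, so that rank statistics per 8-mer class
have guaranteed support.  This module generates such probe sets (two
independent designs by convention, "ME" and "HK") and simulates fluorescence
for a planted sequence-specific binder:

    occupancy(probe)  = sum over all windows, both strands, of the binder's
                        probability-odds score (PWM odds vs uniform 0.25)
    E[intensity]      = background * (1 + affinity_scale * occupancy)
    observed          = E[intensity] * exp(Normal(0, noise_sigma**2))

The forward model is deliberately simple — additive occupancy, no
cooperativity or saturation, multiplicative log-normal noise — because the
downstream E-score statistic is rank-based and only needs a monotone
intensity/occupancy relation plus realistic noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _dna
from .motifs import Motif

__all__ = [
    "DesignSpec", "BinderModel", "ProbeSet", "IntensityTable",
    "generate_probe_set", "simulate_intensities", "CoverageError",
]

N_CLASSES_8 = 32896


class CoverageError(ValueError):
    """Raised when the requested 8-mer class coverage cannot be met."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one universal array design."""

    design_id: str
    n_probes: int
    variable_len: int = 35
    min_kmer_coverage: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.variable_len < 8:
            raise ValueError("variable_len must be >= 8")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.min_kmer_coverage < 0:
            raise ValueError("min_kmer_coverage must be >= 0")


@dataclass
class BinderModel:
    """A sequence-specific (or null) protein for the forward model.

    ``motif`` may be a :class:`~pbmspec.motifs.Motif` or an IUPAC consensus
    string (converted with zero pseudocount, so mismatching windows score 0).
    ``affinity_scale`` multiplies occupancy; 0 gives a null binder whose
    intensities are pure background noise.
    """

    motif: Motif | str
    affinity_scale: float
    background_level: float = 1000.0
    noise_sigma: float = 0.2

    def __post_init__(self):
        if isinstance(self.motif, str):
            self.motif = Motif.from_consensus(self.motif)
        if self.affinity_scale < 0:
            raise ValueError("affinity_scale must be >= 0")
        if self.background_level <= 0:
            raise ValueError("background_level must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def null(cls, background_level: float = 1000.0, noise_sigma: float = 0.2) -> "BinderModel":
        return cls(motif="A", affinity_scale=0.0,
                   background_level=background_level, noise_sigma=noise_sigma)

    @classmethod
    def planted(cls, consensus: str, fg_bg_ratio: float = 3.0,
                match_prob: float = 0.8, background_level: float = 1000.0,
                noise_sigma: float = 0.2) -> "BinderModel":
        """Sequence-specific binder for a consensus, with graded specificity.

        The consensus is softened into a PWM giving each preferred base
        probability ``match_prob`` (mismatches share the rest), i.e. a
        12-fold per-base discrimination at the default — typical of a
        strong TF.  Graded (rather than all-or-nothing) site odds make
        near-consensus 8-mers carry protein-intrinsic intermediate
        affinities, the structure cross-design concordance relies on.
        ``affinity_scale`` is set so one perfect site gives expected
        intensity ``fg_bg_ratio`` times background.
        """
        if not 0.25 < match_prob <= 1.0:
            raise ValueError("match_prob must lie in (0.25, 1]")
        base = Motif.from_consensus(consensus)
        soft = np.where(base.matrix > 0,
                        base.matrix * match_prob,
                        (1.0 - match_prob) / 3.0)
        soft = soft / soft.sum(axis=1, keepdims=True)
        motif = Motif(soft, name=consensus)
        single_site_odds = float(np.prod(motif.matrix.max(axis=1) / 0.25))
        return cls(motif=motif, affinity_scale=(fg_bg_ratio - 1.0) / single_site_odds,
                   background_level=background_level, noise_sigma=noise_sigma)


@dataclass
class ProbeSet:
    """Ordered probe sequences for one array design."""

    design_id: str
    ids: list = field(default_factory=list)
    sequences: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("probe ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("probe sequences must all have the same length")

    def __len__(self):
        return len(self.ids)

    @property
    def variable_len(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    # -- IO ---------------------------------------------------------------

    def to_fasta(self, path):
        with open(path, "w") as fh:
            for pid, seq in zip(self.ids, self.sequences):
                fh.write(f">{pid}\n{seq}\n")

    def to_tsv(self, path):
        pd.DataFrame({"probe_id": self.ids, "design_id": self.design_id,
                      "sequence": self.sequences}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProbeSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        design = df["design_id"].iloc[0]
        if (df["design_id"] != design).any():
            raise ValueError("probe TSV mixes design ids")
        return cls(design, list(df["probe_id"]), list(df["sequence"]))

    @classmethod
    def from_fasta(cls, path, design_id: str) -> "ProbeSet":
        from Bio import SeqIO
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(design_id, ids, seqs)


@dataclass
class IntensityTable:
    """Normalized fluorescence per probe for one assay (protein x design)."""

    assay_id: str
    design_id: str
    values: pd.Series  # index: probe_id

    def __post_init__(self):
        self.values = pd.Series(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("intensities must be nonnegative")

    def to_tsv(self, path):
        self.values.rename("intensity").rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, assay_id: str = "", design_id: str = "") -> "IntensityTable":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls(assay_id, design_id,
                   pd.Series(df["intensity"].to_numpy(), index=df["probe_id"]))


def _coverage_counts(sequences, k: int = 8) -> np.ndarray:
    """Number of probes containing each canonical k-mer class."""
    if not sequences:
        return np.zeros(_dna.n_canonical_classes(k), dtype=np.int64)
    _, cls = _dna.class_memberships(sequences, k)
    return np.bincount(cls, minlength=_dna.n_canonical_classes(k))


def _random_probe(rng: np.random.Generator, length: int) -> str:
    return _dna.decode(rng.integers(0, 4, size=length))


def generate_probe_set(spec: DesignSpec) -> ProbeSet:
    """Generate a universal-array probe set meeting an 8-mer coverage floor.

    Construction: ceil(min_kmer_coverage / 2) passes of a randomized order-8
    de Bruijn sequence, tiled into ``variable_len``-nt probes with step
    ``variable_len - 7`` so that every 8-mer occurrence lands in exactly one
    probe; then a coverage audit plants targeted probes for any class still
    short (reverse-complement palindromes gain only one probe per pass);
    remaining capacity is filled with random probes.  Deterministic given
    ``spec.seed``.
    """
    L, k = spec.variable_len, 8
    rng = np.random.default_rng(spec.seed)
    capacity = spec.n_probes * (L - k + 1)
    demand = N_CLASSES_8 * spec.min_kmer_coverage
    if capacity < demand:
        raise CoverageError(
            f"infeasible coverage: {spec.n_probes} probes x {L - k + 1} windows "
            f"= {capacity} < {N_CLASSES_8} classes x {spec.min_kmer_coverage} = {demand}")

    step = L - k + 1
    sequences: list[str] = []
    if spec.min_kmer_coverage > 0:
        passes = math.ceil(spec.min_kmer_coverage / 2)
        for _ in range(passes):
            db = _dna.random_debruijn_sequence(k, rng)
            for start in range(0, len(db) - k + 1, step):
                chunk = db[start:start + L]
                if len(chunk) < L:
                    chunk = chunk + _random_probe(rng, L - len(chunk))
                sequences.append(chunk)
                if len(sequences) > spec.n_probes:
                    raise CoverageError(
                        f"n_probes={spec.n_probes} too small for the de Bruijn "
                        f"tiling needed to reach coverage {spec.min_kmer_coverage}")
        canon, _ = _dna.canonical_codes(k)
        for _ in range(8):  # audit/top-up loop; converges in 1-2 rounds
            counts = _coverage_counts(sequences, k)
            deficit = spec.min_kmer_coverage - counts
            short = np.nonzero(deficit > 0)[0]
            if short.size == 0:
                break
            for ci in short:
                kmer = _dna.decode_kmer(int(canon[ci]), k)
                for _ in range(int(deficit[ci])):
                    if len(sequences) >= spec.n_probes:
                        raise CoverageError(
                            f"could not reach coverage {spec.min_kmer_coverage} "
                            f"within n_probes={spec.n_probes}")
                    probe = list(_random_probe(rng, L))
                    off = int(rng.integers(0, L - k + 1))
                    probe[off:off + k] = kmer
                    sequences.append("".join(probe))
        else:
            raise CoverageError("coverage audit did not converge")

    while len(sequences) < spec.n_probes:
        sequences.append(_random_probe(rng, L))

    width = len(str(spec.n_probes - 1))
    ids = [f"{spec.design_id}_{i:0{max(width, 5)}d}" for i in range(len(sequences))]
    return ProbeSet(spec.design_id, ids, sequences)


def probe_occupancy(probes: ProbeSet, motif: Motif) -> np.ndarray:
    """Per-probe occupancy: sum of PWM odds over all windows, both strands."""
    mat = _dna.encode_matrix(probes.sequences)
    n, L = mat.shape
    w = motif.width
    if w > L:
        raise ValueError("motif wider than probe variable region")
    occ = np.zeros(n)
    n_win = L - w + 1
    for m in (motif, motif.reverse_complement()):
        odds = m.matrix / 0.25
        scores = np.ones((n, n_win))
        for j in range(w):
            scores *= odds[j, mat[:, j:j + n_win]]
        occ += scores.sum(axis=1)
    return occ


def simulate_intensities(probes: ProbeSet, binder: BinderModel, seed: int,
                         assay_id: str | None = None) -> IntensityTable:
    """Simulate one PBM assay for a binder on a probe set (deterministic
    given ``seed``)."""
    if len(probes) == 0:
        raise ValueError("empty probe set")
    rng = np.random.default_rng(seed)
    occ = probe_occupancy(probes, binder.motif)
    expected = binder.background_level * (1.0 + binder.affinity_scale * occ)
    noise = np.exp(rng.normal(0.0, binder.noise_sigma, size=len(probes))) \
        if binder.noise_sigma > 0 else 1.0
    values = pd.Series(expected * noise, index=pd.Index(probes.ids, name="probe_id"))
    return IntensityTable(assay_id or f"assay_{probes.design_id}",
                          probes.design_id, values)


def write_sidecar(path, spec: DesignSpec | None = None, binder: BinderModel | None = None,
                  seed: int | None = None, extra: dict | None = None):
    """Echo generation parameters next to an artifact as JSON."""
    payload: dict = dict(extra or {})
    if spec is not None:
        payload["design"] = {"design_id": spec.design_id, "n_probes": spec.n_probes,
                             "variable_len": spec.variable_len,
                             "min_kmer_coverage": spec.min_kmer_coverage,
                             "seed": spec.seed}
    if binder is not None:
        payload["binder"] = {"consensus": binder.motif.consensus,
                             "width": binder.motif.width,
                             "affinity_scale": binder.affinity_scale,
                             "background_level": binder.background_level,
                             "noise_sigma": binder.noise_sigma}
    if seed is not None:
        payload["seed"] = seed
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
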