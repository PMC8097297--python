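"""Position weight matrices built from top-scoring 8-mers, and PWM scanning.

The construction mirrors the "top-N stack" style of PBM motif summarization:
the highest-E 8-mer seeds the alignment, each subsequent 8-mer is greedily
placed at the (offset, orientation) that best matches the running weighted
frequency profile, and base counts are accumulated with each 8-mer weighted
by its (floored) Z-score.  Scanning uses base-2 log-odds against a uniform
0.25 background.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from ._dna import BASES, IUPAC, revcomp

__all__ = ["Motif", "MotifMatch", "top10_align", "pwm_scan", "motif_similarity"]

_COL_TOL = 1e-9


@dataclass
class Motif:
    """A nucleotide position weight matrix.

    Attributes
    ----------
    matrix:
        (width, 4) array of per-position probabilities over A, C, G, T.
        Every row sums to 1 within 1e-9.
    name:
        Free-text identifier, used in MEME output.
    provenance:
        For motifs built from k-mer tables: list of
        ``(canonical_kmer, weight, offset, orientation)`` tuples describing
        how each 8-mer was placed.  Orientation is "+" or "-"; offsets are
        relative to the final (trimmed) motif, so each lies in
        [0, width - 8].
    pseudocount:
        Per-base pseudocount added to the weighted counts before
        normalization.
    """

    matrix: np.ndarray
    name: str = "motif"
    provenance: list = field(default_factory=list)
    pseudocount: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("motif matrix must be (width, 4)")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=_COL_TOL):
            raise ValueError("motif columns must each sum to 1")
        if (self.matrix < 0).any():
            raise ValueError("motif probabilities must be nonnegative")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_consensus(cls, consensus: str, pseudocount: float = 0.0,
                       name: str | None = None) -> "Motif":
        """Build a PWM from an IUPAC consensus string.

        Allowed bases at each position share probability equally; with a
        pseudocount p every cell becomes (q + p) / (1 + 4p).
        """
        consensus = consensus.upper()
        mat = np.zeros((len(consensus), 4))
        for i, letter in enumerate(consensus):
            try:
                allowed = IUPAC[letter]
            except KeyError:
                raise ValueError(f"not an IUPAC nucleotide code: {letter!r}")
            for b in allowed:
                mat[i, BASES.index(b)] = 1.0 / len(allowed)
        if pseudocount:
            mat = (mat + pseudocount) / (1.0 + 4.0 * pseudocount)
        return cls(mat, name=name or consensus, pseudocount=pseudocount)

    def reverse_complement(self) -> "Motif":
        return Motif(self.matrix[::-1, ::-1].copy(), name=self.name + "_rc",
                     provenance=list(self.provenance), pseudocount=self.pseudocount)

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / background)

    # -- IO ---------------------------------------------------------------

    def to_meme(self, nsites: int = 20) -> str:
        """Render in MEME minimal motif format."""
        buf = io.StringIO()
        buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        buf.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        buf.write(f"MOTIF {self.name}\n")
        buf.write(f"letter-probability matrix: alength= 4 w= {self.width} "
                  f"nsites= {nsites} E= 0\n")
        for row in self.matrix:
            buf.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_meme(cls, text: str) -> "Motif":
        lines = text.splitlines()
        name = "motif"
        rows = []
        in_matrix = False
        width = None
        for line in lines:
            s = line.strip()
            if s.startswith("MOTIF"):
                parts = s.split()
                if len(parts) > 1:
                    name = parts[1]
            elif s.startswith("letter-probability matrix"):
                in_matrix = True
                for tok_key, tok_val in zip(s.split(), s.split()[1:]):
                    if tok_key == "w=":
                        width = int(tok_val)
            elif in_matrix and s:
                vals = [float(x) for x in s.split()]
                if len(vals) == 4:
                    rows.append(vals)
                    if width is not None and len(rows) == width:
                        break
                else:
                    break
            elif in_matrix and not s and rows:
                break
        if not rows:
            raise ValueError("no letter-probability matrix found in MEME text")
        mat = np.array(rows)
        mat = mat / mat.sum(axis=1, keepdims=True)  # absorb rounding
        return cls(mat, name=name)

    def to_tsv(self) -> str:
        lines = ["pos\tA\tC\tG\tT"]
        for i, row in enumerate(self.matrix):
            lines.append(str(i) + "\t" + "\t".join(f"{p:.6f}" for p in row))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class MotifMatch:
    """One scored window from a PWM scan (0-based position, +/- strand)."""

    position: int
    strand: str
    score: float


def _score_kmer_against_profile(kmer: str, offset: int, counts: dict) -> float:
    """Sum over overlapping columns of the candidate base's relative
    frequency in the running profile (columns outside the profile score 0,
    so longer overlaps are favoured)."""
    score = 0.0
    for j, base in enumerate(kmer):
        col = offset + j
        if col in counts:
            total = counts[col].sum()
            if total > 0:
                score += counts[col][BASES.index(base)] / total
    return score


def top10_align(table, n: int = 10, pseudocount: float = 0.01,
                weight_floor: float = 0.5, name: str | None = None) -> Motif:
    """Build a motif by stacking the top-n 8-mer classes of a k-mer table.

    Classes are ranked by E (ties: higher Z, then lexicographic canonical
    k-mer).  The rank-1 8-mer seeds the profile at offset 0 on the forward
    strand; each subsequent 8-mer is placed at the offset in [-7, +7] and
    orientation maximizing its weighted identity to the running profile
    (ties: smaller |offset|, then forward strand, then leftmost).  Base
    counts are weighted by each class's Z floored at ``weight_floor``;
    a per-base pseudocount is added before normalizing columns.

    Parameters
    ----------
    table:
        A :class:`~pbmspec.kmers.KmerStatTable` (or any object with a ``df``
        DataFrame holding columns E and Z indexed by canonical 8-mer).
    """
    df = table.df if hasattr(table, "df") else table
    rows = df.dropna(subset=["E"])
    if rows.empty:
        raise ValueError("k-mer table has no non-missing E-scores")
    ranked = rows.sort_index().sort_values(["E", "Z"], ascending=[False, False],
                                           kind="mergesort").head(n)
    kmers = list(ranked.index)
    weights = np.maximum(np.nan_to_num(ranked["Z"].to_numpy(), nan=0.0), weight_floor)

    k = len(kmers[0])
    counts: dict[int, np.ndarray] = {}
    provenance = []

    def place(kmer, offset, weight):
        for j, base in enumerate(kmer):
            col = offset + j
            if col not in counts:
                counts[col] = np.zeros(4)
            counts[col][BASES.index(base)] += weight

    place(kmers[0], 0, float(weights[0]))
    provenance.append((kmers[0], float(weights[0]), 0, "+"))

    for kmer, weight in zip(kmers[1:], weights[1:]):
        candidates = []
        for orient, s in (("+", kmer), ("-", revcomp(kmer))):
            for off in range(-(k - 1), k):
                score = _score_kmer_against_profile(s, off, counts)
                candidates.append((-score, abs(off), orient == "-", off, s, orient))
        candidates.sort(key=lambda c: c[:4])
        _, _, _, off, s, orient = candidates[0]
        place(s, off, float(weight))
        provenance.append((kmer, float(weight), off, orient))

    cols = sorted(counts)
    # contiguity holds because every placement overlaps the seed's extent;
    # trim defensively to columns that received any weight
    cols = [c for c in cols if counts[c].sum() > 0]
    left = cols[0]
    mat = np.stack([counts[c] for c in cols]) + pseudocount
    mat = mat / mat.sum(axis=1, keepdims=True)
    provenance = [(km, w, off - left, orient) for km, w, off, orient in provenance]
    return Motif(mat, name=name or "top%d_alignZ" % n,
                 provenance=provenance, pseudocount=pseudocount)


def pwm_scan(motif: Motif, sequence: str, seq_id: str | None = None) -> list[MotifMatch]:
    """Score every window of a sequence on both strands, best first.

    Scores are base-2 log-odds against a uniform 0.25 background; a match on
    the minus strand at position p means the motif's reverse complement
    matches the forward sequence at p.  Sorting is by descending score, then
    leftmost position, then "+" before "-".
    """
    sequence = sequence.upper()
    w = motif.width
    if len(sequence) < w:
        raise ValueError(f"sequence length {len(sequence)} < motif width {w}")
    from ._dna import encode  # local import to avoid cycle at module load

    codes = encode(sequence)
    n_win = len(sequence) - w + 1
    matches = []
    for strand, m in (("+", motif), ("-", motif.reverse_complement())):
        lo = m.log_odds()
        scores = np.zeros(n_win)
        for j in range(w):
            scores += lo[j, codes[j:j + n_win]]
        for pos in range(n_win):
            matches.append(MotifMatch(pos, strand, float(scores[pos])))
    matches.sort(key=lambda m: (-m.score, m.position, m.strand == "-"))
    return matches


def _column_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 1.0 if np.allclose(x - x.mean(), y - y.mean()) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def motif_similarity(a: Motif, b: Motif, min_overlap: int = 4) -> float:
    """Best mean columnwise Pearson correlation over alignments of two PWMs.

    Maximized over all relative offsets and both orientations of ``b`` with
    at least ``min_overlap`` overlapping columns.  Returns NaN when no
    admissible overlap exists.  Result lies in [-1, 1]; a motif against
    itself or its reverse complement scores 1.
    """
    best = -np.inf
    found = False
    for bb in (b, b.reverse_complement()):
        wa, wb = a.width, bb.width
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a = max(0, off)
            hi_a = min(wa, off + wb)
            if hi_a - lo_a < min_overlap:
                continue
            found = True
            cols_a = a.matrix[lo_a:hi_a]
            cols_b = bb.matrix[lo_a - off:hi_a - off]
            corr = np.mean([_column_corr(ca, cb) for ca, cb in zip(cols_a, cols_b)])
            best = max(best, corr)
    if not found:
        return math.nan
    return float(min(1.0, max(-1.0, best)))
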