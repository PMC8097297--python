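"""Screening CGGBP candidates for the conserved residues that predict
successful DNA binding.

CGGBPs carry an N-terminal BED zinc finger (zf-BED) and a C-terminal Hermes
transposase DNA-binding domain.  Seven diagnostic residues recur in the
proteins that yielded sequence-specific PBM data: the two Cys and two His
that coordinate zinc in the zf-BED, a leucine two positions N-terminal to
the zf-BED, and two prolines widely conserved in the Hermes domain.  A
construct is predicted viable when at least five of the seven residues are
present and the N-terminal linker (tag fusion point to zf-BED start) is at
least 14 residues.

Key residue positions are supplied as alignment columns (the alignments
themselves are built upstream with standard aligners), so this module also
provides gap-fraction column trimming and expression-construct design
(domain plus 50 flanking residues, clipped at the protein ends).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "KEY_ROLES", "EXPECTED_RESIDUES", "KeyPositions", "DomainAnnotation",
    "ScreenResult", "ConstructDesign", "annotate_key_residues",
    "screen_construct", "trim_alignment", "design_construct",
    "construct_sequence",
]

KEY_ROLES = ("zf_bed_cys1", "zf_bed_cys2", "zf_bed_his1", "zf_bed_his2",
             "leu_minus2", "hermes_pro1", "hermes_pro2")
EXPECTED_RESIDUES = dict(zip(KEY_ROLES, "CCHHLPP"))

GAP_CHARS = "-."


@dataclass(frozen=True)
class KeyPositions:
    """0-based alignment columns of the seven diagnostic residues.

    ``zf_bed_start`` is the alignment column where the zf-BED begins, used
    to measure the linker; when absent the Cys1 column is used as a proxy.
    """

    columns: dict
    zf_bed_start: int | None = None

    def __post_init__(self):
        missing = set(KEY_ROLES) - set(self.columns)
        if missing:
            raise ValueError(f"missing key roles: {sorted(missing)}")
        vals = [self.columns[r] for r in KEY_ROLES]
        if len(set(vals)) != len(vals):
            raise ValueError("key positions must be distinct columns")
        if any(v < 0 for v in vals):
            raise ValueError("key positions must be nonnegative")

    @property
    def domain_start_column(self) -> int:
        if self.zf_bed_start is not None:
            return self.zf_bed_start
        return self.columns["zf_bed_cys1"]

    def to_tsv(self, path):
        rows = [{"column_index": self.columns[r],
                 "expected_residue": EXPECTED_RESIDUES[r], "role": r}
                for r in KEY_ROLES]
        if self.zf_bed_start is not None:
            rows.append({"column_index": self.zf_bed_start,
                         "expected_residue": "", "role": "zf_bed_start"})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "KeyPositions":
        df = pd.read_csv(path, sep="\t")
        cols, start = {}, None
        for _, row in df.iterrows():
            if row["role"] == "zf_bed_start":
                start = int(row["column_index"])
            else:
                cols[row["role"]] = int(row["column_index"])
        return cls(cols, start)


@dataclass
class DomainAnnotation:
    """Per-protein presence of the diagnostic residues and linker length."""

    protein_id: str
    alignment_row: str
    presence: dict = field(default_factory=dict)
    linker_len: int = 0

    @property
    def n_present(self) -> int:
        return sum(self.presence.values())


@dataclass(frozen=True)
class ScreenResult:
    protein_id: str
    passed: bool
    n_present: int
    linker_len: int
    reasons: tuple = ()


@dataclass(frozen=True)
class ConstructDesign:
    """1-based inclusive coordinates of an expression construct."""

    protein_id: str
    start: int
    end: int
    tag: str = "GST"

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError("require 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _load_alignment(alignment) -> MultipleSeqAlignment:
    if isinstance(alignment, MultipleSeqAlignment):
        return alignment
    if isinstance(alignment, (str, Path)):
        return AlignIO.read(str(alignment), "fasta")
    # iterable of (id, gapped string)
    return MultipleSeqAlignment(
        SeqRecord(Seq(row), id=pid) for pid, row in alignment)


def annotate_key_residues(alignment, key_positions: KeyPositions) -> list[DomainAnnotation]:
    """Flag the expected residue at each key column for every sequence.

    A gap (or any residue other than the expected one, case-insensitive) at
    a key column yields a False flag.  ``linker_len`` counts the non-gap
    residues strictly before the zf-BED start column — the N-terminal
    stretch between the tag fusion point and the domain.
    """
    aln = _load_alignment(alignment)
    width = aln.get_alignment_length()
    for role in KEY_ROLES:
        if key_positions.columns[role] >= width:
            raise ValueError(
                f"key column {key_positions.columns[role]} ({role}) outside "
                f"alignment of width {width}")
    start_col = key_positions.domain_start_column
    out = []
    for rec in aln:
        row = str(rec.seq).upper()
        if len(row) != width:
            raise ValueError(f"{rec.id}: row length {len(row)} != alignment width {width}")
        presence = {role: row[key_positions.columns[role]] == EXPECTED_RESIDUES[role]
                    for role in KEY_ROLES}
        linker = sum(1 for ch in row[:start_col] if ch not in GAP_CHARS)
        out.append(DomainAnnotation(rec.id, row, presence, linker))
    return out


def screen_construct(annotation: DomainAnnotation, min_residues: int = 5,
                     min_linker: int = 14) -> ScreenResult:
    """Predict construct viability: >= min_residues of the 7 diagnostic
    residues present AND linker >= min_linker residues."""
    reasons = []
    if annotation.n_present < min_residues:
        reasons.append(f"only {annotation.n_present}/7 conserved residues "
                       f"(need {min_residues})")
    if annotation.linker_len < min_linker:
        reasons.append(f"linker {annotation.linker_len} AA "
                       f"(need {min_linker})")
    return ScreenResult(annotation.protein_id, not reasons,
                        annotation.n_present, annotation.linker_len,
                        tuple(reasons))


def screen_report(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"protein_id": r.protein_id, "n_present": r.n_present,
          "linker_len": r.linker_len, "pass": r.passed,
          "reasons": "; ".join(r.reasons)} for r in results]
    ).set_index("protein_id")


def trim_alignment(alignment, max_gap_frac: float = 0.20):
    """Remove columns whose gap fraction strictly exceeds ``max_gap_frac``.

    Returns (trimmed MultipleSeqAlignment, kept original column indices) so
    coordinates can be lifted over.  Idempotent.
    """
    aln = _load_alignment(alignment)
    if len(aln) == 0:
        raise ValueError("empty alignment")
    n = len(aln)
    rows = [str(rec.seq) for rec in aln]
    kept = []
    for col in range(aln.get_alignment_length()):
        gaps = sum(1 for row in rows if row[col] in GAP_CHARS)
        if gaps / n <= max_gap_frac:
            kept.append(col)
    records = [SeqRecord(Seq("".join(row[c] for c in kept)), id=rec.id,
                         description=rec.description)
               for rec, row in zip(aln, rows)]
    return MultipleSeqAlignment(records), kept


def design_construct(protein, domain_start: int, domain_end: int,
                     flank: int = 50, tag: str = "GST",
                     protein_id: str | None = None) -> ConstructDesign:
    """Expression construct: domain plus ``flank`` residues on both sides,
    clipped at the protein ends.  Coordinates are 1-based inclusive on the
    unaligned protein; ``protein`` may be a sequence string or a length."""
    if isinstance(protein, int):
        length, pid = protein, protein_id or "protein"
    else:
        length = len(str(protein))
        pid = protein_id or getattr(protein, "id", None) or "protein"
    if not (1 <= domain_start <= domain_end <= length):
        raise ValueError(
            f"domain [{domain_start}, {domain_end}] outside protein of length {length}")
    return ConstructDesign(pid, max(1, domain_start - flank),
                           min(length, domain_end + flank), tag)


def construct_sequence(protein_seq: str, design: ConstructDesign) -> str:
    if design.end > len(protein_seq):
        raise ValueError("construct extends past protein end")
    return protein_seq[design.start - 1:design.end]
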