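"""Screen candidate CGGBP proteins for the residues that predict success.

Builds a toy alignment of four candidates with known substitutions, trims
high-gap columns, flags the seven diagnostic residues (zf-BED 2xCys/2xHis,
Leu at -2, Hermes 2xPro), and applies the 5-of-7-residues / 14-AA-linker
construct screen.  Construct coordinates add 50 flanking residues around
the domain, clipped at the protein ends.
"""

from pbmspec import (KeyPositions, annotate_key_residues, design_construct,
                     screen_construct, trim_alignment)
from pbmspec.domains import screen_report

keys = KeyPositions(
    columns={"leu_minus2": 18, "zf_bed_cys1": 21, "zf_bed_cys2": 24,
             "zf_bed_his1": 28, "zf_bed_his2": 31,
             "hermes_pro1": 36, "hermes_pro2": 39},
    zf_bed_start=20)

body = "XCXXCXXXHXXHXXXXPXXPXXXXX"          # key residues at known columns


def candidate(linker, broken=()):
    row = ["-"] * 20
    for i in range(linker):
        row[20 - 1 - i] = "A"
    row += list(body)
    row[18] = "L"
    for role in broken:
        row[keys.columns[role]] = "G"
    return "".join(row)


alignment = [
    ("intact_long_linker", candidate(18)),
    ("intact_short_linker", candidate(9)),
    ("two_substitutions", candidate(20, broken=("zf_bed_his2", "hermes_pro1"))),
    ("three_substitutions", candidate(30, broken=("zf_bed_cys1", "zf_bed_his1",
                                                  "hermes_pro2"))),
]

trimmed, kept = trim_alignment(alignment, max_gap_frac=0.20)
print(f"alignment: {len(alignment[0][1])} columns, {len(kept)} kept after "
      f"trimming columns with >20% gaps\n")

annotations = annotate_key_residues(alignment, keys)
results = [screen_construct(a, min_residues=5, min_linker=14)
           for a in annotations]
print(screen_report(results).to_string(), "\n")

construct = design_construct(300, domain_start=100, domain_end=200, flank=50,
                             protein_id="intact_long_linker")
print(f"expression construct for a 300-AA protein with domain 100-200: "
      f"residues {construct.start}-{construct.end} "
      f"({construct.length} AA, N-terminal {construct.tag} tag)")
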