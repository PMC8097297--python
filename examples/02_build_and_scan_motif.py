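"""Build a motif from the top-scoring 8-mers and scan a sequence with it.

Stacks the ten best 8-mer classes of an assay into a position weight
matrix (Z-weighted greedy alignment), then scans a transposon-like
sequence with a planted site.  The best match should land on the planted
position with a strongly positive base-2 log-odds score.
"""

import numpy as np

from pbmspec import (BinderModel, DesignSpec, Motif, compute_kmer_table,
                     generate_probe_set, motif_similarity, pwm_scan,
                     simulate_intensities, top10_align)

probes = generate_probe_set(DesignSpec("ME", 8000, min_kmer_coverage=2, seed=1))
binder = BinderModel.planted("CGGCGG")
table = compute_kmer_table(probes, simulate_intensities(probes, binder, seed=7),
                           min_fg=2)

motif = top10_align(table, n=10, name="recovered")
planted = Motif.from_consensus("CGGCGG", pseudocount=0.01)
print(f"recovered motif: width {motif.width}, consensus {motif.consensus}")
print(f"similarity to planted CGGCGG PWM: "
      f"{motif_similarity(motif, planted):.3f} (1.0 = identical columns)\n")

rng = np.random.default_rng(5)
subterminal = list(rng.choice(list("ACGT"), size=200))
site = motif.consensus
subterminal[120:120 + len(site)] = list(site)
best = pwm_scan(motif, "".join(subterminal))[0]
print(f"best match in a 200-nt sequence with the consensus planted at 120:")
print(f"  position {best.position}, strand {best.strand}, "
      f"log2-odds score {best.score:.2f}")
print("\nMEME output:\n")
print(motif.to_meme())
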