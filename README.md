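# pbmspec

Analysis of protein-binding microarray (PBM) data for sequence-specific
DNA-binding proteins, built around the zf-BED + Hermes (CGGBP-type)
domain family: 8-mer E-score statistics on universal array designs, motif
construction from top-scoring 8-mers, cross-design specificity clustering
and concordance calling, PWM scanning of candidate target sequences, and
a conserved-residue screen for expression constructs.  A first-class
synthetic-data module generates universal arrays with planted binders so
the whole pipeline can be exercised and validated end to end.

## Who this is for

Researchers characterizing the DNA-binding specificity of uncharacterized
proteins (e.g. transposase-derived candidate transcription factors) with
universal PBMs, and anyone who needs a tested, reproducible reference
implementation of the 8-mer E-score / top-k-mer-motif workflow.

## The statistics

For each of the 32,896 canonical 8-mer classes (8-mer and reverse
complement collapsed), probes containing the class are compared with all
other probes by a truncated Wilcoxon–Mann–Whitney statistic, the
**E-score**:

    E = U / (|fg'| |bg'|) − 0.5 ∈ [−0.5, +0.5]

where fg′ and bg′ are the top halves of foreground and background by
intensity rank and U counts foreground-above-background pairs (ties ½).
E is invariant to any monotone transform of the intensities.  Motifs are
built by stacking the ten best 8-mers, Z-weighted (Z = standardized log
median foreground intensity); heatmaps use scaled E-scores
s(E) = max(0, 10^(10E) − 3) min–max normalized to [0, 100]; an assay
succeeds when a protein's two independent array designs correlate better
with each other than with any other protein's assay.  Details and all
defaults: `docs/methods.md`.

## Worked example

`examples/01_simulate_and_escore.py` simulates one assay on a 12,000-probe
universal design with a planted CGGCGG binder (single perfect site = 3×
background intensity, log-normal noise σ = 0.2) and scores all 8-mer
classes:

```
12000 probes, 32896 scored 8-mer classes
...
top 8-mer classes (E-score, Z, median intensity):
                   E      Z  median_intensity  n_fg_probes
canonical_8mer
CCGCCGCC       0.500 12.340          4712.470            6
CGCCGCCG       0.499 11.345          4183.778            8
CCGCCGGC       0.499 10.470          3768.281            8
```

Every top class contains the planted consensus (CCGCCG... rows are the
reverse-complement canonical forms of CGGCGG-containing 8-mers), with E
at the +0.5 ceiling: probes carrying the site occupy the top intensity
ranks outright.  `examples/02_build_and_scan_motif.py` stacks the top ten
classes into a PWM and recovers the planted motif:

```
recovered motif: width 13, consensus AGCCCGCCGCCGG
similarity to planted CGGCGG PWM: 0.998 (1.0 = identical columns)
best match in a 200-nt sequence with the consensus planted at 120:
  position 120, strand +, log2-odds score 23.75
```

`examples/03_specificity_and_concordance.py` runs a three-protein panel
(CGGCGG binder, GCGCGC binder, null control) on both designs and calls
success per protein:

```
            r_self  r_best_other best_other_assay  n_shared_enriched  success
protein_id
CGGBP_A      0.217         0.103        NULL_C:ME                 66     True
CGGBP_B      0.208        -0.001        NULL_C:HK                104     True
NULL_C         NaN         0.103       CGGBP_A:ME                  0    False
```

Both planted binders' ME/HK profiles agree with each other better than
with anything else; the null control has no enriched 8-mers shared
between designs and fails.  The remaining examples cover the domain
screen (`04`) and the full checksummed pipeline (`05`).  A thin CLI
(`pbmspec simulate|escore|motif|scan|matrix|concordance|screen|run`)
wraps the same functions for shell use.

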