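# Methods

`pbmspec` implements the analysis used to characterize sequence-specific
DNA binding of CGGBP-type proteins (zf-BED + Hermes transposase-derived
domains) on universal protein-binding microarrays (PBMs), together with a
synthetic-data generator that reproduces the statistical structure the
analysis assumes.  This note records the model, the defaults and why they
are what they are, and the design choices made where the published
procedure leaves details open.

## The E-score statistic

Universal PBM designs place every DNA k-mer on the array, each embedded in
many distinct probe contexts.  For each of the 32,896 canonical 8-mer
classes (an 8-mer and its reverse complement collapsed; 256 of the 4^8
8-mers are reverse-complement palindromes), the probes whose 35-nt variable
region contains the class form the foreground and all remaining probes the
background.  The E-score is a truncated ("halved") Wilcoxon–Mann–Whitney
rank statistic:

1. rank all probes by intensity, descending (average ranks for ties; ties
   broken by lexicographic probe id when selecting halves);
2. keep the top ⌈n/2⌉ of foreground (fg′) and of background (bg′);
3. E = U / (|fg′|·|bg′|) − 0.5, where U counts (f, b) pairs with f ranked
   above b, ties contributing ½.

E lies in [−0.5, +0.5] and is exactly invariant to any strictly monotone
transform of the intensities, which is why no normalization model is
needed downstream of per-array normalization.  The `compute_escore`
function is the literal definition; `compute_kmer_table` uses an
algebraically equivalent vectorized path (valid when intensities are
tie-free, verified by test against the definition and against a
brute-force pair-enumeration oracle) and falls back to the exact
definition when ties are present.  Truncation behaviour for odd-sized
sets uses the ceiling, so singleton foregrounds remain usable.

Per class the table also records the median foreground intensity, the
foreground probe count, and Z — the natural-log median intensity
standardized (population SD) across all classes passing the support
filter.  Classes with fewer than `min_fg` foreground probes (default 10)
are reported as missing rather than dropped, so cross-assay matrices stay
rectangular.  Only contiguous 8-mers are scored; gapped 8-mer patterns
present on some commercial designs are out of scope and documented as
such.

## Synthetic universal arrays

`generate_probe_set` builds a design in which every canonical 8-mer class
is guaranteed to appear on at least `min_kmer_coverage` probes (default
16, matching the multi-spot support real universal arrays provide).
Construction: ⌈coverage/2⌉ passes of a randomized order-8 de Bruijn
sequence — each pass contains every 8-mer exactly once and is tiled into
35-nt probes with step 28, so every 8-mer occurrence lands in exactly one
probe — followed by a coverage audit that plants targeted probes for any
class still short (palindromic classes gain only one probe per pass), and
random filler up to `n_probes`.  Randomized Eulerian circuits make
different designs ("ME", "HK") embed every 8-mer in unrelated 35-mer
contexts, which is the property the cross-design concordance analysis
exploits.  Requests that cannot be satisfied (window capacity below
class-count × coverage, or a tiling that cannot fit in `n_probes`) raise
`CoverageError` rather than silently under-covering.

The forward model for a binder is deliberately minimal:

    occupancy(probe) = Σ windows, both strands  Π_j p(base_j)/0.25
    E[intensity]     = background · (1 + affinity_scale · occupancy)
    observed         = E[intensity] · exp(N(0, noise_sigma²))

Occupancy is additive over windows — no cooperativity, no saturation —
because the downstream statistic is rank-based and needs only a monotone
intensity–occupancy relation; noise is multiplicative log-normal, the
usual convention for fluorescence data.  `BinderModel.planted` softens a
consensus into a PWM with per-position match probability 0.8 (12-fold
per-base discrimination, typical of a strong transcription factor), so
near-consensus 8-mers carry *protein-intrinsic* intermediate affinities.
This matters: with an all-or-nothing consensus, the graded variation among
enriched 8-mers would be design-specific context noise and the two array
designs would not correlate.  `affinity_scale` defaults to
(ratio − 1)/single-site-odds with ratio 3, i.e. one perfect site triples
the expected intensity over background; noise_sigma defaults to 0.2.
The default planted consensus for end-to-end fixtures is CGGCGG, the
canonical CGGBP1 preference; the second panel binder uses GCGCGC and the
third is a null (affinity 0) control.

What the generator does **not** emulate: real probe catalogs (Agilent ME/
HK), spatial array artifacts, scanner saturation, position-on-probe
effects, or raw-image quantification — intensities are assumed already
normalized.  Passing tests therefore demonstrate correctness of the
statistics and the recoverability of planted signal under realistic noise,
not robustness to array-level artifacts.

## Motif construction (top-10 Z-weighted stacking)

`top10_align` summarizes an assay by stacking its top 10 8-mer classes
(ranked by E; ties by higher Z, then lexicographic canonical 8-mer) into a
position weight matrix.  The rank-1 8-mer seeds the profile; each
subsequent 8-mer is placed greedily at the offset in [−7, +7] and
orientation that maximizes the summed relative frequency of its bases in
the running profile (ties: smaller |offset|, then forward strand, then
leftmost).  Base counts are weighted by the class Z floored at 0.5 — the
floor keeps degenerate tables from contributing zero or negative weight —
and a 0.01 pseudocount per base is added before column normalization.
Summed (not averaged) overlap identity is used so that a 7-base perfect
overlap beats a 1-base one.  The exact tie-breaking and trimming rules of
the published tool are not specified anywhere we could consult, so the
rules above are documented substitutes; every placement overlaps the seed,
so the covered columns are contiguous and trimming reduces to the covered
span.  Provenance (8-mer, weight, offset, orientation) is retained on the
motif object and in MEME output order.

Scanning (`pwm_scan`) scores every window on both strands with base-2
log-odds against a uniform 0.25 background, sorted best-first (ties:
leftmost, then + strand).  Background estimation from scanned sequence is
deliberately out of scope.  Motif similarity is the maximum over relative
offsets and orientations of the mean columnwise Pearson correlation with
at least 4 overlapping columns; columns with zero variance compare equal
(1.0) if identical after centering, else 0.

## Specificity matrix, clustering, concordance

The cross-assay matrix collects every 8-mer class with E ≥ 0.45 in at
least one assay.  Cells are transformed s(E) = max(0, 10^(10·E) − 3) and
min–max normalized over the whole matrix to [0, 100].  The transform is an
exponential emphasis of the high-E regime; the printed formula it derives
from is typographically ambiguous (exponent vs product), and the
exponential reading is the only one with a sensible positive dynamic
range — this is the package's documented choice.  Min–max is matrix-wide,
not per row, so relative enrichment across assays is preserved; a
constant matrix maps to 0.

Displayed dendrograms use complete-linkage hierarchical clustering on
Pearson distance (1 − r) between scaled profiles, computed
pairwise-complete; pairs with fewer than 20 shared columns (assay rows;
2 for 8-mer columns, where assays are few) are reported missing and
enter linkage at the maximal distance 2.  Cell grouping uses
average-linkage on (NaN-aware) Euclidean distances, the metric being an
explicit assumption since none is stated.  Leaf order is deterministic
for a fixed input order.  Pearson distance is not invariant under the
nonlinear scaling, so merge orders of raw and scaled matrices can differ
in principle; reproducibility (bit-identical trees for identical input)
is the property tested.

Concordance: for each protein assayed on both designs, r_self is the
Pearson correlation between its two E-profiles over the union of classes
enriched in either design; r_best_other is the maximum correlation
between any of its assays and any assay of a different protein, each pair
compared over the union of that pair's enriched classes.  An experiment is
called successful when r_self is finite, exceeds r_best_other, and at
least one class is enriched on both designs ("related high-scoring 8-mers
shared between designs").  Null binders enrich nothing, so their union is
empty, r_self is missing, and the call fails — by construction, not by
threshold tuning.

## Domain screen

Seven diagnostic residues are screened: the two Cys and two His that
coordinate zinc in the zf-BED, a leucine two positions N-terminal to the
zf-BED, and two prolines conserved in the Hermes domain.  Their alignment
columns are supplied as an annotation table rather than inferred by HMM,
since the reference annotation is not programmatically available;
coordinates are 0-based alignment columns in the annotation file and
1-based inclusive protein coordinates everywhere in construct space.  The
linker is the count of non-gap residues strictly before the zf-BED start
column — the N-terminal stretch between the expression-tag fusion point
and the domain; when the start column is not annotated the Cys1 column is
used as a proxy (documented approximation).  A construct passes when at
least 5 of 7 residues are present and the linker is ≥ 14 AA; the screen is
monotone in both arguments.  Alignment trimming removes columns with gap
fraction strictly greater than 20% and reports the kept-column map for
coordinate lift-over; construct design spans the domain plus 50 flanking
residues clipped at the protein ends.

## Pipeline, determinism, problem sizes

All randomness derives from one master seed through SHA-256-based child
seeds (always < 2³¹), so pipeline reruns are bit-identical; artifacts are
checksummed in a manifest and reruns into the same directory reuse stage
outputs whose checksums still match.  Floating-point TSVs are written at
17 significant digits and parsed with round-trip precision so a resumed
run equals a fresh one exactly.

Default panel conditions, used by the acceptance checks and
`scripts/acceptance.py`: two designs × 45,000 probes (coverage floor 16),
three binders (CGGCGG, GCGCGC, null), noise sigma 0.2, single-site ratio
3, min_fg 10, threshold E ≥ 0.45, 20 replicate seeds.  Examples use
8,000–24,000-probe arrays with proportionally reduced coverage floors and
min_fg — array size changes support per class, not the analysis.

## Known limitations

- Contiguous 8-mers only; no gapped patterns, no 10-mer statistics.
- The Z-score definition (standardized log median foreground intensity)
  is the conventional one; alternative definitions would change motif
  weighting but not E-based calls.
- Greedy sequential stacking is not an exhaustive multiple alignment; with
  adversarial 8-mer sets it can lock in a suboptimal seed placement.
- Pearson on pairwise-complete cells can be computed over different column
  subsets for different pairs; with < 20 shared columns the distance is
  reported missing rather than estimated.
- The linker measurement ignores any vector-encoded residues between tag
  and insert, which are not represented in the alignment.
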