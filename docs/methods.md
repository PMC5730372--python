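# Methods

## The problem

Proximity-labeling RNA pulldowns (APEX/HRP-style biotinylation of
compartment-resident proteins, followed by crosslinking and streptavidin
enrichment of the RNAs bound to them) produce paired expression tables: FPKM
per gene before and after the pulldown, over a few biological replicates,
plus a differential p-value from the upstream quantification pipeline. The
analysis task is to turn those tables into a defensible list of
compartment-enriched RNAs and to quantify how good that list is. `ripcall`
implements that downstream analysis; read alignment and FPKM/differential
quantification are upstream producers whose output it consumes.

## Enrichment calling

Per gene, with replicate means `mean_pre` and `mean_post` (FPKM) and
pseudocount `c`:

    log2_fc = log2((mean_post + c) / (mean_pre + c))

`c` defaults to 0; genes with zero FPKM in both conditions are dropped
(logged). A configurable pseudocount (0.1 FPKM is a reasonable choice)
handles genes with zero pre-pulldown signal. For bidirectional designs where
two constructs mark opposite compartments, the combined statistic is the
log2 ratio of the two post-pulldown means, and the second compartment is
called on the negated axis.

Order of operations is fixed: genes without a p-value or with p > alpha
(default 0.05) are removed first, together with an optional inclusive
pre-pulldown abundance floor; only the survivors enter threshold selection.
Untested genes (missing p) are treated as not significant, because "absent"
from the upstream differential test means "untested", not "null".

The log2 fold-change cutoff comes from ROC analysis against curated
true-positive and false-positive reference gene sets. Candidate thresholds
are the observed reference fold changes plus a sentinel above the maximum
(at which nothing is called); at each threshold the true- and false-positive
rates are the fractions of reference genes called (inclusively, >= t), and
the chosen cutoff maximizes Youden's J = TPR − FPR. Two numerical choices
matter:

- J is maximized in exact integer arithmetic on the counts
  (`tp_ge*n_fp − fp_ge*n_tp`), because rational ties such as
  9/10 − 5/10 = 8/10 − 4/10 are not exact ties in floating point and a
  float `max` can silently land on the wrong side of a tie.
- Ties are broken toward the largest (most stringent) threshold, favouring
  specificity over coverage. The chosen cutoff and J are recorded in every
  output's metadata.

Reference genes absent from the (filtered) expression records are excluded
from the TPR/FPR denominators, with a logged count; a reference set with no
genes left raises an error naming the empty side. Because ROC runs after the
significance filter, false-positive reference genes must be genes the
upstream test actually covered — in practice FP lists should be large
(hundreds to thousands of genes), which is also what keeps the rates stable.

## Benchmark metrics

All metrics are plain set arithmetic, reported with their denominators:

- contamination frequency = |called ∩ off-target| / |called|;
- secretory specificity = fraction of called protein-coding genes with any
  of the four secretory flags (Phobius, TMHMM, SignalP, GO cellular
  component). Genes missing from the annotation count as unannotated in the
  default (conservative) denominator; a matched-only variant is reported
  alongside;
- recall = |called ∩ reference standard| / |reference standard|;
- sensitivity floor = the q-th quantile (linear interpolation between order
  statistics, default q = 0.05) of pre-pulldown mean FPKM over called genes —
  "95% of called transcripts have input abundance of at least the floor";
- biotype composition (counts sum to the list size) and sub-mitochondrial
  destination fractions over {OMM, IMM, matrix, IMS}, where only genes with
  a known destination enter the denominator.

## Overlap analysis

Two called lists drawn from a shared expressed-gene universe of size N are
intersected, and the overlap size k is tested against the upper tail of
Hypergeometric(N, n1, n2) via scipy's log-space survival function
(`sf(k-1, N, n1, n2)`), stable for universes of at least 1e5 genes. Only the
enrichment (upper) tail is tested. Per-biotype-class tests restrict the
universe and both lists to that class; Benjamini–Hochberg correction across
classes is available but off by default. The universe is the caller's
choice (a sensible default: genes expressed at >= 1 FPKM in both
experiments) and is recorded in the output.

The interface (nuclear-lamina) workflow intersects a nuclear list with an
ER-lumen list and removes protein-coding genes carrying any secretory flag:
gene-level quantification convolves nuclear pre-mRNA with mature
ER-localized mRNA of the same gene, so secretory mRNAs in the overlap are
uninformative about the interface. Survivors are split into mRNA vs
noncoding. The operation is symmetric in its two inputs.

## qPCR yields

With per-primer amplification efficiency eps (fractional gain per cycle,
flagged — not dropped — below 0.90):

    yield% = 100 * (1 + eps) ** dCt,   dCt = Ct_input_corr − Ct_RIP_corr

The input aliquot is a fraction f of the lysate (default 0.2), so the input
Ct is corrected down by log_{1+eps}(1/f) cycles to the full-lysate
equivalent; a generic per-sample `ct_offset` accommodates other volume
corrections. Replicate spread uses the n−1 estimator. Uncertainty is
propagated to first order: sigma_D = sqrt(sigma_A² + sigma_B²) for
differences, relative variances add for products/quotients, and
sigma_f = sigma_x·|f′(x)| in general, giving
sigma_yield = sigma_dCt · yield · ln(1+eps). Because the yield is computed
from the replicate mean Ct, the plate-level pipeline feeds the standard
error of that mean (sd/sqrt(n)) into the propagation; Monte-Carlo checks in
the test suite confirm the first-order sigma tracks the empirical spread to
within ~10% at the relative errors seen in practice (<= 10%).

## Synthetic data: what it does and does not emulate

The generator plants known ground truth so every stage is testable offline:

- baseline abundance: log10 FPKM ~ Normal(0, 1), i.e. a heavy-tailed FPKM
  distribution with about half the genes above 1 FPKM;
- replicates: multiplicative log-normal noise with unit mean and a given CV
  (default 0.2, three replicates, matching a typical three-biological-
  replicate design);
- enrichment: post-pulldown abundance is scaled by 2^effect, where effect is
  2.0 ± 0.1 (log2) for the 15% of genes planted as targets, 0.5 ± 0.1 for
  the 5% planted as off-target leakage, and exactly 0 for the background;
- p-values: Welch's t-test on log2(FPKM + 0.01) replicates. This stands in
  for the upstream differential caller; it does not replicate count-based
  dispersion modelling, so its power at n = 3 is lower than a count model's;
- annotation: targets are secretory at rate 0.9, background at 0.2
  (matching the ~20% background transmembrane-annotation rate of
  mitochondrial proteomes); each of the four predictor flags fires at 0.85
  given secretory status and 0.02 otherwise; 8% of genes are mitochondrial,
  60% of those with a known destination drawn as OMM .18 / IMM .42 /
  matrix .30 / IMS .10;
- reference sets: 50 TP genes sampled from the planted targets and 500 FP
  genes from the pure background, mirroring the scale of curated reference
  lists (tens of TP genes, hundreds-to-thousands of FP genes). FP reference
  genes are true nulls, so only ~alpha of them survive the significance
  filter — small FP sets would make the post-filter ROC unstable or empty;
- all randomness flows from one seed through per-table substreams
  (`SeedSequence.spawn`), so one table can be regenerated without
  disturbing the others; an optional `planted` truth table lets related
  experiments share target genes.

Not emulated: compositional effects of sequencing depth (enriching targets
does not depress background FPKM here, whereas real per-million
normalization couples them), batch effects, gene length/GC bias,
isoform-level structure, and correlated annotation errors. Passing the
recovery tests therefore shows the calling logic is correct under the
model's assumptions, not that real pulldowns achieve these numbers.

The qPCR simulator inverts the yield equation (dCt = log_{1+eps}(y/100)),
anchors the input at a corrected Ct of 20 cycles (a typical mid-range
value), and adds per-replicate Gaussian Ct noise; at zero noise the yield
computation recovers the planted truth exactly.

## Problem sizes and degenerate inputs

The recovery study in the tests and acceptance script uses 20 independent
seeds of 5000 genes at the default conditions — large enough that recall and
contamination are stable to a couple of percent, small enough to run in
seconds. Monte-Carlo propagation checks use 1e6 draws. Degenerate inputs
are reported as missing rather than guessed: empty called lists have no
contamination frequency or sensitivity floor; a called list with no mRNAs
has no secretory specificity; genes without sub-mitochondrial annotation
never enter destination fractions.

## Identifier handling

GENCODE-style version suffixes ("ENSG….N") are stripped for all joins and
set operations (normalization is idempotent) but the original identifier is
preserved in every output, since annotation versions drift between tables.
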