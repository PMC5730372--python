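# ripcall

Calling, benchmarking and overlap analysis of compartment-enriched RNAs from
proximity-labeling pulldown expression tables.

Proximity labeling (APEX/HRP peroxidases targeted to a subcellular
compartment) biotinylates compartment-resident proteins in live cells;
crosslinking and streptavidin pulldown then enrich the RNAs bound to them.
After upstream alignment and quantification, the experiment reduces to a
gene-level table: FPKM per replicate before and after pulldown, plus a
differential p-value. `ripcall` is the downstream analysis for people who
have such tables (or want to prototype against simulated ones): it decides
which RNAs are compartment-enriched, quantifies how trustworthy the list is,
compares lists between compartments, and checks yields by qPCR.

## The statistics

Per gene, enrichment is the log2 ratio of replicate-mean abundances,
log2FC = log2((mean_post + c)/(mean_pre + c)). Genes failing the upstream
differential test (p > α, default 0.05) are removed; the log2FC cutoff is
then selected by ROC analysis against curated true-positive / false-positive
reference gene sets, maximizing Youden's J = TPR − FPR (ties broken toward
the most stringent cutoff), and genes at or above the cutoff are called.
Called lists are benchmarked by contamination frequency
(|called ∩ off-target| / |called|), secretory specificity, recall of a
reference standard, the 5th-percentile input-abundance sensitivity floor,
and biotype / sub-mitochondrial composition. Overlaps between compartment
lists are tested against the hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, n1, n2); the nuclear-lamina workflow removes
secretory mRNAs from the nuclear ∩ ER overlap before nominating interface
candidates. qPCR percent yields use the ΔCt method,
yield = 100·(1+ε)^ΔCt with ΔCt = Ct_input,corr − Ct_RIP,corr, with
first-order error propagation throughout.

A synthetic-data generator (`ripcall.simulate`) plants known targets,
off-target leakage, annotation and reference sets, so the whole pipeline is
testable end to end without any external data. See `docs/methods.md` for
model details and the generator's assumptions.

## Worked example

The numbered scripts under `analysis/` run the whole story on simulated
data (each is a thin driver over the library; all write under `results/`):

```
$ python analysis/01_simulate.py
nuclear dataset: 750 planted targets
ER dataset:      750 planted targets
targets planted in both compartments: 300

$ python analysis/02_call_enrichment.py
nuclear: cutoff log2_fc >= 1.528 (J = 1.000), 727 RNAs called, 96.9% of planted targets recovered
er: cutoff log2_fc >= 1.543 (J = 1.000), 730 RNAs called, 97.3% of planted targets recovered

$ python analysis/03_benchmark.py
nuclear: 727 called | contamination 0.00% | secretory specificity 92.1% | recall 96.9% | 5% sensitivity floor 0.023 FPKM | 183 noncoding RNAs (25.2%)

$ python analysis/04_overlap.py
overlap: 288 RNAs of 727 nuclear x 730 ER in a universe of 5000; hypergeometric p 1.35e-75
interface candidates: 88 of 288 overlapping RNAs after removing 200 secretory mRNAs (17 mRNA, 71 noncoding)

$ python analysis/05_qpcr.py
target    true%   measured%   fold vs GAPDH
GAPDH       0.8    0.77 +/- 0.03         ref
MALAT1      6.5    6.83 +/- 0.36      8.8 +/- 0.6
MT-CO1     35.0   35.71 +/- 1.79     46.2 +/- 3.1
```

Reading: the ROC-chosen cutoff (~1.5 log2 units) sits between the planted
4-fold targets and the 1.4-fold off-target leakage, so ~97% of true targets
are recovered with no off-target RNAs called; the two compartments share 288
called RNAs — far beyond the hypergeometric expectation for independent
lists of this size, because 300 targets were planted in both — and after
removing secretory mRNAs (whose double membership is explained by nuclear
pre-mRNA plus mature ER transcripts) 88 interface candidates remain. The
qPCR step recovers planted yields within its propagated uncertainty.

The same stages are available as a CLI (`ripcall simulate|call|benchmark|
overlap|qpcr`, see `--help`) for running on real tables: point `call` at a
CuffDiff-style expression table, two reference gene lists, and a column
mapping if your headers differ.

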