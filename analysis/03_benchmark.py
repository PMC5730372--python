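#!/usr/bin/env python
"""Benchmark the called lists against the planted truth and annotation.

Reports, per compartment: contamination frequency (called off-target RNAs /
all called RNAs), secretory specificity of called mRNAs, recall of the
planted targets, the 5th-percentile input-abundance sensitivity floor, and
biotype composition. Writes results/benchmark_<label>.tsv.
"""

from pathlib import Path

import pandas as pd

from ripcall import benchmarks
from ripcall.io_tables import read_annotation, read_enriched_list

SIM = Path("results/sim")
CALLED = Path("results/called")
OUT = Path("results")


def main() -> None:
    for label in ("nuclear", "er"):
        enriched = read_enriched_list(CALLED / f"enriched_{label}.tsv")
        annot = read_annotation(SIM / label / "annotation.tsv")
        truth = pd.read_csv(SIM / label / "truth.tsv", sep="\t")
        truth["gene_id_norm"] = truth["gene_id"].str.replace(r"\.\d+$", "", regex=True)
        targets = set(truth.loc[truth["is_target"], "gene_id_norm"])
        off = set(truth.loc[truth["is_off_target"], "gene_id_norm"])

        report = benchmarks.benchmark(enriched, annot, off_target=off, reference=targets)
        report.to_frame().to_csv(OUT / f"benchmark_{label}.tsv", sep="\t", index=False)
        noncoding = report.n_enriched - report.biotype_counts.get("protein_coding", 0)
        print(
            f"{label}: {report.n_enriched} called | "
            f"contamination {100 * report.contamination_frequency:.2f}% | "
            f"secretory specificity {100 * report.secretory_specificity:.1f}% | "
            f"recall {100 * report.recall:.1f}% | "
            f"5% sensitivity floor {report.sensitivity_floor_fpkm:.3f} FPKM | "
            f"{noncoding} noncoding RNAs "
            f"({100 * noncoding / report.n_enriched:.1f}%)"
        )
    print(f"wrote benchmark reports to {OUT}")


if __name__ == "__main__":
    main()
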