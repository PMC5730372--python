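#!/usr/bin/env python
"""Intersect the nuclear and ER lists and nominate interface candidates.

Tests the overlap of the two called lists against the hypergeometric null
over the full simulated gene universe (globally and per biotype class), then
applies the interface workflow: remove secretory mRNAs from the overlap —
their presence in both lists is explained by nuclear pre-mRNA plus mature
ER-localized transcripts — and split the surviving candidates into mRNA vs
noncoding. Writes results/overlap.tsv and results/laminar_candidates.tsv.
"""

import math
from pathlib import Path

import pandas as pd

from ripcall.io_tables import read_annotation, read_enriched_list
from ripcall.overlap import laminar_candidates, overlap_analysis, venn_counts

SIM = Path("results/sim")
CALLED = Path("results/called")
OUT = Path("results")


def main() -> None:
    nuclear = read_enriched_list(CALLED / "enriched_nuclear.tsv")
    er = read_enriched_list(CALLED / "enriched_er.tsv")
    annot = read_annotation(SIM / "nuclear" / "annotation.tsv")
    expr = pd.read_csv(SIM / "nuclear" / "expression.tsv", sep="\t", usecols=["gene_id"])
    universe = set(expr["gene_id"].str.replace(r"\.\d+$", "", regex=True))

    res = overlap_analysis(nuclear, er, universe, annot=annot)
    res.to_frame().to_csv(OUT / "overlap.tsv", sep="\t", index=False)
    regions = venn_counts([nuclear, er])
    print(
        f"venn: nuclear-only {regions['1']}, er-only {regions['2']}, "
        f"shared {regions['12']}"
    )
    p_txt = f"{res.p_upper:.3g}" if res.p_upper > 0 else "< 1e-300"
    print(
        f"overlap: {res.k} RNAs of {res.size_a} nuclear x {res.size_b} ER "
        f"in a universe of {res.universe_size}; hypergeometric p {p_txt}"
    )

    lam = laminar_candidates(nuclear, er, annot)
    rows = [
        {
            "gene_id": g,
            "is_candidate": g in lam.candidates,
            "removed_secretory_mrna": g in lam.removed_secretory_mrnas,
        }
        for g in sorted(lam.all_overlap)
    ]
    pd.DataFrame(rows).to_csv(OUT / "laminar_candidates.tsv", sep="\t", index=False)
    print(
        f"interface candidates: {len(lam.candidates)} of {len(lam.all_overlap)} "
        f"overlapping RNAs after removing {len(lam.removed_secretory_mrnas)} "
        f"secretory mRNAs ({lam.class_counts['mRNA']} mRNA, "
        f"{lam.class_counts['noncoding']} noncoding)"
    )


if __name__ == "__main__":
    main()
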