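"""Specificity, contamination, recall and composition metrics for called lists.

All rates are plain set arithmetic over gene identifiers, reported together
with their denominators so they can be audited. Contamination frequency is
the fraction of a called list that belongs to a known off-target set;
secretory specificity is the fraction of called mRNAs carrying any secretory
annotation (Phobius, TMHMM, SignalP or GO cellular component); recall is the
fraction of a reference standard recovered; the sensitivity floor is the
lower quantile of pre-pulldown abundance among called genes ("95% of called
transcripts have input abundance >= floor" corresponds to the 5th
percentile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import EnrichedList
from .errors import ParameterError
from .io_tables import SECRETORY_FLAGS, SUBMITO_LOCATIONS, normalize_gene_id

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkReport:
    label: str
    n_enriched: int
    contamination_frequency: float | None = None
    secretory_specificity: float | None = None
    secretory_specificity_matched_only: float | None = None
    recall: float | None = None
    sensitivity_floor_fpkm: float | None = None
    biotype_counts: dict[str, int] = field(default_factory=dict)
    submito_fractions: dict[str, float] = field(default_factory=dict)
    denominators: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_enriched", self.n_enriched, self.n_enriched)]
        for name in (
            "contamination_frequency",
            "secretory_specificity",
            "secretory_specificity_matched_only",
            "recall",
            "sensitivity_floor_fpkm",
        ):
            rows.append((name, getattr(self, name), self.denominators.get(name)))
        for bt, n in sorted(self.biotype_counts.items()):
            rows.append((f"biotype:{bt}", n, self.n_enriched))
        for loc, f in self.submito_fractions.items():
            rows.append((f"submito:{loc}", f, self.denominators.get("submito")))
        return pd.DataFrame(rows, columns=["metric", "value", "denominator"])


def _annot_for(genes: set[str], annot: pd.DataFrame) -> pd.DataFrame:
    sub = annot.loc[annot["gene_id_norm"].isin(genes)]
    return sub.drop_duplicates("gene_id_norm")


def contamination_frequency(
    enriched: EnrichedList, off_target: set[str]
) -> float | None:
    """|called ∩ off_target| / |called|; None (with warning) for an empty list."""
    if not enriched.genes:
        logger.warning("contamination frequency undefined for empty list %s", enriched.label)
        return None
    off = {normalize_gene_id(g) for g in off_target}
    return len(enriched.genes & off) / len(enriched.genes)


def secretory_specificity(
    enriched: EnrichedList, annot: pd.DataFrame, matched_only: bool = False
) -> float | None:
    """Fraction of called protein-coding genes with any secretory flag.

    By default every called mRNA counts in the denominator and genes missing
    from the annotation count as unannotated (conservative). With
    ``matched_only`` the denominator is restricted to annotated genes.
    """
    mrnas = set(
        enriched.records.loc[
            enriched.records["biotype"] == "protein_coding", "gene_id_norm"
        ]
    )
    if not mrnas:
        logger.warning("no protein-coding genes in list %s; specificity undefined", enriched.label)
        return None
    sub = _annot_for(mrnas, annot)
    n_flagged = int(sub[list(SECRETORY_FLAGS)].any(axis=1).sum())
    n_unmatched = len(mrnas) - len(sub)
    if n_unmatched:
        logger.info("%d called mRNAs lack annotation entries", n_unmatched)
    denom = len(sub) if matched_only else len(mrnas)
    if denom == 0:
        return None
    return n_flagged / denom


def recall(enriched: EnrichedList, reference: set[str]) -> float:
    """Fraction of the reference standard recovered by the called list."""
    ref = {normalize_gene_id(g) for g in reference}
    if not ref:
        raise ParameterError("reference set for recall is empty")
    return len(enriched.genes & ref) / len(ref)


def sensitivity_floor(enriched: EnrichedList, quantile: float = 0.05) -> float | None:
    """Lower quantile (linear interpolation) of pre-pulldown mean FPKM."""
    if not 0 < quantile < 1:
        raise ParameterError(f"quantile must be in (0, 1), got {quantile}")
    if enriched.records.empty:
        logger.warning("sensitivity floor undefined for empty list %s", enriched.label)
        return None
    return float(
        np.quantile(enriched.records["mean_pre"].to_numpy(), quantile, method="linear")
    )


def biotype_composition(enriched: EnrichedList, annot: pd.DataFrame | None = None) -> dict[str, int]:
    """Counts per biotype; genes without a biotype are binned as 'unknown'."""
    if enriched.records.empty:
        return {}
    biotypes = enriched.records["biotype"].fillna("unknown").replace("", "unknown")
    if annot is not None:
        lookup = annot.drop_duplicates("gene_id_norm").set_index("gene_id_norm")["biotype"]
        mapped = enriched.records["gene_id_norm"].map(lookup)
        biotypes = biotypes.where(biotypes != "unknown", mapped.fillna("unknown"))
    return biotypes.value_counts().to_dict()


def submito_composition(
    enriched: EnrichedList, annot: pd.DataFrame
) -> tuple[dict[str, float], int]:
    """Sub-mitochondrial destination fractions among annotated called genes.

    Only genes with a known sub-mitochondrial location enter the denominator;
    returns (fractions over OMM/IMM/matrix/IMS summing to 1, denominator).
    """
    sub = _annot_for(enriched.genes, annot)
    located = sub.loc[sub["submito_location"].isin(SUBMITO_LOCATIONS)]
    n = len(located)
    if n == 0:
        logger.warning("no called genes carry sub-mitochondrial annotation")
        return {}, 0
    counts = located["submito_location"].value_counts()
    return {loc: counts.get(loc, 0) / n for loc in SUBMITO_LOCATIONS}, n


def transmembrane_enrichment(
    enriched: EnrichedList, annot: pd.DataFrame, background: set[str]
) -> tuple[float | None, float | None]:
    """TMHMM-flag fraction among the list's mitochondrial mRNAs vs background.

    Both fractions are computed over mitochondrial genes only (is_mito true).
    """
    bg = {normalize_gene_id(g) for g in background}
    if not bg:
        raise ParameterError("background set is empty")

    def _fraction(genes: set[str]) -> float | None:
        sub = _annot_for(genes, annot)
        mito = sub.loc[sub["is_mito"]]
        if mito.empty:
            return None
        return float(mito["secretory_tmhmm"].mean())

    frac_list = _fraction(enriched.genes)
    frac_bg = _fraction(bg)
    if frac_list is None or frac_bg is None:
        logger.warning("empty mitochondrial subset in list or background")
    return frac_list, frac_bg


def benchmark(
    enriched: EnrichedList,
    annot: pd.DataFrame,
    off_target: set[str] | None = None,
    reference: set[str] | None = None,
    quantile: float = 0.05,
) -> BenchmarkReport:
    """Assemble the full benchmark report for one called list."""
    report = BenchmarkReport(label=enriched.label, n_enriched=len(enriched.genes))
    if off_target is not None:
        report.contamination_frequency = contamination_frequency(enriched, off_target)
        report.denominators["contamination_frequency"] = len(enriched.genes)
    report.secretory_specificity = secretory_specificity(enriched, annot)
    report.secretory_specificity_matched_only = secretory_specificity(
        enriched, annot, matched_only=True
    )
    n_mrna = int((enriched.records["biotype"] == "protein_coding").sum()) if not enriched.records.empty else 0
    report.denominators["secretory_specificity"] = n_mrna
    if reference is not None:
        report.recall = recall(enriched, reference)
        report.denominators["recall"] = len(reference)
    report.sensitivity_floor_fpkm = sensitivity_floor(enriched, quantile)
    report.biotype_counts = biotype_composition(enriched)
    report.submito_fractions, n_submito = submito_composition(enriched, annot)
    report.denominators["submito"] = n_submito
    return report
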