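"""Fold-enrichment computation, significance filtering and ROC-based calling.

The core statistic is the log2 fold enrichment of each gene's mean FPKM after
streptavidin pulldown over its mean FPKM before pulldown,

    log2_fc = log2((mean_post + c) / (mean_pre + c))

with pseudocount ``c`` (default 0). Genes failing the upstream differential
test (p > alpha, or untested) are removed first; the remaining genes enter a
ROC analysis against curated true-positive / false-positive reference sets,
and the log2 fold-change cutoff maximizing Youden's J = TPR − FPR is chosen.
Calling is inclusive (log2_fc >= cutoff). When several cutoffs attain the
maximal J the largest (most stringent) one is chosen, favouring specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io_tables import ExpressionTable, ReferenceSets

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    """Full ROC trace over candidate log2 fold-change cutoffs.

    ``thresholds`` are the sorted unique candidate cutoffs (reference-set
    fold changes plus a sentinel above the maximum, at which nothing is
    called). ``chosen_threshold`` maximizes ``youden`` = TPR − FPR; ties go
    to the largest threshold.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    youden: np.ndarray
    chosen_threshold: float
    chosen_j: float
    n_tp: int = 0
    n_fp: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tpr": self.tpr,
                "fpr": self.fpr,
                "youden": self.youden,
            }
        )


@dataclass
class EnrichedList:
    """A called compartment list with the provenance of its threshold."""

    label: str
    genes: set[str]
    threshold: float
    alpha: float
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.genes)


def compute_fold_changes(
    table: ExpressionTable, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Per-gene log2 fold enrichment of mean post- over mean pre-pulldown FPKM.

    Returns a DataFrame with columns gene_id, gene_id_norm, biotype, mean_pre,
    mean_post, log2_fc, p_value. Genes with mean_pre = mean_post = 0 carry no
    information and are dropped (count logged).
    """
    if pseudocount < 0:
        raise ParameterError(f"pseudocount must be >= 0, got {pseudocount}")
    if len(table) == 0:
        raise ValidationError("expression table is empty")

    out = table.data[["gene_id", "gene_id_norm", "biotype", "p_value"]].copy()
    out["mean_pre"] = table.fpkm_pre().mean(axis=1)
    out["mean_post"] = table.fpkm_post().mean(axis=1)

    both_zero = (out["mean_pre"] == 0) & (out["mean_post"] == 0)
    if both_zero.any():
        logger.info("dropping %d genes with zero FPKM pre and post", both_zero.sum())
        out = out.loc[~both_zero].reset_index(drop=True)

    with np.errstate(divide="ignore"):
        out["log2_fc"] = np.log2(
            (out["mean_post"] + pseudocount) / (out["mean_pre"] + pseudocount)
        )
    return out


def compute_combined_fold_changes(
    table_a_post: ExpressionTable,
    table_b_post: ExpressionTable,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """log2 ratio of post-pulldown means between two experiments (A over B).

    Used for bidirectional partitioning where the two pulldowns mark opposite
    compartments (e.g. nuclear- vs cytosol-targeted constructs); a gene's
    p_value is the larger (more conservative) of the two experiments' values.
    Genes present in only one table are dropped with a logged count.
    """
    if pseudocount < 0:
        raise ParameterError(f"pseudocount must be >= 0, got {pseudocount}")
    a = table_a_post.data[["gene_id", "gene_id_norm", "biotype", "p_value"]].copy()
    a["mean_post_a"] = table_a_post.fpkm_post().mean(axis=1)
    a["mean_pre"] = table_a_post.fpkm_pre().mean(axis=1)
    b = table_b_post.data[["gene_id_norm", "p_value"]].copy()
    b["mean_post_b"] = table_b_post.fpkm_post().mean(axis=1)

    merged = a.merge(b, on="gene_id_norm", how="inner", suffixes=("_a", "_b"))
    n_dropped = len(a) + len(b) - 2 * len(merged)
    if len(merged) == 0:
        raise ValidationError("no shared gene identifiers between the two tables")
    if n_dropped:
        logger.info("dropped %d genes present in only one table", n_dropped)

    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "gene_id_norm": merged["gene_id_norm"],
            "biotype": merged["biotype"],
            "mean_pre": merged["mean_pre"],
            "mean_post": merged["mean_post_a"],
            "p_value": merged[["p_value_a", "p_value_b"]].max(axis=1),
        }
    )
    out["log2_fc"] = np.log2(
        (merged["mean_post_a"] + pseudocount) / (merged["mean_post_b"] + pseudocount)
    )
    return out


def filter_significant(
    records: pd.DataFrame, alpha: float = 0.05, min_pre_fpkm: float = 0.0
) -> pd.DataFrame:
    """Keep genes the upstream differential test called at p <= alpha.

    Genes without a p-value were not tested and are treated as not
    significant. ``min_pre_fpkm`` applies an inclusive abundance floor on the
    pre-pulldown mean (0 disables it).
    """
    if not 0 < alpha <= 1:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    if min_pre_fpkm < 0:
        raise ParameterError(f"min_pre_fpkm must be >= 0, got {min_pre_fpkm}")
    keep = (
        records["p_value"].notna()
        & (records["p_value"] <= alpha)
        & (records["mean_pre"] >= min_pre_fpkm)
    )
    logger.info(
        "significance filter (alpha=%g, min_pre_fpkm=%g): %d -> %d genes",
        alpha,
        min_pre_fpkm,
        len(records),
        int(keep.sum()),
    )
    return records.loc[keep].reset_index(drop=True)


def roc_curve(records: pd.DataFrame, refs: ReferenceSets) -> RocCurve:
    """ROC threshold selection over the reference sets' fold changes.

    Candidate thresholds are the sorted unique log2 fold changes of the
    reference genes present in ``records``, plus a sentinel above the
    maximum. At each threshold t, TPR (FPR) is the fraction of present
    true-positive (false-positive) genes with log2_fc >= t. Reference genes
    absent from the records are dropped from the denominators (logged).
    """
    universe = records.set_index("gene_id_norm")["log2_fc"]
    tp_vals = universe.reindex(sorted(refs.true_positives)).dropna().to_numpy()
    fp_vals = universe.reindex(sorted(refs.false_positives)).dropna().to_numpy()
    n_tp_missing = len(refs.true_positives) - tp_vals.size
    n_fp_missing = len(refs.false_positives) - fp_vals.size
    if n_tp_missing or n_fp_missing:
        logger.info(
            "reference genes absent from records: %d TP, %d FP (excluded from rates)",
            n_tp_missing,
            n_fp_missing,
        )
    if tp_vals.size == 0:
        raise ValidationError("no true-positive reference genes present in records")
    if fp_vals.size == 0:
        raise ValidationError("no false-positive reference genes present in records")

    all_vals = np.concatenate([tp_vals, fp_vals])
    thresholds = np.unique(all_vals)
    sentinel = thresholds[-1] + 1.0  # calls nothing
    thresholds = np.append(thresholds, sentinel)

    # counts of reference values >= t, via searchsorted on sorted values
    n_tp, n_fp = tp_vals.size, fp_vals.size
    tp_ge = n_tp - np.searchsorted(np.sort(tp_vals), thresholds, side="left")
    fp_ge = n_fp - np.searchsorted(np.sort(fp_vals), thresholds, side="left")
    tpr = tp_ge / n_tp
    fpr = fp_ge / n_fp
    youden = tpr - fpr

    # maximize J in exact integer arithmetic so rational ties are true ties,
    # broken toward the largest (most stringent) threshold
    j_num = tp_ge * n_fp - fp_ge * n_tp
    chosen_idx = np.flatnonzero(j_num == j_num.max()).max()
    curve = RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        youden=youden,
        chosen_threshold=float(thresholds[chosen_idx]),
        chosen_j=float(youden[chosen_idx]),
        n_tp=int(tp_vals.size),
        n_fp=int(fp_vals.size),
    )
    logger.info(
        "ROC (%s): chosen log2 fold-change cutoff %.4f with J = %.4f "
        "(%d TP, %d FP genes)",
        refs.label,
        curve.chosen_threshold,
        curve.chosen_j,
        curve.n_tp,
        curve.n_fp,
    )
    return curve


def call_enriched(
    records: pd.DataFrame,
    threshold: float,
    alpha: float = 0.05,
    label: str = "",
) -> EnrichedList:
    """Call genes with log2_fc >= threshold (inclusive) and p_value <= alpha."""
    keep = (
        (records["log2_fc"] >= threshold)
        & records["p_value"].notna()
        & (records["p_value"] <= alpha)
    )
    surviving = records.loc[keep].reset_index(drop=True)
    logger.info(
        "called %d/%d genes at log2_fc >= %.4f, p <= %g (%s)",
        len(surviving),
        len(records),
        threshold,
        alpha,
        label,
    )
    return EnrichedList(
        label=label,
        genes=set(surviving["gene_id_norm"]),
        threshold=float(threshold),
        alpha=float(alpha),
        records=surviving,
    )


def call_with_roc(
    records: pd.DataFrame,
    refs: ReferenceSets,
    alpha: float = 0.05,
    min_pre_fpkm: float = 0.0,
    label: str = "",
) -> tuple[EnrichedList, RocCurve]:
    """Full calling path: significance filter, then ROC, then thresholding."""
    filtered = filter_significant(records, alpha=alpha, min_pre_fpkm=min_pre_fpkm)
    curve = roc_curve(filtered, refs)
    enriched = call_enriched(
        filtered, curve.chosen_threshold, alpha=alpha, label=label or refs.label
    )
    return enriched, curve


def call_bidirectional(
    records: pd.DataFrame,
    refs_nuclear: ReferenceSets,
    refs_cytosolic: ReferenceSets,
    alpha: float = 0.05,
) -> tuple[EnrichedList, EnrichedList]:
    """Partition a combined (A-post over B-post) fold-change table both ways.

    The nuclear list is called on log2_fc with the nuclear references; the
    cytosolic list on the negated log2_fc with the cytosolic references, so
    cytosolic genes satisfy log2_fc <= −cutoff. The outputs are disjoint
    whenever both cutoffs are positive, i.e. whenever each reference pair is
    separable in its own direction.
    """
    filtered = filter_significant(records, alpha=alpha)
    curve_nuc = roc_curve(filtered, refs_nuclear)
    nuclear = call_enriched(
        filtered, curve_nuc.chosen_threshold, alpha=alpha, label=refs_nuclear.label
    )

    flipped = filtered.copy()
    flipped["log2_fc"] = -flipped["log2_fc"]
    curve_cyt = roc_curve(flipped, refs_cytosolic)
    cytosolic = call_enriched(
        flipped, curve_cyt.chosen_threshold, alpha=alpha, label=refs_cytosolic.label
    )
    # restore the shared sign convention in the cytosolic records
    cytosolic.records = cytosolic.records.assign(
        log2_fc=-cytosolic.records["log2_fc"]
    )
    cytosolic.threshold = -cytosolic.threshold

    shared = nuclear.genes & cytosolic.genes
    if shared:
        logger.warning(
            "%d genes fall in both directions (non-positive cutoffs); "
            "removing them from both lists",
            len(shared),
        )
        for lst in (nuclear, cytosolic):
            lst.genes -= shared
            lst.records = lst.records.loc[
                ~lst.records["gene_id_norm"].isin(shared)
            ].reset_index(drop=True)
    return nuclear, cytosolic
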