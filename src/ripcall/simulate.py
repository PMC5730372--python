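"""Synthetic pulldown experiments with known ground truth.

The generator emulates the statistical structure the enrichment analysis
assumes: each gene has a log-normally distributed baseline abundance (FPKM);
pre-pulldown replicates are the baseline times multiplicative log-normal
noise of a given coefficient of variation; post-pulldown replicates are
additionally scaled by 2**effect, where the true log2 effect is the target
effect size for compartment RNAs, a smaller leakage effect for off-target
contaminants, and exactly zero for the background. Differential p-values
come from a Welch t-test on log2-transformed replicates, standing in for the
upstream differential-expression caller whose output the real pipeline
consumes. A companion annotation table (secretory flags, mitochondrial
destination, biotype) and ROC reference sets are generated jointly so every
downstream stage is testable without any external data.

All randomness flows from a single seed through per-table substreams, so any
one table can be regenerated without disturbing the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .io_tables import ExpressionTable, ReferenceSets
from .qpcr import CtMeasurement, PrimerPair

logger = logging.getLogger(__name__)

DEFAULT_BIOTYPE_MIX = {
    "protein_coding": 0.72,
    "lincRNA": 0.12,
    "antisense": 0.08,
    "processed_pseudogene": 0.05,
    "snoRNA": 0.03,
}
DEFAULT_SUBMITO_MIX = {"OMM": 0.18, "IMM": 0.42, "matrix": 0.30, "IMS": 0.10}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic pulldown experiment.

    Defaults model a three-replicate compartment pulldown over ~5000
    expressed genes with a 4-fold (2 log2 units) true enrichment of 15% of
    genes, 5% off-target leakage at 1.4-fold, log10 baseline FPKM ~ N(0, 1)
    (about half the genes above 1 FPKM) and 20% replicate noise.
    """

    n_genes: int = 5000
    fraction_enriched: float = 0.15
    fraction_off_target: float = 0.05
    effect_log2: float = 2.0
    contaminant_log2: float = 0.5
    effect_jitter_sd: float = 0.1  # per-gene spread of the true effect, log2 units
    baseline_log10_fpkm_mean: float = 0.0
    baseline_log10_fpkm_sd: float = 1.0
    replicate_cv: float = 0.2
    n_replicates: int = 3
    biotype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_MIX)
    )
    secretory_rate_targets: float = 0.9
    secretory_rate_background: float = 0.2
    mito_rate: float = 0.08
    submito_known_rate: float = 0.6
    submito_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBMITO_MIX)
    )
    n_reference_tp: int = 50
    n_reference_fp: int = 500
    pseudocount: float = 0.01  # for the log-scale differential test only
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        for name in ("fraction_enriched", "fraction_off_target"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_enriched + self.fraction_off_target > 1:
            raise ParameterError("fraction_enriched + fraction_off_target must be <= 1")
        if self.replicate_cv < 0:
            raise ParameterError("replicate_cv must be >= 0")
        if self.n_replicates < 2:
            raise ParameterError("n_replicates must be >= 2")
        if abs(sum(self.biotype_mix.values()) - 1.0) > 1e-9:
            raise ParameterError("biotype_mix must sum to 1")
        for name in ("secretory_rate_targets", "secretory_rate_background"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV; exactly 1 at CV 0."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def _welch_pvalues(
    log_pre: np.ndarray, log_post: np.ndarray
) -> np.ndarray:
    """Row-wise Welch t-test p-values; NaN where both groups are constant."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(log_post, log_pre, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def simulate_expression(
    config: SimulationConfig,
    planted: pd.DataFrame | None = None,
) -> tuple[ExpressionTable, pd.DataFrame, ReferenceSets, pd.DataFrame]:
    """Generate (expression table, annotation table, reference sets, truth).

    The truth table has one row per gene with ``is_target``,
    ``is_off_target``, ``true_log2_effect`` and the annotation fields.
    ``planted`` optionally fixes the ground truth (columns ``is_target``,
    ``is_off_target``, ``true_log2_effect``, one row per gene in order)
    instead of drawing it, so related experiments can share target genes;
    abundances, noise, annotation and reference draws still come from the
    config's seed.
    """
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_expr, rng_annot, rng_refs, _ = (np.random.default_rng(s) for s in seeds)

    n = config.n_genes
    gene_ids = np.array([f"SYNG{i:08d}.1" for i in range(1, n + 1)])

    # biotype assignment
    biotypes_all = list(config.biotype_mix)
    biotype = rng_annot.choice(
        biotypes_all, size=n, p=[config.biotype_mix[b] for b in biotypes_all]
    )

    # compartment status
    if planted is not None:
        if len(planted) != n:
            raise ParameterError(
                f"planted truth has {len(planted)} rows for {n} genes"
            )
        is_target = planted["is_target"].to_numpy(dtype=bool)
        is_off = planted["is_off_target"].to_numpy(dtype=bool)
        if (is_target & is_off).any():
            raise ParameterError("planted targets and off-targets must be disjoint")
        effect = planted["true_log2_effect"].to_numpy(dtype=float)
    else:
        n_target = int(round(config.fraction_enriched * n))
        n_off = int(round(config.fraction_off_target * n))
        perm = rng_expr.permutation(n)
        is_target = np.zeros(n, dtype=bool)
        is_target[perm[:n_target]] = True
        is_off = np.zeros(n, dtype=bool)
        is_off[perm[n_target : n_target + n_off]] = True

        effect = np.zeros(n)
        effect[is_target] = config.effect_log2 + rng_expr.normal(
            0.0, config.effect_jitter_sd, is_target.sum()
        )
        effect[is_off] = config.contaminant_log2 + rng_expr.normal(
            0.0, config.effect_jitter_sd, is_off.sum()
        )

    baseline = 10.0 ** rng_expr.normal(
        config.baseline_log10_fpkm_mean, config.baseline_log10_fpkm_sd, n
    )
    k = config.n_replicates
    pre = baseline[:, None] * _lognormal_noise(rng_expr, config.replicate_cv, (n, k))
    post = (
        baseline[:, None]
        * 2.0 ** effect[:, None]
        * _lognormal_noise(rng_expr, config.replicate_cv, (n, k))
    )

    pvals = _welch_pvalues(
        np.log2(pre + config.pseudocount), np.log2(post + config.pseudocount)
    )

    data = pd.DataFrame({"gene_id": gene_ids})
    data["gene_id_norm"] = [g[:-2] for g in gene_ids]  # strip the '.1'
    data["gene_name"] = [f"SynGene{i}" for i in range(1, n + 1)]
    data["biotype"] = biotype
    data["p_value"] = pvals
    pre_cols, post_cols = [], []
    for j in range(k):
        data[f"fpkm_pre_{j + 1}"] = pre[:, j]
        pre_cols.append(f"fpkm_pre_{j + 1}")
    for j in range(k):
        data[f"fpkm_post_{j + 1}"] = post[:, j]
        post_cols.append(f"fpkm_post_{j + 1}")
    table = ExpressionTable(data=data, pre_cols=pre_cols, post_cols=post_cols)

    # annotation: targets are mostly secretory, background mostly not
    sec_rate = np.where(
        is_target, config.secretory_rate_targets, config.secretory_rate_background
    )
    is_secretory = rng_annot.random(n) < sec_rate
    annot = pd.DataFrame(
        {"gene_id": gene_ids, "gene_id_norm": data["gene_id_norm"], "biotype": biotype}
    )
    for flag in ("secretory_phobius", "secretory_tmhmm", "secretory_signalp", "secretory_gocc"):
        hit = rng_annot.random(n) < np.where(is_secretory, 0.85, 0.02)
        annot[flag] = hit
    annot["is_mito"] = rng_annot.random(n) < config.mito_rate
    locs = list(config.submito_mix)
    drawn = rng_annot.choice(locs, size=n, p=[config.submito_mix[l] for l in locs])
    known = annot["is_mito"].to_numpy() & (
        rng_annot.random(n) < config.submito_known_rate
    )
    annot["submito_location"] = np.where(known, drawn, "unknown")

    # reference sets for ROC: TPs from true targets, FPs from pure background
    target_ids = gene_ids[is_target]
    bg_ids = gene_ids[~is_target & ~is_off]
    n_tp = min(config.n_reference_tp, target_ids.size)
    n_fp = min(config.n_reference_fp, bg_ids.size)
    if n_tp == 0 or n_fp == 0:
        refs = ReferenceSets(set(), set(), label="synthetic")
    else:
        tp_ids = rng_refs.choice(target_ids, size=n_tp, replace=False)
        fp_ids = rng_refs.choice(bg_ids, size=n_fp, replace=False)
        refs = ReferenceSets(set(tp_ids), set(fp_ids), label="synthetic")

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_id_norm": data["gene_id_norm"],
            "is_target": is_target,
            "is_off_target": is_off,
            "true_log2_effect": effect,
            "baseline_fpkm": baseline,
            "biotype": biotype,
        }
    )
    for col in (
        "secretory_phobius",
        "secretory_tmhmm",
        "secretory_signalp",
        "secretory_gocc",
        "is_mito",
        "submito_location",
    ):
        truth[col] = annot[col]
    logger.info(
        "simulated %d genes: %d targets, %d off-target, %d background",
        n,
        int(is_target.sum()),
        int(is_off.sum()),
        int((~is_target & ~is_off).sum()),
    )
    return table, annot, refs, truth


def simulate_qpcr(
    yield_truth: dict[str, float],
    efficiencies: dict[str, float],
    ct_noise_sd: float = 0.0,
    n_replicates: int = 4,
    seed: int = 0,
    input_fraction: float = 0.2,
    input_ct_corr: float = 20.0,
) -> tuple[list[CtMeasurement], dict[str, PrimerPair]]:
    """Invert the yield equation to synthesize a qPCR plate.

    For each target, dCt = log_{1+eps}(yield/100); the input sample is given
    a corrected Ct of ``input_ct_corr`` cycles (raw Ct re-inflated by the
    input-fraction offset) and the pulldown Ct is placed dCt cycles away.
    Gaussian noise of sd ``ct_noise_sd`` is added per replicate. With zero
    noise, running the yield computation on the output recovers
    ``yield_truth`` exactly.
    """
    if ct_noise_sd < 0:
        raise ParameterError("ct_noise_sd must be >= 0")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    measurements: list[CtMeasurement] = []
    pairs: dict[str, PrimerPair] = {}
    for target in sorted(yield_truth):
        y = yield_truth[target]
        if y <= 0:
            raise ParameterError(f"yield for {target} must be > 0, got {y}")
        eps = efficiencies[target]
        if not 0 < eps <= 1:
            raise ParameterError(f"efficiency for {target} must be in (0, 1], got {eps}")
        delta_ct = math.log(y / 100.0, 1.0 + eps)
        ct_input_raw = input_ct_corr + math.log(1.0 / input_fraction, 1.0 + eps)
        ct_rip = input_ct_corr - delta_ct
        for sample, center in (("input", ct_input_raw), ("RIP", ct_rip)):
            reps = center + rng.normal(0.0, ct_noise_sd, n_replicates) if ct_noise_sd else np.full(n_replicates, center)
            measurements.append(
                CtMeasurement(
                    sample=sample,
                    target=target,
                    ct_replicates=[float(v) for v in reps],
                    input_fraction=input_fraction,
                )
            )
        pairs[target] = PrimerPair(target, eps)
    return measurements, pairs


def write_simulation(
    outdir,
    table: ExpressionTable,
    annot: pd.DataFrame,
    refs: ReferenceSets,
    truth: pd.DataFrame,
) -> None:
    """Write the four simulated tables as TSV / plain-text gene lists."""
    from pathlib import Path

    from .io_tables import write_reference_set

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.data.drop(columns=["gene_id_norm"]).to_csv(
        outdir / "expression.tsv", sep="\t", index=False
    )
    annot.drop(columns=["gene_id_norm"]).to_csv(
        outdir / "annotation.tsv", sep="\t", index=False
    )
    write_reference_set(refs.true_positives, outdir / "reference_tp.txt")
    write_reference_set(refs.false_positives, outdir / "reference_fp.txt")
    truth.drop(columns=["gene_id_norm"]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
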