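"""End-to-end orchestration of the calling, benchmarking and overlap stages.

Each ``run_*`` function reads its inputs, executes the fixed stage order and
writes deterministic TSV artifacts; every filter logs gene counts before and
after so published-style list sizes are auditable from the log alone. Stage
failures abort with a stage-labeled error and remove partial outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import benchmarks, enrichment, io_tables, overlap
from .errors import RipcallError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.

    alpha is the differential-test p-value cutoff (0.05 by default, matching
    the upstream caller's conventional level); min_pre_fpkm is an inclusive
    pre-pulldown abundance floor (0 disables); pseudocount guards zero FPKM.
    """

    expression: str | None = None
    annotation: str | None = None
    reference_tp: str | None = None
    reference_fp: str | None = None
    off_target: str | None = None
    reference_standard: str | None = None
    enriched_a: str | None = None
    enriched_b: str | None = None
    universe: str | None = None
    ct_table: str | None = None
    qpcr_reference: str | None = None
    label: str = "compartment"
    alpha: float = 0.05
    min_pre_fpkm: float = 0.0
    pseudocount: float = 0.0
    quantile: float = 0.05
    seed: int = 0
    outdir: str = "results"
    dialect: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise RipcallError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _read_gene_list(path: str | Path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


class _Stage:
    """Context manager labeling errors with the failing stage and cleaning up."""

    def __init__(self, name: str, partials: list[Path]):
        self.name = name
        self.partials = partials

    def __enter__(self):
        logger.info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            for p in self.partials:
                Path(p).unlink(missing_ok=True)
            raise RipcallError(f"[{self.name}] {exc}") from exc
        return False


def run_call(config: RunConfig) -> tuple[enrichment.EnrichedList, enrichment.RocCurve]:
    """read -> fold change -> significance filter -> ROC -> call -> write."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    list_path = outdir / f"enriched_{config.label}.tsv"
    roc_path = outdir / f"roc_{config.label}.tsv"
    partials = [list_path, roc_path]

    with _Stage("read", partials):
        table = io_tables.read_expression_table(config.expression, config.dialect or None)
        refs = io_tables.read_reference_sets(
            config.reference_tp, config.reference_fp, label=config.label
        )
    with _Stage("fold-change", partials):
        records = enrichment.compute_fold_changes(table, config.pseudocount)
    with _Stage("filter", partials):
        filtered = enrichment.filter_significant(
            records, alpha=config.alpha, min_pre_fpkm=config.min_pre_fpkm
        )
    with _Stage("roc", partials):
        curve = enrichment.roc_curve(filtered, refs)
    with _Stage("call", partials):
        enriched = enrichment.call_enriched(
            filtered, curve.chosen_threshold, alpha=config.alpha, label=config.label
        )
    with _Stage("write", partials):
        io_tables.write_enriched_list(enriched, list_path)
        curve.to_frame().to_csv(roc_path, sep="\t", index=False)
    return enriched, curve


def run_benchmark(config: RunConfig) -> benchmarks.BenchmarkReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_path = outdir / f"benchmark_{config.label}.tsv"

    with _Stage("read", [report_path]):
        enriched = io_tables.read_enriched_list(config.enriched_a)
        annot = io_tables.read_annotation(config.annotation)
        off = _read_gene_list(config.off_target) if config.off_target else None
        ref = (
            _read_gene_list(config.reference_standard)
            if config.reference_standard
            else None
        )
    with _Stage("benchmark", [report_path]):
        report = benchmarks.benchmark(
            enriched, annot, off_target=off, reference=ref, quantile=config.quantile
        )
    with _Stage("write", [report_path]):
        report.to_frame().to_csv(report_path, sep="\t", index=False)
    return report


def run_overlap(config: RunConfig) -> overlap.OverlapResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out_path = outdir / "overlap.tsv"
    laminar_path = outdir / "laminar_candidates.tsv"

    with _Stage("read", [out_path, laminar_path]):
        a = io_tables.read_enriched_list(config.enriched_a)
        b = io_tables.read_enriched_list(config.enriched_b)
        annot = io_tables.read_annotation(config.annotation)
        universe = (
            _read_gene_list(config.universe)
            if config.universe
            else a.genes | b.genes
        )
    with _Stage("overlap", [out_path, laminar_path]):
        result = overlap.overlap_analysis(a, b, universe, annot=annot)
        laminar = overlap.laminar_candidates(a, b, annot)
    with _Stage("write", [out_path, laminar_path]):
        result.to_frame().to_csv(out_path, sep="\t", index=False)
        annot_idx = annot.drop_duplicates("gene_id_norm").set_index("gene_id_norm")
        rows = []
        for g in sorted(laminar.all_overlap):
            rows.append(
                {
                    "gene_id": g,
                    "biotype": annot_idx["biotype"].get(g, "unknown"),
                    "is_candidate": g in laminar.candidates,
                    "removed_secretory_mrna": g in laminar.removed_secretory_mrnas,
                }
            )
        pd.DataFrame(
            rows,
            columns=["gene_id", "biotype", "is_candidate", "removed_secretory_mrna"],
        ).to_csv(laminar_path, sep="\t", index=False)
    return result


def run_qpcr(config: RunConfig) -> pd.DataFrame:
    from . import qpcr

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out_path = outdir / "qpcr_yields.tsv"
    with _Stage("read", [out_path]):
        measurements, pairs = qpcr.read_ct_table(config.ct_table)
    with _Stage("yield", [out_path]):
        table = qpcr.yields_from_plate(
            measurements, pairs, reference_target=config.qpcr_reference
        )
    with _Stage("write", [out_path]):
        table.to_csv(out_path, sep="\t", index=False)
    return table
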