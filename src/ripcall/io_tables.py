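"""Reading and writing the delimited-text tables the pipeline consumes.

Expression tables are gene-level FPKM matrices with pre- and post-pulldown
replicate columns plus a differential p-value (CuffDiff-style output is the
model). Annotation tables carry per-gene secretory-prediction flags,
mitochondrial flags and biotypes, read either from a delimited table or from
a GENCODE-dialect GTF. Reference sets are plain one-id-per-line gene lists
anchoring ROC threshold selection.

Gene identifiers are GENCODE-style and may carry a version suffix
("ENSG00000123456.7"); versions are stripped for joins but the original id
is preserved in every output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

_VERSION_RE = re.compile(r"\.\d+$")

SECRETORY_FLAGS = (
    "secretory_phobius",
    "secretory_tmhmm",
    "secretory_signalp",
    "secretory_gocc",
)
SUBMITO_LOCATIONS = ("OMM", "IMM", "matrix", "IMS")


def normalize_gene_id(gene_id: str) -> str:
    """Strip a trailing GENCODE version suffix; idempotent."""
    return _VERSION_RE.sub("", str(gene_id))


@dataclass
class ExpressionTable:
    """Per-gene FPKM replicates before and after pulldown.

    ``data`` has one row per gene with columns ``gene_id``, ``gene_id_norm``,
    ``gene_name``, ``biotype``, ``p_value`` plus the replicate FPKM columns
    named in ``pre_cols`` / ``post_cols``. ``p_value`` is NaN when the
    upstream differential test did not cover the gene.
    """

    data: pd.DataFrame
    pre_cols: list[str]
    post_cols: list[str]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.data["gene_id_norm"])

    def fpkm_pre(self) -> np.ndarray:
        return self.data[self.pre_cols].to_numpy(dtype=float)

    def fpkm_post(self) -> np.ndarray:
        return self.data[self.post_cols].to_numpy(dtype=float)


@dataclass
class ReferenceSets:
    """Disjoint true-positive / false-positive gene sets for one compartment."""

    true_positives: set[str]
    false_positives: set[str]
    label: str = ""

    def __post_init__(self) -> None:
        self.true_positives = {normalize_gene_id(g) for g in self.true_positives}
        self.false_positives = {normalize_gene_id(g) for g in self.false_positives}
        shared = self.true_positives & self.false_positives
        if shared:
            raise ValidationError(
                f"reference sets for {self.label!r} overlap: {sorted(shared)[:5]}"
            )


DEFAULT_DIALECT: dict = {
    "gene_id": "gene_id",
    "gene_name": "gene_name",
    "biotype": "biotype",
    "p_value": "p_value",
    # fpkm_pre / fpkm_post default to every column matching these prefixes
    "fpkm_pre_prefix": "fpkm_pre",
    "fpkm_post_prefix": "fpkm_post",
}


def _resolve_replicate_cols(
    header: Sequence[str], dialect: Mapping, key: str, prefix_key: str
) -> list[str]:
    if key in dialect:
        cols = list(dialect[key])
        missing = [c for c in cols if c not in header]
        if missing:
            raise ConfigurationError(f"mapped column(s) {missing} absent from header")
        return cols
    prefix = dialect.get(prefix_key, DEFAULT_DIALECT[prefix_key])
    cols = [c for c in header if c.startswith(prefix)]
    if not cols:
        raise ConfigurationError(
            f"no columns matching prefix {prefix!r} for {key} found in header"
        )
    return cols


def read_expression_table(
    path: str | Path,
    dialect: Mapping | None = None,
    sep: str = "\t",
) -> ExpressionTable:
    """Read a gene-level expression table.

    ``dialect`` maps logical fields to file columns: ``gene_id`` (required in
    file), optional ``gene_name``, ``biotype``, ``p_value``, and either
    explicit replicate column lists ``fpkm_pre`` / ``fpkm_post`` or prefixes
    ``fpkm_pre_prefix`` / ``fpkm_post_prefix`` (defaults ``fpkm_pre`` /
    ``fpkm_post``).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"expression table not found: {path}")
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)

    raw = pd.read_csv(path, sep=sep, comment="#")
    header = list(raw.columns)

    gid_col = d["gene_id"]
    if gid_col not in header:
        raise ConfigurationError(f"gene id column {gid_col!r} absent from header")
    pre_cols = _resolve_replicate_cols(header, d, "fpkm_pre", "fpkm_pre_prefix")
    post_cols = _resolve_replicate_cols(header, d, "fpkm_post", "fpkm_post_prefix")

    if raw.empty:
        logger.warning("expression table %s has a header but no rows", path)

    data = pd.DataFrame({"gene_id": raw[gid_col].astype(str)})
    dup = data["gene_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate gene_id(s) in {path}: {sorted(set(data['gene_id'][dup]))[:5]}"
        )
    data["gene_id_norm"] = data["gene_id"].map(normalize_gene_id)
    data["gene_name"] = (
        raw[d["gene_name"]].astype(str) if d.get("gene_name") in header else data["gene_id"]
    )
    data["biotype"] = (
        raw[d["biotype"]].astype(str) if d.get("biotype") in header else "unknown"
    )
    if d.get("p_value") in header:
        data["p_value"] = pd.to_numeric(raw[d["p_value"]], errors="coerce")
        bad_p = data["p_value"].dropna()
        if ((bad_p < 0) | (bad_p > 1)).any():
            raise ValidationError(f"p_value outside [0,1] in {path}")
    else:
        data["p_value"] = np.nan

    for col in pre_cols + post_cols:
        vals = pd.to_numeric(raw[col], errors="raise").astype(float)
        neg = np.flatnonzero(vals.to_numpy() < 0)
        if neg.size:
            raise ValidationError(
                f"negative FPKM in column {col!r} of {path}, first at data row {neg[0] + 1}"
            )
        data[col] = vals

    logger.info("read %d genes from %s", len(data), path)
    return ExpressionTable(data=data, pre_cols=pre_cols, post_cols=post_cols)


# ---------------------------------------------------------------------------
# Annotation


def _empty_annotation() -> pd.DataFrame:
    cols = ["gene_id", "gene_id_norm", "biotype", *SECRETORY_FLAGS, "is_mito", "submito_location"]
    return pd.DataFrame(columns=cols)


def read_annotation(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a per-gene annotation table (delimited text or GENCODE GTF).

    Returns a DataFrame with columns ``gene_id``, ``gene_id_norm``,
    ``biotype``, the four secretory flags, ``is_mito`` and
    ``submito_location`` (one of OMM/IMM/matrix/IMS/unknown). Files ending in
    ``.gtf`` are parsed for gene-level ``gene_type`` biotypes; all flags then
    default to false/unknown.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"annotation file not found: {path}")
    if path.suffix.lower() == ".gtf":
        return _read_annotation_gtf(path)

    raw = pd.read_csv(path, sep=sep, comment="#")
    if "gene_id" not in raw.columns:
        raise ConfigurationError(f"annotation table {path} lacks a gene_id column")
    out = pd.DataFrame({"gene_id": raw["gene_id"].astype(str)})
    out["gene_id_norm"] = out["gene_id"].map(normalize_gene_id)
    out["biotype"] = raw["biotype"].astype(str) if "biotype" in raw.columns else "unknown"
    for flag in (*SECRETORY_FLAGS, "is_mito"):
        out[flag] = (
            raw[flag].astype(bool) if flag in raw.columns else False
        )
    if "submito_location" in raw.columns:
        loc = raw["submito_location"].fillna("unknown").astype(str)
        bad = ~loc.isin([*SUBMITO_LOCATIONS, "unknown"])
        if bad.any():
            raise ValidationError(
                f"unknown submito_location value(s): {sorted(set(loc[bad]))}"
            )
        out["submito_location"] = loc
    else:
        out["submito_location"] = "unknown"
    located = out["submito_location"] != "unknown"
    if (located & ~out["is_mito"]).any():
        offenders = out.loc[located & ~out["is_mito"], "gene_id"].tolist()[:5]
        raise ValidationError(
            f"submito_location set but is_mito false for {offenders}"
        )
    return out


def _read_annotation_gtf(path: Path) -> pd.DataFrame:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils reports the offending line itself
        raise ValidationError(f"unparseable GTF {path}: {exc}") from exc

    rows = []
    for gene in db.features_of_type("gene"):
        biotype = (gene.attributes.get("gene_type") or gene.attributes.get("gene_biotype") or ["unknown"])[0]
        rows.append({"gene_id": gene.id, "biotype": biotype})
    out = pd.DataFrame(rows) if rows else _empty_annotation()
    if rows:
        out["gene_id_norm"] = out["gene_id"].map(normalize_gene_id)
        for flag in (*SECRETORY_FLAGS, "is_mito"):
            out[flag] = False
        out["submito_location"] = "unknown"
    logger.info("read %d gene annotations from GTF %s", len(out), path)
    return out


def read_reference_sets(
    tp_path: str | Path, fp_path: str | Path, label: str = ""
) -> ReferenceSets:
    """Read plain-text TP/FP gene lists (one identifier per line, '#' comments)."""

    def _read(p: str | Path) -> set[str]:
        p = Path(p)
        if not p.exists():
            raise ConfigurationError(f"reference set file not found: {p}")
        ids = set()
        for line in p.read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
        return ids

    return ReferenceSets(_read(tp_path), _read(fp_path), label=label)


# ---------------------------------------------------------------------------
# Enriched-list round trip (EnrichedList itself lives in ripcall.enrichment)


def write_enriched_list(enriched, path: str | Path) -> None:
    """Write a called list as TSV with '#' metadata lines.

    Rows are sorted by descending log2 fold change, ties broken by gene_id,
    so repeated runs on the same inputs are byte-identical.
    """
    path = Path(path)
    rec = enriched.records.sort_values(
        ["log2_fc", "gene_id"], ascending=[False, True]
    )
    lines = [
        f"# label={enriched.label}",
        f"# threshold={enriched.threshold!r}",
        f"# alpha={enriched.alpha!r}",
        "\t".join(["gene_id", "biotype", "log2_fc", "mean_pre", "mean_post", "p_value"]),
    ]
    for row in rec.itertuples(index=False):
        lines.append(
            "\t".join(
                [
                    row.gene_id,
                    str(row.biotype),
                    repr(float(row.log2_fc)),
                    repr(float(row.mean_pre)),
                    repr(float(row.mean_post)),
                    "NA" if pd.isna(row.p_value) else repr(float(row.p_value)),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_enriched_list(path: str | Path):
    """Read back a list written by :func:`write_enriched_list`."""
    from .enrichment import EnrichedList

    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if line.startswith("#") and "=" in line:
            k, v = line[1:].split("=", 1)
            meta[k.strip()] = v.strip()
        elif not line.startswith("#"):
            break
    records = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    records["gene_id"] = records["gene_id"].astype(str)
    records["gene_id_norm"] = records["gene_id"].map(normalize_gene_id)
    return EnrichedList(
        label=meta.get("label", ""),
        genes=set(records["gene_id_norm"]),
        threshold=float(meta["threshold"]),
        alpha=float(meta["alpha"]),
        records=records,
    )


def write_reference_set(ids, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")
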