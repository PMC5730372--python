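import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ripcall.io_tables import ExpressionTable, normalize_gene_id

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_records(lfc_by_gene, p_value=0.01, mean_pre=5.0, biotype="protein_coding"):
    """Fold-change record table from {gene_id: log2_fc} for threshold tests."""
    rows = []
    for gid, lfc in lfc_by_gene.items():
        p = p_value[gid] if isinstance(p_value, dict) else p_value
        pre = mean_pre[gid] if isinstance(mean_pre, dict) else mean_pre
        rows.append(
            {
                "gene_id": gid,
                "gene_id_norm": normalize_gene_id(gid),
                "biotype": biotype,
                "p_value": p,
                "mean_pre": pre,
                "mean_post": pre * 2.0**lfc,
                "log2_fc": float(lfc),
            }
        )
    return pd.DataFrame(rows)


def make_expression(pre, post, gene_ids=None, p_values=None, biotypes=None):
    """ExpressionTable from per-gene replicate lists."""
    pre = np.atleast_2d(np.asarray(pre, dtype=float))
    post = np.atleast_2d(np.asarray(post, dtype=float))
    n = pre.shape[0]
    gene_ids = gene_ids or [f"G{i}" for i in range(1, n + 1)]
    data = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_id_norm": [normalize_gene_id(g) for g in gene_ids],
            "gene_name": gene_ids,
            "biotype": biotypes or ["protein_coding"] * n,
            "p_value": p_values if p_values is not None else [0.01] * n,
        }
    )
    pre_cols, post_cols = [], []
    for j in range(pre.shape[1]):
        data[f"fpkm_pre_{j + 1}"] = pre[:, j]
        pre_cols.append(f"fpkm_pre_{j + 1}")
    for j in range(post.shape[1]):
        data[f"fpkm_post_{j + 1}"] = post[:, j]
        post_cols.append(f"fpkm_post_{j + 1}")
    return ExpressionTable(data=data, pre_cols=pre_cols, post_cols=post_cols)


def make_annotation(genes, **columns):
    """Annotation DataFrame; per-gene values given as dicts or broadcast scalars."""
    out = pd.DataFrame(
        {"gene_id": list(genes), "gene_id_norm": [normalize_gene_id(g) for g in genes]}
    )
    defaults = {
        "biotype": "protein_coding",
        "secretory_phobius": False,
        "secretory_tmhmm": False,
        "secretory_signalp": False,
        "secretory_gocc": False,
        "is_mito": False,
        "submito_location": "unknown",
    }
    defaults.update(columns)
    for col, val in defaults.items():
        if isinstance(val, dict):
            out[col] = [val.get(g, False if col.startswith(("secretory", "is_")) else "unknown") for g in genes]
        else:
            out[col] = val
    return out


@pytest.fixture
def small_simulation():
    from ripcall.simulate import SimulationConfig, simulate_expression

    cfg = SimulationConfig(n_genes=1500, seed=7)
    return cfg, *simulate_expression(cfg)
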