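#!/usr/bin/env python
"""Generate the two synthetic pulldown experiments used by steps 02-05.

Writes results/sim/nuclear and results/sim/er, each with expression.tsv,
annotation.tsv, reference_tp/fp.txt and truth.tsv. The ER experiment's
target set is planted to share 40% of the nuclear targets — emulating an
interface population (the nuclear envelope lumen is contiguous with the ER,
and secretory mRNAs are measured both as nuclear pre-mRNA and as mature
ER-bound transcripts) — so the overlap analysis in step 04 has a real signal
to find. Usage: python analysis/01_simulate.py [seed]
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from ripcall.simulate import SimulationConfig, simulate_expression, write_simulation

OUT = Path("results/sim")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
SHARED_TARGET_FRACTION = 0.4


def main() -> None:
    cfg_nuc = SimulationConfig(seed=SEED)
    table_nuc, annot_nuc, refs_nuc, truth_nuc = simulate_expression(cfg_nuc)
    write_simulation(OUT / "nuclear", table_nuc, annot_nuc, refs_nuc, truth_nuc)

    # plant the ER target set: 40% shared with the nuclear targets, the rest
    # drawn from genes outside the nuclear target set
    rng = np.random.default_rng(SEED + 1000)
    n = cfg_nuc.n_genes
    nuc_target_idx = np.flatnonzero(truth_nuc["is_target"].to_numpy())
    other_idx = np.flatnonzero(~truth_nuc["is_target"].to_numpy())
    n_er = int(round(cfg_nuc.fraction_enriched * n))
    n_shared = int(round(SHARED_TARGET_FRACTION * n_er))
    er_idx = np.concatenate(
        [
            rng.choice(nuc_target_idx, n_shared, replace=False),
            rng.choice(other_idx, n_er - n_shared, replace=False),
        ]
    )
    is_target = np.zeros(n, dtype=bool)
    is_target[er_idx] = True
    n_off = int(round(cfg_nuc.fraction_off_target * n))
    off_pool = np.flatnonzero(~is_target)
    is_off = np.zeros(n, dtype=bool)
    is_off[rng.choice(off_pool, n_off, replace=False)] = True
    effect = np.zeros(n)
    effect[is_target] = cfg_nuc.effect_log2 + rng.normal(0, cfg_nuc.effect_jitter_sd, n_er)
    effect[is_off] = cfg_nuc.contaminant_log2 + rng.normal(0, cfg_nuc.effect_jitter_sd, n_off)
    planted = pd.DataFrame(
        {"is_target": is_target, "is_off_target": is_off, "true_log2_effect": effect}
    )

    cfg_er = SimulationConfig(seed=SEED + 1)
    tables_er = simulate_expression(cfg_er, planted=planted)
    write_simulation(OUT / "er", *tables_er)

    shared = is_target & truth_nuc["is_target"].to_numpy()
    print(f"nuclear dataset: {truth_nuc['is_target'].sum()} planted targets")
    print(f"ER dataset:      {int(is_target.sum())} planted targets")
    print(f"targets planted in both compartments: {int(shared.sum())}")
    print(f"wrote {OUT}/nuclear and {OUT}/er")


if __name__ == "__main__":
    main()
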