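"""Reference experiments run on the synthetic atlas.

The partition-robustness experiment mirrors the atlas-scale procedure:
simulate the default atlas, quality-filter it, embed in 50-PC space, select
the top-5% most differentiated cells per lineage as sinks, run partitioned
stationary OT (10 subsets x 10 repeats, epsilon = 0.025, unit-mean cost),
average fates cell-by-cell into the consensus, and compare single subset
runs against the consensus. Reported statistics are the medians over all
single-run comparisons: the fraction of cells sharing the consensus argmax
fate, the Pearson correlation of per-cell maximum fate values, and the
Pearson correlation over all fate entries.
"""
from __future__ import annotations

import numpy as np

from . import fate as fate_mod
from . import qc as qc_mod
from . import simulate as sim
from .preprocess import log_normalize, pca_embed

__all__ = ["partition_robustness"]


def partition_robustness(
    seed: int,
    n_cells: int = 5000,
    n_genes: int = 2000,
    n_subsets: int = 10,
    n_repeats: int = 10,
    epsilon: float = 0.025,
    sink_fraction: float = 0.05,
    n_pcs: int = 50,
) -> dict:
    """Run the full partition-consensus experiment; returns summary stats."""
    cfg = sim.default_config(n_cells=n_cells, n_genes=n_genes, seed=int(seed) % (2**31))
    adata, truth = sim.simulate_root(cfg)

    res = qc_mod.run_copilot(adata.X, adata.var["mito"].to_numpy())
    adata = adata[res.keep_mask].copy()
    truth = truth.loc[adata.obs_names]
    lineages = truth["lineage"].to_numpy()
    keep = lineages != sim.QC_CENTER_LABEL
    adata = adata[keep].copy()
    truth = truth.loc[adata.obs_names]
    lineages = lineages[keep]

    emb = pca_embed(log_normalize(adata.X), n_comps=n_pcs, random_state=int(seed) % (2**31))
    growth = sim.simulate_growth_rates(truth, {l.name: l.growth_rate for l in cfg.lineages})
    sink_mask, sink_classes = fate_mod.select_sinks(
        truth["pseudotime"].to_numpy(), lineages, sink_fraction
    )
    params = fate_mod.OTParams(epsilon=epsilon, sink_fraction=sink_fraction)
    consensus, runs, _ = fate_mod.consensus_fates(
        emb, growth, sink_mask, sink_classes, params,
        n_subsets=n_subsets, n_repeats=n_repeats, seed=int(seed) % (2**31),
    )

    Fc = consensus.to_numpy()
    agree, r_max, r_all = [], [], []
    for r in runs:
        sub = r["cells"]
        Fs = r["fates"].to_numpy()
        Fcc = Fc[sub]
        agree.append(float(np.mean(Fs.argmax(1) == Fcc.argmax(1))))
        r_max.append(float(np.corrcoef(Fs.max(1), Fcc.max(1))[0, 1]))
        r_all.append(float(np.corrcoef(Fs.ravel(), Fcc.ravel())[0, 1]))

    return {
        "argmax_agreement_pct": 100.0 * float(np.median(agree)),
        "max_fate_correlation": float(np.median(r_max)),
        "all_fate_correlation": float(np.median(r_all)),
        "n_cells": int(adata.n_obs),
        "n_runs": len(runs),
        "consensus": consensus,
        "truth": truth,
        "lineages": lineages,
    }
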