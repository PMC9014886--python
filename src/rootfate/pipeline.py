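"""End-to-end pipeline driver: simulate/ingest -> QC -> annotate ->
pseudotime -> fates -> regulators -> abundance, with every intermediate
written as TSV plus a per-stage log of cell/gene counts."""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import fate as fate_mod
from . import qc as qc_mod
from . import regulators as reg_mod
from . import simulate as sim
from . import stats as stats_mod
from .io import read_10x_mtx, write_10x_mtx
from .preprocess import log_normalize, pca_embed
from .pseudotime import ConsensusPseudotime

log = logging.getLogger("rootfate")

_KNOWN_KEYS = {
    "seed", "input_dir", "out_dir", "simulate", "n_cells", "n_genes",
    "dying_fraction", "run_qc", "run_annotate", "run_pseudotime",
    "run_fates", "run_regulators", "run_abundance", "mito_threshold",
    "top_umi_fraction", "iterate_qc", "epsilon", "sink_fraction",
    "n_subsets", "n_repeats", "n_pcs", "contrast",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    input_dir: str | None = None  # None -> simulate
    out_dir: str = "rootfate_out"
    simulate: bool = True
    n_cells: int = 1000
    n_genes: int = 2000
    dying_fraction: float = 0.10
    run_qc: bool = True
    run_annotate: bool = True
    run_pseudotime: bool = True
    run_fates: bool = True
    run_regulators: bool = True
    run_abundance: bool = False
    mito_threshold: float = 0.05
    top_umi_fraction: float = 0.01
    iterate_qc: bool = False
    epsilon: float = 0.025
    sink_fraction: float = 0.05
    n_subsets: int = 1
    n_repeats: int = 1
    n_pcs: int = 50
    contrast: tuple[str, str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrast" in raw and raw["contrast"] is not None:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if d["contrast"] is not None:
            d["contrast"] = list(d["contrast"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stage_log = []

    def record(stage, **info):
        stage_log.append({"stage": stage, **info})
        log.info("%s: %s", stage, info)

    # --- ingest / simulate
    if config.simulate or config.input_dir is None:
        cfg = sim.default_config(n_cells=config.n_cells, n_genes=config.n_genes,
                                 dying_fraction=config.dying_fraction, seed=config.seed)
        adata, truth = sim.simulate_root(cfg)
        write_10x_mtx(adata, out / "counts")
        truth.to_csv(out / "truth.tsv", sep="\t")
    else:
        adata = read_10x_mtx(config.input_dir)
        truth = None
    record("ingest", n_cells=adata.n_obs, n_genes=adata.n_vars)

    # --- QC
    if config.run_qc:
        mito = (adata.var["mito"].to_numpy() if "mito" in adata.var
                else np.char.startswith(adata.var_names.to_numpy().astype(str), "MT"))
        params = qc_mod.QCParams(config.mito_threshold, config.top_umi_fraction,
                                 config.iterate_qc)
        res = qc_mod.run_copilot(adata.X, mito, params, barcodes=adata.obs_names)
        pd.DataFrame({"barcode": adata.obs_names, "status": res.status,
                      "total_umi": res.total_umi,
                      "mito_fraction": res.mito_fraction}).to_csv(
            out / "qc_report.tsv", sep="\t", index=False)
        adata = adata[res.keep_mask, res.kept_genes].copy()
        record("qc", kept=adata.n_obs, boundary=res.boundary)

    Xn = log_normalize(adata.X)
    emb = pca_embed(Xn, n_comps=config.n_pcs, random_state=config.seed)

    # --- annotation (consensus over four evidence sources on synthetic refs)
    if config.run_annotate and truth is not None:
        truth_kept = truth.loc[adata.obs_names].copy()
        # reference profiles need >=10 good cells per label; tiny anchor
        # populations are folded out of the reference set
        counts_per = truth_kept.loc[truth_kept["quality"] == "good", "lineage"].value_counts()
        big = set(counts_per[counts_per >= 10].index)
        truth_refs = truth_kept[truth_kept["lineage"].isin(big)]
        adata_refs = adata[truth_kept["lineage"].isin(big).to_numpy()]
        refs = sim.simulate_reference_profiles(adata_refs, truth_refs, "lineage")
        markers = {
            g: l for g, l in zip(adata.var_names, adata.var["marker_lineage"])
            if l
        }
        spec_ann = ann.ICIAnnotator(seed=config.seed).fit(refs)
        ev = [
            spec_ann.annotate(adata.X, adata.var_names),
            ann.correlation_annotate(adata.X, adata.var_names, refs,
                                     n_hvg=min(181, adata.n_vars)),
            ann.neighborhood_enrichment(emb[:, :10], Xn, adata.var_names, markers,
                                        seed=config.seed),
            ann.microcluster_zscore_annotate(adata.X, adata.var_names, markers,
                                             max(2, adata.n_obs // 35),
                                             seed=config.seed),
        ]
        consensus = ann.combine_annotations(ev, adata.X, adata.var_names,
                                            seed=config.seed)
        table = pd.DataFrame({
            "barcode": adata.obs_names,
            "ici": ev[0]["label"].to_numpy(),
            "correlation": ev[1]["label"].to_numpy(),
            "neighborhood": ev[2]["label"].to_numpy(),
            "microcluster": ev[3]["label"].to_numpy(),
            "consensus": consensus["label"].to_numpy(),
            "agreement": consensus["agreement"].to_numpy(),
            "confidence": consensus["confidence"].to_numpy(),
        })
        table.to_csv(out / "annotation.tsv", sep="\t", index=False)
        lineages = consensus["label"].to_numpy()
        record("annotate", n_labels=len(set(lineages)))
    else:
        lineages = None

    # --- pseudotime
    pt_res = None
    if config.run_pseudotime and lineages is not None:
        cp = ConsensusPseudotime(seed=config.seed)
        pt_res = cp.fit_transform(adata.X, lineages)
        pt_res.insert(0, "barcode", adata.obs_names)
        pt_res.to_csv(out / "pseudotime.tsv", sep="\t", index=False)
        record("pseudotime", n_binned=int(pt_res["consensus"].notna().sum()))

    # --- fates
    fates = None
    if config.run_fates and pt_res is not None and truth is not None:
        ok = pt_res["consensus"].notna().to_numpy()
        rates = {l: 0.205 for l in set(lineages)}
        growth = np.full(adata.n_obs, 0.205)
        sink_mask, sink_classes = fate_mod.select_sinks(
            np.nan_to_num(pt_res["consensus"].to_numpy(), nan=-1.0)[ok],
            lineages[ok], config.sink_fraction)
        fates_df, _, report = fate_mod.consensus_fates(
            emb[ok], growth[ok], sink_mask, sink_classes,
            fate_mod.OTParams(epsilon=config.epsilon,
                              sink_fraction=config.sink_fraction),
            n_subsets=config.n_subsets, n_repeats=config.n_repeats,
            seed=config.seed)
        labels, maxp = fate_mod.max_fate(fates_df)
        fates_out = fates_df.copy()
        fates_out.insert(0, "barcode", adata.obs_names[ok])
        fates_out["argmax"] = labels
        fates_out["max_probability"] = maxp
        fates_out.to_csv(out / "fates.tsv", sep="\t", index=False)
        fates = (fates_df, ok)
        record("fates", **{k: v for k, v in report.items() if np.isscalar(v)})

    # --- regulators
    if config.run_regulators and fates is not None and "tf" in adata.var:
        fates_df, ok = fates
        stages = sim.stage_of_pseudotime(
            np.nan_to_num(pt_res["consensus"].to_numpy()[ok], nan=0.0))
        res = reg_mod.rank_regulators(adata.X[ok], adata.var_names,
                                      adata.var["tf"].to_numpy(), fates_df,
                                      stages, min_cells=50)
        for (stage, lin), r in res.items():
            r["ranking"].to_csv(out / f"regulators_{stage}_{lin}.tsv",
                                sep="\t", index=False)
        record("regulators", n_fits=len(res))

    # --- abundance
    if config.run_abundance and lineages is not None and truth is not None:
        truth_kept = truth.loc[adata.obs_names]
        tab = stats_mod.label_abundance_counts(lineages, truth_kept["sample_id"])
        meta = truth_kept.groupby("sample_id").agg(
            genotype=("genotype", "first"), batch=("batch", "first"))
        if config.contrast:
            res = stats_mod.nb_glm_abundance(tab, meta, config.contrast)
            res.to_csv(out / "abundance.tsv", sep="\t")
            record("abundance", n_sig=int((res["fdr"] < 0.05).sum()))

    pd.DataFrame(stage_log).to_csv(out / "pipeline_log.tsv", sep="\t", index=False)
    return out
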