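"""Synthetic root-atlas scRNA-seq generator with known ground truth.

Emulates the statistical structure of an organ-scale *Arabidopsis* root tip
atlas: several branching lineages sharing an undifferentiated origin, a
continuous per-lineage pseudotime axis, lineage-restricted identity markers,
stage-restricted (pseudotime-windowed) genes, mitochondrial genes, a planted
population of dying/low-quality cells with elevated mitochondrial share,
multiple samples/batches, and genotypes with depleted cell-type abundances.

Counts follow a negative-binomial (Gamma-Poisson) model with a dispersion
shared across genes, which keeps every recovery test analytically checkable.
Generation is fully deterministic given ``SimConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .preprocess import log_normalize

__all__ = [
    "LineageSpec",
    "SampleSpec",
    "SimConfig",
    "default_config",
    "simulate_root",
    "simulate_reference_profiles",
    "simulate_growth_rates",
    "stage_of_pseudotime",
]

QC_CENTER_LABEL = "quiescent_center"
STAGE_NAMES = ("meristem", "elongation", "maturation")


class SimConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class LineageSpec:
    name: str
    abundance: float
    n_markers: int = 25
    marker_log2fc: float = 4.0
    growth_rate: float = 0.205  # per day


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    genotype: str = "wt"
    batch: str = "b0"


@dataclass(frozen=True)
class SimConfig:
    n_cells: int = 5000
    n_genes: int = 2000
    lineages: tuple[LineageSpec, ...] = ()
    n_mito_genes: int = 20
    dying_fraction: float = 0.10
    dying_mito_fraction: float = 0.08
    samples: tuple[SampleSpec, ...] = (SampleSpec("sc_1"),)
    depletion: dict = field(default_factory=dict)  # genotype -> {lineage: multiplier}
    nb_dispersion: float = 10.0
    depth_mean: float = 10000.0
    seed: int = 0
    # secondary structure, defaults are part of the study conditions
    n_stage_genes_per_lineage: int = 10
    stage_log2fc: float = 4.0
    n_cellcycle_genes: int = 40
    qc_center_fraction: float = 0.004
    n_qc_center_markers: int = 20
    n_stress_genes: int = 80
    stress_log2fc: float = 5.0
    good_mito_fraction: float = 0.015
    dying_depth_factor: float = 0.35
    depth_sigma: float = 0.35  # log-normal sigma of library size
    batch_lfc_sd: float = 0.05
    early_gene_fraction: float = 0.30
    late_gene_fraction: float = 0.10
    lineage_lfc_sd: float = 0.6  # log-sd of per-lineage loadings on baseline genes
    lineage_ring_mix: float = 0.0  # loading share drawn from ring-adjacent lineages
    # commitment ramp: young cells share an undifferentiated expression state;
    # lineage-distinguishing loadings and stage programs fade in with maturity
    commitment_floor: float = 0.08
    commitment_midpoint: float = 0.25
    commitment_tau: float = 0.12
    tf_markers_per_lineage: int = 10
    n_extra_tf_genes: int = 100
    doublet_fraction: float = 0.0  # mixing option, off by default

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise SimConfigError("n_cells and n_genes must be positive")
        if not self.lineages:
            raise SimConfigError("at least one lineage is required")
        tot = sum(l.abundance for l in self.lineages)
        if abs(tot - 1.0) > 1e-9:
            raise SimConfigError(f"lineage abundances must sum to 1, got {tot!r}")
        if not (0 <= self.dying_fraction < 1):
            raise SimConfigError("dying_fraction must be in [0, 1)")
        if self.dying_fraction > 0 and self.dying_mito_fraction <= 0.05:
            raise SimConfigError("dying_mito_fraction must exceed 0.05")
        for g, mult in self.depletion.items():
            for lin, m in mult.items():
                if m < 0:
                    raise SimConfigError(f"depletion multiplier for {g}/{lin} is negative")
        if self.nb_dispersion <= 0 or self.depth_mean <= 0:
            raise SimConfigError("nb_dispersion and depth_mean must be positive")
        n_special = (
            self.n_mito_genes
            + sum(l.n_markers for l in self.lineages)
            + self.n_stage_genes_per_lineage * len(self.lineages)
            + self.n_cellcycle_genes
            + self.n_qc_center_markers
            + self.n_stress_genes
        )
        if self.n_genes < n_special:
            raise SimConfigError(
                f"n_genes={self.n_genes} smaller than markers+mito+structural genes ({n_special})"
            )


_DEFAULT_LINEAGES = (
    LineageSpec("atrichoblast", 0.12, growth_rate=0.21),
    LineageSpec("columella", 0.10, growth_rate=0.19),
    LineageSpec("cortex", 0.16, growth_rate=0.22),
    LineageSpec("endodermis", 0.14, growth_rate=0.20),
    LineageSpec("lateral_root_cap", 0.12, growth_rate=0.19),
    LineageSpec("pericycle", 0.12, growth_rate=0.21),
    LineageSpec("trichoblast", 0.14, growth_rate=0.22),
    LineageSpec("xylem", 0.10, growth_rate=0.18),
)


def default_config(**overrides) -> SimConfig:
    """Default synthetic atlas: 5,000 cells, 8 root lineages, 10% dying cells."""
    base = dict(
        lineages=_DEFAULT_LINEAGES,
        samples=(
            SampleSpec("sc_1", "wt", "b0"),
            SampleSpec("sc_2", "wt", "b0"),
            SampleSpec("sc_3", "wt", "b1"),
            SampleSpec("sc_4", "wt", "b1"),
        ),
    )
    base.update(overrides)
    cfg = SimConfig(**base)
    cfg.validate()
    return cfg


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def stage_of_pseudotime(t: np.ndarray) -> np.ndarray:
    """Coarse developmental stage from pseudotime thirds."""
    out = np.full(len(t), STAGE_NAMES[0], dtype=object)
    out[np.asarray(t) >= 1 / 3] = STAGE_NAMES[1]
    out[np.asarray(t) >= 2 / 3] = STAGE_NAMES[2]
    return out


def _build_gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign gene roles. Order: mito | identity markers | stage genes |
    cell-cycle | qc-center markers | baseline (early/late/flat)."""
    n = cfg.n_genes
    lineage_names = [l.name for l in cfg.lineages]
    role = np.full(n, "baseline", dtype=object)
    marker_lineage = np.full(n, "", dtype=object)
    stage_lineage = np.full(n, "", dtype=object)
    onset = np.full(n, np.nan)  # logistic midpoint for windowed genes
    direction = np.zeros(n)  # +1 rising with time, -1 falling
    mito = np.zeros(n, dtype=bool)
    tf = np.zeros(n, dtype=bool)

    i = 0
    mito[i : i + cfg.n_mito_genes] = True
    role[i : i + cfg.n_mito_genes] = "mito"
    i += cfg.n_mito_genes

    for spec in cfg.lineages:
        sl = slice(i, i + spec.n_markers)
        role[sl] = "marker"
        marker_lineage[sl] = spec.name
        # early-onset ramps: markers switch on as cells leave the
        # undifferentiated pool, staying informative for ~85% of the lineage
        onset[sl] = rng.uniform(0.05, 0.25, spec.n_markers)
        direction[sl] = 1.0
        tf[i : i + min(cfg.tf_markers_per_lineage, spec.n_markers)] = True
        i += spec.n_markers

    for spec in cfg.lineages:
        sl = slice(i, i + cfg.n_stage_genes_per_lineage)
        role[sl] = "stage"
        stage_lineage[sl] = spec.name
        onset[sl] = rng.uniform(0.1, 0.9, cfg.n_stage_genes_per_lineage)
        direction[sl] = rng.choice([-1.0, 1.0], cfg.n_stage_genes_per_lineage)
        i += cfg.n_stage_genes_per_lineage

    sl = slice(i, i + cfg.n_cellcycle_genes)
    role[sl] = "cellcycle"
    onset[sl] = 0.30
    direction[sl] = -1.0
    i += cfg.n_cellcycle_genes

    sl = slice(i, i + cfg.n_qc_center_markers)
    role[sl] = "qc_center"
    i += cfg.n_qc_center_markers

    # degradation/stress signature of dying cells
    sl = slice(i, i + cfg.n_stress_genes)
    role[sl] = "stress"
    i += cfg.n_stress_genes

    n_base = n - i
    n_early = int(round(cfg.early_gene_fraction * n_base))
    n_late = int(round(cfg.late_gene_fraction * n_base))
    sl = slice(i, i + n_early)
    role[sl] = "early"
    onset[sl] = rng.uniform(0.2, 0.8, n_early)
    direction[sl] = -1.0
    sl = slice(i + n_early, i + n_early + n_late)
    role[sl] = "late"
    onset[sl] = rng.uniform(0.2, 0.8, n_late)
    direction[sl] = 1.0
    # extra TF flags on flat baseline genes (uninformative TFs)
    flat_idx = np.arange(i + n_early + n_late, n)
    n_extra = min(cfg.n_extra_tf_genes, len(flat_idx))
    tf[rng.choice(flat_idx, n_extra, replace=False)] = True

    names = np.array(
        [f"MT{j:04d}" if mito[j] else f"G{j:05d}" for j in range(n)], dtype=object
    )
    return pd.DataFrame(
        {
            "gene_id": names,
            "role": role,
            "marker_lineage": marker_lineage,
            "stage_lineage": stage_lineage,
            "onset": onset,
            "direction": direction,
            "mito": mito,
            "tf": tf,
        }
    ).set_index("gene_id")


def _assign_cells(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lineage_names = [l.name for l in cfg.lineages]
    abund = np.array([l.abundance for l in cfg.lineages])
    n = cfg.n_cells
    sample_ix = rng.integers(0, len(cfg.samples), n)
    samples = np.array([cfg.samples[k].sample_id for k in sample_ix], dtype=object)
    genotypes = np.array([cfg.samples[k].genotype for k in sample_ix], dtype=object)
    batches = np.array([cfg.samples[k].batch for k in sample_ix], dtype=object)

    lineage = np.empty(n, dtype=object)
    for k, spec in enumerate(cfg.samples):
        mask = sample_ix == k
        mult = np.array(
            [cfg.depletion.get(spec.genotype, {}).get(name, 1.0) for name in lineage_names]
        )
        p = abund * mult
        p = p / p.sum()
        lineage[mask] = rng.choice(lineage_names, size=mask.sum(), p=p)

    is_qc = rng.random(n) < cfg.qc_center_fraction
    lineage[is_qc] = QC_CENTER_LABEL
    pt = rng.uniform(0.0, 1.0, n)
    pt[is_qc] = rng.uniform(0.0, 0.05, int(is_qc.sum()))
    quality = np.where(rng.random(n) < cfg.dying_fraction, "dying", "good")

    return pd.DataFrame(
        {
            "cell_id": [f"cell_{j:05d}" for j in range(n)],
            "lineage": lineage,
            "pseudotime": pt,
            "stage": stage_of_pseudotime(pt),
            "quality": quality,
            "sample_id": samples,
            "genotype": genotypes,
            "batch": batches,
        }
    ).set_index("cell_id")


def _expected_rates(
    cfg: SimConfig, genes: pd.DataFrame, cells: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Relative per-cell expression rates (cells x genes), rows sum to 1."""
    n_cells, n_genes = len(cells), len(genes)
    base = np.exp(rng.normal(0.0, 1.0, n_genes))
    special = genes["role"].isin(["marker", "stage", "cellcycle", "qc_center", "stress"]).to_numpy()
    # restricted genes: low off-state, moderate between-gene spread so every
    # marker is well expressed when on
    base[special] = 0.25 * np.exp(rng.normal(0.3, 0.5, int(special.sum())))
    mito = genes["mito"].to_numpy()

    t = cells["pseudotime"].to_numpy()[:, None]
    onset = genes["onset"].to_numpy()[None, :]
    direction = genes["direction"].to_numpy()[None, :]
    lineage = cells["lineage"].to_numpy()
    is_qc_cell = lineage == QC_CENTER_LABEL

    R = np.tile(base, (n_cells, 1))

    role = genes["role"].to_numpy()
    # identity markers: soft logistic ramp, mostly on within own lineage
    midx = np.where(role == "marker")[0]
    if len(midx):
        own = lineage[:, None] == genes["marker_lineage"].to_numpy()[None, midx]
        lfc = np.array(
            [next(l.marker_log2fc for l in cfg.lineages if l.name == ml) for ml in genes["marker_lineage"].to_numpy()[midx]]
        )
        w = _logistic((t - onset[:, midx]) / 0.07)
        R[:, midx] *= np.where(own, 1.0 + (2.0 ** lfc - 1.0)[None, :] * w, 1.0)
    commit = cfg.commitment_floor + (1 - cfg.commitment_floor) * _logistic(
        (t - cfg.commitment_midpoint) / cfg.commitment_tau
    )  # (n_cells, 1)
    # stage genes: sharp on/off windows within own lineage, fading in with
    # commitment
    sidx = np.where(role == "stage")[0]
    if len(sidx):
        own = lineage[:, None] == genes["stage_lineage"].to_numpy()[None, sidx]
        w = _logistic(direction[:, sidx] * (t - onset[:, sidx]) / 0.06)
        R[:, sidx] *= np.where(own, 2.0 ** (cfg.stage_log2fc * w * commit), 1.0)
    # cell-cycle genes: high in young cells of ordinary lineages, off in QC-center
    cidx = np.where(role == "cellcycle")[0]
    if len(cidx):
        w = _logistic(-(t - onset[:, cidx]) / 0.08)
        R[:, cidx] *= (2.0 ** 2.5) * w
        R[np.ix_(is_qc_cell, cidx)] *= 0.05
    # QC-center markers
    qidx = np.where(role == "qc_center")[0]
    if len(qidx):
        R[np.ix_(is_qc_cell, qidx)] *= 2.0 ** 4.0
    # stress/degradation program of dying cells
    stidx = np.where(role == "stress")[0]
    dying_cells = (cells["quality"] == "dying").to_numpy()
    if len(stidx) and dying_cells.any():
        R[np.ix_(dying_cells, stidx)] *= 2.0 ** cfg.stress_log2fc
    # early/late baseline waves (gene-diversity decay along maturation)
    for r, amp in (("early", 1.0), ("late", 1.0)):
        idx = np.where(role == r)[0]
        if len(idx):
            w = amp * _logistic(direction[:, idx] * (t - onset[:, idx]) / 0.10)
            R[:, idx] *= 0.05 + 0.95 * w

    # broad cross-lineage expression differences: real cell types differ in
    # thousands of genes, not just canonical markers
    if cfg.lineage_lfc_sd > 0:
        base_roles = np.isin(role, ["baseline", "early", "late"])
        all_lineages = [l.name for l in cfg.lineages] + [QC_CENTER_LABEL]
        z = rng.normal(0.0, 1.0, (len(all_lineages), n_genes))
        # orthogonalize the lineage programs so every pair of tissues is
        # equally distinct (no chance near-duplicate programs)
        q, _ = np.linalg.qr(z.T)
        z = q.T * np.sqrt(n_genes)
        if cfg.lineage_ring_mix > 0:
            # optional radial organization: adjacent lineages share part of
            # their program
            w = cfg.lineage_ring_mix
            nl = len(cfg.lineages)
            zr = z.copy()
            for k in range(nl):
                zr[k] = (1 - w) * z[k] + (w / 2) * (z[(k - 1) % nl] + z[(k + 1) % nl])
            z = zr / np.sqrt((1 - w) ** 2 + w ** 2 / 2)
        loadings = np.exp(cfg.lineage_lfc_sd * z)
        lin_ix = {name: k for k, name in enumerate(all_lineages)}
        cell_lin = np.array([lin_ix[l] for l in lineage])
        L = loadings[np.ix_(cell_lin, np.where(base_roles)[0])]
        R[:, base_roles] *= np.exp(np.log(L) * commit)

    # batch effect: mild per-batch gene factors
    if cfg.batch_lfc_sd > 0:
        batches = sorted(set(cells["batch"]))
        for b in batches:
            fac = np.exp(rng.normal(0.0, cfg.batch_lfc_sd, n_genes))
            R[cells["batch"].to_numpy() == b] *= fac[None, :]

    # mitochondrial share: exact expected share per cell (good vs dying)
    dying = (cells["quality"] == "dying").to_numpy()
    share = np.where(dying, cfg.dying_mito_fraction, cfg.good_mito_fraction)
    non_mito_sum = R[:, ~mito].sum(axis=1)
    mito_base = base[mito]
    mito_profile = mito_base / mito_base.sum()
    R[:, mito] = (share * non_mito_sum / (1.0 - share))[:, None] * mito_profile[None, :]

    R /= R.sum(axis=1, keepdims=True)
    return R


def simulate_root(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Generate the synthetic atlas.

    Returns an AnnData (cells x genes, raw integer counts in ``.X``; truth in
    ``.obs`` and gene roles in ``.var``) and the per-cell truth table
    (identical to ``.obs``) for use as the recovery oracle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _build_gene_table(config, rng)
    cells = _assign_cells(config, rng)
    R = _expected_rates(config, genes, cells, rng)

    depth = rng.lognormal(
        mean=np.log(config.depth_mean) - config.depth_sigma**2 / 2,
        sigma=config.depth_sigma,
        size=config.n_cells,
    )
    dying = (cells["quality"] == "dying").to_numpy()
    depth[dying] *= config.dying_depth_factor

    mu = R * depth[:, None]
    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int32)

    if config.doublet_fraction > 0:
        n_dbl = int(round(config.doublet_fraction * config.n_cells))
        if n_dbl:
            donors = rng.integers(0, config.n_cells, n_dbl)
            hosts = rng.choice(config.n_cells, n_dbl, replace=False)
            counts[hosts] += counts[donors]
            cells.iloc[hosts, cells.columns.get_loc("quality")] = "doublet"

    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=cells.copy(),
        var=genes.copy(),
    )
    return adata, cells.copy()


def simulate_reference_profiles(
    adata: ad.AnnData, truth: pd.DataFrame, label_key: str = "lineage"
) -> pd.DataFrame:
    """Mean log-normalized expression per label over good cells (genes x labels).

    Stands in for the FACS/microarray whole-transcriptome reference profiles
    used for correlation annotation and ICI spec tables.
    """
    if label_key not in ("lineage", "stage"):
        raise ValueError("label_key must be 'lineage' or 'stage'")
    labels = truth[label_key].to_numpy()
    good = (truth["quality"] == "good").to_numpy()
    Xn = log_normalize(adata.X)
    cols = {}
    for lab in sorted(set(labels)):
        mask = good & (labels == lab)
        if mask.sum() < 10:
            raise ValueError(f"label {lab!r} has fewer than 10 good cells ({int(mask.sum())})")
        cols[lab] = np.asarray(Xn[mask].mean(axis=0)).ravel()
    return pd.DataFrame(cols, index=adata.var_names)


def simulate_growth_rates(truth: pd.DataFrame, lineage_rates: dict) -> np.ndarray:
    """Per-cell growth rate: each cell inherits its lineage's rate (per day)."""
    lineage = truth["lineage"].to_numpy()
    missing = sorted(set(lineage) - set(lineage_rates))
    if missing:
        raise ValueError(f"no growth rate for lineages: {missing}")
    rates = np.array([lineage_rates[l] for l in lineage], dtype=float)
    if np.any(rates <= 0):
        raise ValueError("growth rates must be strictly positive")
    return rates
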