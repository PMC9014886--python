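"""Differential cell-type abundance and marker/DE discovery.

Abundance: per-sample cell counts per label are modeled with a log-linear
negative-binomial GLM (offset = log total cells per sample, genotype effect,
batch blocking factor); the genotype coefficient is tested per label with a
likelihood-ratio test and BH-adjusted across labels. Dispersion is a
method-of-moments estimate from an initial Poisson fit.

Markers: one-vs-rest Wilcoxon rank-sum markers with adjusted p < 0.05,
average logFC > 3 and pct.diff > 0.4 (multi-label genes are reassigned to
the label with the highest logFC); ROC markers across pseudotime bins with
a log2FC >= 1 / pct.diff >= 0.25 prefilter and AUC > 0.75 retention;
Spearman correlation with consensus time re-ranks dynamic genes.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.stats import chi2, mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .preprocess import log_normalize

__all__ = [
    "label_abundance_counts",
    "nb_glm_abundance",
    "roc_auc_scores",
    "roc_bin_markers",
    "wilcoxon_markers",
    "spearman_time_rank",
    "significance_tier",
]


def significance_tier(fdr: float) -> str:
    if fdr < 0.001:
        return "***"
    if fdr < 0.01:
        return "**"
    if fdr < 0.05:
        return "*"
    return ""


def label_abundance_counts(labels, sample_ids, all_labels=None, all_samples=None) -> pd.DataFrame:
    """Samples x labels contingency counts, zero-filled for absent pairs."""
    labels = np.asarray(labels, dtype=object)
    sample_ids = np.asarray(sample_ids, dtype=object)
    tab = pd.crosstab(pd.Series(sample_ids, name="sample"), pd.Series(labels, name="label"))
    if all_labels is not None:
        tab = tab.reindex(columns=list(all_labels), fill_value=0)
    if all_samples is not None:
        tab = tab.reindex(index=list(all_samples), fill_value=0)
    return tab.astype(int)


def _nb_dispersion_mom(y, mu, n_params):
    """Degrees-of-freedom-corrected moment NB2 dispersion: var = mu + a mu^2.

    Average of the per-observation moment estimates, divided by the residual
    degrees of freedom; without the df correction the estimate is biased low
    and the downstream likelihood-ratio test becomes anticonservative.
    """
    df = max(len(y) - n_params, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = ((y - mu) ** 2 - mu) / mu**2
    return float(np.clip(np.nansum(terms) / df, 1e-8, 100.0))


def nb_glm_abundance(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    blocking: str | None = "batch",
) -> pd.DataFrame:
    """Per-label NB GLM test of a genotype contrast (mutant vs reference).

    ``table``: samples x labels counts; ``meta``: per-sample frame with at
    least a ``genotype`` column (and the blocking column when requested).
    Returns per label: log2 fold-change (mutant/reference), raw p from the
    likelihood-ratio test, BH FDR, significance tier, and a separation flag
    for labels observed in only one genotype (fitted with a 0.5 continuity
    correction).
    """
    mutant, ref = contrast
    meta = meta.loc[table.index]
    sel = meta["genotype"].isin([mutant, ref])
    table = table.loc[sel]
    meta = meta.loc[sel]
    for g in (mutant, ref):
        if (meta["genotype"] == g).sum() < 2:
            raise ValueError(f"need at least two samples of genotype {g!r}")

    geno = (meta["genotype"] == mutant).astype(float).to_numpy()
    design = pd.DataFrame({"intercept": 1.0, "genotype": geno}, index=table.index)
    if blocking is not None and blocking in meta and meta[blocking].nunique() > 1:
        dummies = pd.get_dummies(meta[blocking], prefix=blocking, drop_first=True)
        design = pd.concat([design, dummies.astype(float)], axis=1)
    offset = np.log(table.sum(axis=1).to_numpy().astype(float))

    Xf = design.to_numpy(dtype=float)
    Xr = design.drop(columns="genotype").to_numpy(dtype=float)

    # common dispersion pooled across labels (a per-label moment estimate
    # from 2x(samples/genotype) observations is too noisy to keep the test
    # calibrated)
    alphas = []
    for label in table.columns:
        y = table[label].to_numpy(dtype=float)
        try:
            pois = sm.GLM(y + 0.5 * (y.sum() == 0), Xf,
                          family=sm.families.Poisson(), offset=offset).fit()
            alphas.append(_nb_dispersion_mom(y, pois.fittedvalues, Xf.shape[1]))
        except Exception:
            pass
    alpha = float(np.mean(alphas)) if alphas else 1e-8

    rows = []
    for label in table.columns:
        y = table[label].to_numpy(dtype=float)
        separated = (y[geno == 1].sum() == 0) != (y[geno == 0].sum() == 0)
        yy = y + 0.5 if separated else y
        try:
            fam = sm.families.NegativeBinomial(alpha=alpha)
            full = sm.GLM(yy, Xf, family=fam, offset=offset).fit()
            red = sm.GLM(yy, Xr, family=fam, offset=offset).fit()
            lr = 2.0 * (full.llf - red.llf)
            p = float(chi2.sf(max(lr, 0.0), df=1))
            coef = float(full.params[1])
        except Exception as e:  # singular fits on degenerate labels
            warnings.warn(f"GLM failed for label {label!r}: {e}")
            coef, p = np.nan, 1.0
        rows.append({"label": label, "log2fc": coef / np.log(2), "p_value": p,
                     "separated": bool(separated)})
    out = pd.DataFrame(rows).set_index("label")
    out["fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["tier"] = [significance_tier(q) for q in out["fdr"]]
    return out


# ---------------------------------------------------------------------------
# markers

def _dense(X):
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def roc_auc_scores(expr_group: np.ndarray, expr_rest: np.ndarray) -> np.ndarray:
    """One-vs-rest AUC per gene (columns) via the rank-sum identity."""
    n1, n2 = expr_group.shape[0], expr_rest.shape[0]
    both = np.concatenate([expr_group, expr_rest], axis=0)
    ranks = np.apply_along_axis(rankdata, 0, both)
    r1 = ranks[:n1].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n2)


def _pct_detect(M: np.ndarray) -> np.ndarray:
    return (M > 0).mean(axis=0)


def _avg_log2fc(M1: np.ndarray, M2: np.ndarray) -> np.ndarray:
    # means on the count scale of log-normalized data, pseudocount 1
    return np.log2(np.expm1(M1).mean(axis=0) + 1) - np.log2(np.expm1(M2).mean(axis=0) + 1)


def roc_bin_markers(
    expr,
    gene_names,
    group_mask,
    lineage_mask=None,
    min_log2fc: float = 1.0,
    min_pct_diff: float = 0.25,
    min_auc: float = 0.75,
) -> pd.DataFrame:
    """ROC markers of a (cell type, pseudotime bin) group vs its lineage.

    ``expr`` is log-normalized cells x genes; the comparison set is the rest
    of the lineage's cells. Genes pass a log2FC / pct.diff prefilter, are
    scored by one-vs-rest AUC, retained above ``min_auc``, and ranked by
    (AUC, pct.diff, log2FC) descending with a lexicographic gene tie-break.
    """
    E = _dense(expr)
    gene_names = pd.Index(gene_names)
    group_mask = np.asarray(group_mask, dtype=bool)
    lineage_mask = (np.ones(E.shape[0], dtype=bool) if lineage_mask is None
                    else np.asarray(lineage_mask, dtype=bool))
    if not group_mask.any():
        raise ValueError("empty group")
    rest_mask = lineage_mask & ~group_mask
    if not rest_mask.any():
        raise ValueError("group covers the whole lineage: nothing to compare against")

    G, Rm = E[group_mask], E[rest_mask]
    lfc = _avg_log2fc(G, Rm)
    pct_diff = _pct_detect(G) - _pct_detect(Rm)
    pre = (lfc >= min_log2fc) & (pct_diff >= min_pct_diff)
    idx = np.where(pre)[0]
    if idx.size == 0:
        return pd.DataFrame(columns=["gene", "auc", "log2fc", "pct_diff", "rank"])
    auc = roc_auc_scores(G[:, idx], Rm[:, idx])
    keep = auc > min_auc
    idx, auc = idx[keep], auc[keep]
    order = np.lexsort((gene_names[idx], -lfc[idx], -pct_diff[idx], -auc))
    idx, auc = idx[order], auc[order]
    return pd.DataFrame(
        {
            "gene": gene_names[idx],
            "auc": auc,
            "log2fc": lfc[idx],
            "pct_diff": pct_diff[idx],
            "rank": np.arange(1, len(idx) + 1),
        }
    )


def wilcoxon_markers(
    expr,
    gene_names,
    labels,
    max_adj_p: float = 0.05,
    min_avg_logfc: float = 3.0,
    min_pct_diff: float = 0.4,
    logfc_base: float = np.e,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest rank-sum markers per label with threshold selection.

    Average log fold change uses means of expm1(log-normalized) expression
    with pseudocount 1 (natural log by default; ``logfc_base`` switches the
    base). Genes passing thresholds for several labels are reassigned to the
    label with the highest logFC (tie-break: pct.diff).
    """
    E = _dense(expr)
    gene_names = pd.Index(gene_names)
    labels = np.asarray(labels, dtype=object)
    ulabels = sorted(set(labels))
    if len(ulabels) < 2:
        raise ValueError("at least two labels are required")

    records = []
    for lab in ulabels:
        g = labels == lab
        if g.sum() < min_cells:
            warnings.warn(f"label {lab!r} has fewer than {min_cells} cells; skipped")
            continue
        G, Rm = E[g], E[~g]
        with np.errstate(all="ignore"):
            stat, p = mannwhitneyu(G, Rm, alternative="two-sided", axis=0,
                                   method="asymptotic")
        p = np.where(np.isfinite(p), p, 1.0)
        adj = multipletests(p, method="fdr_bh")[1]
        lfc = (np.log(np.expm1(G).mean(axis=0) + 1)
               - np.log(np.expm1(Rm).mean(axis=0) + 1)) / np.log(logfc_base)
        pct = _pct_detect(G) - _pct_detect(Rm)
        ok = (adj < max_adj_p) & (lfc > min_avg_logfc) & (pct > min_pct_diff)
        for j in np.where(ok)[0]:
            records.append({"gene": gene_names[j], "label": lab, "adj_p": adj[j],
                            "avg_logfc": lfc[j], "pct_diff": pct[j]})
    if not records:
        return pd.DataFrame(columns=["gene", "label", "adj_p", "avg_logfc", "pct_diff"])
    df = pd.DataFrame(records)
    # reassign multi-label genes: highest avg logFC, then pct.diff
    df = (df.sort_values(["gene", "avg_logfc", "pct_diff"],
                         ascending=[True, False, False])
            .drop_duplicates("gene", keep="first")
            .reset_index(drop=True))
    return df


def spearman_time_rank(expr, gene_names, consensus_time, top_k: int = 10) -> pd.DataFrame:
    """Per-gene Spearman correlation with consensus pseudotime.

    Constant genes get rho = 0 with a flag. ``top_k`` is the per-group
    selection size used downstream when picking dynamic genes.
    """
    E = _dense(expr)
    t = np.asarray(consensus_time, dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("consensus time is constant")
    rt = rankdata(t)
    rt = (rt - rt.mean()) / rt.std()
    R = np.apply_along_axis(rankdata, 0, E)
    sd = R.std(axis=0)
    const = sd == 0
    sd[const] = 1.0
    Rc = (R - R.mean(axis=0)) / sd
    rho = (Rc * rt[:, None]).mean(axis=0)
    rho[const] = 0.0
    out = pd.DataFrame({"gene": pd.Index(gene_names), "rho": rho, "constant": const})
    out.attrs["top_k"] = top_k
    return out
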