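"""Consensus pseudotime per lineage and equal-frequency decile binning.

Two per-lineage estimators are averaged after min-max scaling and
orientation alignment: (A) a gene-diversity score — the rank of the number
of detected genes per cell, smoothed over k nearest neighbors in PCA space
(more detected genes = less differentiated); (B) by default a diffusion
pseudotime rooted at a designated young anchor. The consensus convention is
that larger values mean more mature cells; cells are then split into ten
equally sized bins T0 (youngest) .. T9.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .preprocess import log_normalize, pca_embed

__all__ = [
    "gene_diversity_pseudotime",
    "anchored_diffusion_pseudotime",
    "consensus_pseudotime",
    "average_anchor_consensus",
    "bin_pseudotime",
    "ConsensusPseudotime",
]


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def gene_diversity_pseudotime(X, knn_k: int = 30, n_pcs: int = 50, seed: int = 0) -> np.ndarray:
    """Smoothed, rescaled rank of detected-gene counts (higher = younger)."""
    X = X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X))
    n = X.shape[0]
    if knn_k >= n:
        raise ValueError("knn_k must be smaller than the number of cells")
    detected = np.asarray((X > 0).sum(axis=1)).ravel().astype(float)
    score = rankdata(detected, method="average")
    if knn_k > 0:
        emb = pca_embed(log_normalize(X), n_comps=n_pcs, random_state=seed)
        nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(emb)
        _, idx = nn.kneighbors(emb)  # includes self
        score = score[idx].mean(axis=1)
    return _minmax(score)


def anchored_diffusion_pseudotime(adata_or_X, anchor_cells, gene_names=None,
                                  n_pcs: int = 50, n_neighbors: int = 15,
                                  seed: int = 0) -> np.ndarray:
    """Diffusion pseudotime rooted at a young anchor (scanpy dpt).

    ``anchor_cells`` is an index array of young cells; the root is the
    anchor cell closest to the anchor centroid in PCA space.
    """
    import anndata as ad
    import scanpy as sc

    if hasattr(adata_or_X, "X"):
        adata = adata_or_X.copy()
        X = adata.X
    else:
        X = adata_or_X
        adata = ad.AnnData(X=sp.csr_matrix(X))
    anchor_cells = np.asarray(anchor_cells, dtype=int)
    if anchor_cells.size == 0:
        raise ValueError("anchor cell set is empty")
    Xn = log_normalize(X)
    emb = pca_embed(Xn, n_comps=n_pcs, random_state=seed)
    adata.obsm["X_pca"] = emb
    centroid = emb[anchor_cells].mean(axis=0)
    root = anchor_cells[int(np.argmin(((emb[anchor_cells] - centroid) ** 2).sum(axis=1)))]
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, X.shape[0] - 1), use_rep="X_pca",
                    random_state=seed)
    sc.tl.diffmap(adata)
    adata.uns["iroot"] = int(root)
    sc.tl.dpt(adata)
    pt = adata.obs["dpt_pseudotime"].to_numpy(dtype=float)
    pt[~np.isfinite(pt)] = np.nanmax(pt[np.isfinite(pt)]) if np.isfinite(pt).any() else 0.0
    return _minmax(pt)


def consensus_pseudotime(pt_a, pt_b, anchor_mask=None) -> np.ndarray:
    """Average of two orientation-aligned, min-max-scaled estimators.

    If the estimators are negatively correlated (scale conventions differ),
    the first is flipped. When a young-cell anchor set is supplied, both are
    flipped together if the anchors do not come out early, so that larger
    consensus always means more mature.
    """
    pt_a = np.asarray(pt_a, dtype=float)
    pt_b = np.asarray(pt_b, dtype=float)
    if pt_a.shape != pt_b.shape:
        raise ValueError("estimators must cover the same cells")
    if np.ptp(pt_a) == 0 or np.ptp(pt_b) == 0:
        raise ValueError("zero-variance pseudotime estimate")
    a = _minmax(pt_a)
    b = _minmax(pt_b)
    if np.corrcoef(a, b)[0, 1] < 0:
        a = 1.0 - a
    cons = 0.5 * (a + b)
    if anchor_mask is not None:
        anchor_mask = np.asarray(anchor_mask, dtype=bool)
        if anchor_mask.any() and cons[anchor_mask].mean() > np.median(cons):
            cons = 1.0 - cons
    return cons


def average_anchor_consensus(consensus, anchor_mask) -> np.ndarray:
    """Assign all anchor cells their mean consensus value (pre-binning)."""
    consensus = np.asarray(consensus, dtype=float).copy()
    anchor_mask = np.asarray(anchor_mask, dtype=bool)
    if anchor_mask.any():
        consensus[anchor_mask] = consensus[anchor_mask].mean()
    return consensus


def bin_pseudotime(consensus, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency bins T0 (youngest) .. T{n_bins-1}; sizes differ <= 1.

    Ties and equal values are resolved by stable cell order; when the cell
    count is not divisible, the earliest bins take the extra cell.
    """
    consensus = np.asarray(consensus, dtype=float)
    n = len(consensus)
    if n_bins > n:
        raise ValueError("n_bins exceeds the number of cells")
    order = np.argsort(consensus, kind="stable")
    base, extra = divmod(n, n_bins)
    sizes = [base + 1 if k < extra else base for k in range(n_bins)]
    labels = np.empty(n, dtype=object)
    start = 0
    for k, s in enumerate(sizes):
        labels[order[start : start + s]] = f"T{k}"
        start += s
    return labels


class ConsensusPseudotime(BaseEstimator):
    """Per-lineage consensus pseudotime.

    ``fit`` takes a counts matrix, per-cell lineage labels, and optionally a
    young-anchor mask (e.g. quiescent-center cells, which can be pooled into
    every lineage to anchor the young end). Attributes after fitting:
    ``result_`` (DataFrame with lineage, pt_a, pt_b, consensus, bin).
    """

    def __init__(self, n_bins=10, knn_k=30, n_pcs=50, n_neighbors=15,
                 average_anchors=False, seed=0, estimator_b=None):
        self.n_bins = n_bins
        self.knn_k = knn_k
        self.n_pcs = n_pcs
        self.n_neighbors = n_neighbors
        self.average_anchors = average_anchors
        self.seed = seed
        self.estimator_b = estimator_b  # optional externally computed vector

    def fit(self, X, lineages, anchor_mask=None, include_anchors_in=None):
        X = X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X))
        lineages = np.asarray(lineages, dtype=object)
        n = X.shape[0]
        anchor_mask = (np.zeros(n, dtype=bool) if anchor_mask is None
                       else np.asarray(anchor_mask, dtype=bool))
        ext_b = None if self.estimator_b is None else np.asarray(self.estimator_b, dtype=float)

        res = pd.DataFrame(index=np.arange(n))
        res["lineage"] = lineages
        for col in ("pt_a", "pt_b", "consensus"):
            res[col] = np.nan
        res["bin"] = None

        for lin in sorted(set(lineages) - {None}):
            sel = np.where((lineages == lin) | anchor_mask)[0] \
                if (include_anchors_in is None or lin in include_anchors_in) \
                else np.where(lineages == lin)[0]
            if len(sel) < max(3, self.n_bins):
                continue
            Xl = X[sel]
            k = min(self.knn_k, len(sel) - 1)
            pt_a = gene_diversity_pseudotime(Xl, knn_k=k, n_pcs=self.n_pcs, seed=self.seed)
            if ext_b is not None:
                pt_b = ext_b[sel]
            else:
                local_anchor = np.where(anchor_mask[sel])[0]
                if local_anchor.size == 0:
                    # fall back: root at the most diverse (youngest) cells
                    local_anchor = np.argsort(-pt_a)[: max(1, len(sel) // 50)]
                pt_b = anchored_diffusion_pseudotime(
                    Xl, local_anchor, n_pcs=self.n_pcs,
                    n_neighbors=self.n_neighbors, seed=self.seed,
                )
            try:
                cons = consensus_pseudotime(pt_a, pt_b, anchor_mask=anchor_mask[sel])
            except ValueError as e:
                import warnings

                warnings.warn(f"lineage {lin!r}: {e}; left unbinned")
                continue
            if self.average_anchors:
                cons = average_anchor_consensus(cons, anchor_mask[sel])
            own = lineages[sel] == lin
            res.loc[sel[own], "pt_a"] = pt_a[own]
            res.loc[sel[own], "pt_b"] = pt_b[own]
            res.loc[sel[own], "consensus"] = cons[own]
            res.loc[sel[own], "bin"] = bin_pseudotime(cons[own], self.n_bins)
        self.result_ = res
        return self

    def fit_transform(self, X, lineages, **kw):
        return self.fit(X, lineages, **kw).result_
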