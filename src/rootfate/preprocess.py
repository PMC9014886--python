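"""Shared normalization and embedding helpers.

All downstream modules work on log-normalized expression: counts scaled to a
common library size (counts-per-ten-thousand) and log1p-transformed. This is
the simplest monotone normalization; every correlation/voting step in the
pipeline only requires monotonicity.
"""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

DEFAULT_TARGET_SUM = 10_000.0


def _as_csr(X) -> sp.csr_matrix:
    if sp.issparse(X):
        return X.tocsr()
    return sp.csr_matrix(np.asarray(X))


def total_counts(X) -> np.ndarray:
    """Per-cell total UMI of a cells x genes matrix."""
    X = _as_csr(X)
    return np.asarray(X.sum(axis=1)).ravel()


def log_normalize(X, target_sum: float = DEFAULT_TARGET_SUM) -> sp.csr_matrix:
    """log1p(counts / cell_total * target_sum), cells x genes.

    Cells with zero total are left as zero rows (callers that forbid them
    raise before normalizing).
    """
    X = _as_csr(X).astype(np.float64)
    totals = total_counts(X)
    scale = np.zeros_like(totals)
    nz = totals > 0
    scale[nz] = target_sum / totals[nz]
    Xn = sp.diags(scale) @ X
    Xn.data = np.log1p(Xn.data)
    return Xn.tocsr()


def pca_embed(X_lognorm, n_comps: int = 50, random_state: int = 0) -> np.ndarray:
    """Dense PCA embedding of log-normalized expression (cells x n_comps)."""
    X = X_lognorm.toarray() if sp.issparse(X_lognorm) else np.asarray(X_lognorm, dtype=float)
    n_comps = min(n_comps, min(X.shape) - 1)
    p = PCA(n_components=n_comps, svd_solver="randomized", random_state=random_state)
    return p.fit_transform(X)


def zscore_genes(X_lognorm) -> np.ndarray:
    """Gene-wise standardized log expression (dense cells x genes)."""
    X = X_lognorm.toarray() if sp.issparse(X_lognorm) else np.asarray(X_lognorm, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd
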