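"""Fate-predictive transcription-factor regression.

For every developmental stage (meristem, elongation, maturation, and the
full set) and every lineage, the per-cell fate probability f is regressed
on TF-restricted log-normalized expression E with an L1 penalty:

    minimize (1/2n) ||f - E w||^2 + alpha ||w||_1

The model is fitted over a decreasing alpha grid; the working alpha is the
knee of the R^2 versus number-of-nonzero-coefficients curve (Kneedle
procedure). Coefficient magnitudes rank genes by lineage-determining
capacity; a positive sign means up-regulation favors the lineage.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso

from .preprocess import log_normalize

__all__ = [
    "lasso_fit",
    "default_alpha_grid",
    "alpha_knee",
    "kneedle",
    "rank_regulators",
    "FateLassoRanker",
]

STAGES = ("meristem", "elongation", "maturation", "all")


def lasso_fit(E, f, alpha: float, tol: float = 1e-6, max_iter: int = 20_000):
    """Solve the L1-penalized least-squares problem; returns (w, R^2).

    No intercept is fitted, so the optimality (KKT) conditions
    |(1/n) E_j^T (f - E w)| <= alpha hold exactly as written, and
    alpha >= max|E^T f|/n forces w = 0.
    """
    E = np.asarray(E, dtype=float)
    f = np.asarray(f, dtype=float)
    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(f))):
        raise ValueError("non-finite values in the regression inputs")
    if E.shape[0] < 2:
        raise ValueError("need at least two cells")
    model = Lasso(alpha=alpha, fit_intercept=False, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(E, f)
    w = model.coef_
    resid = f - E @ w
    ss_tot = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return w, r2


def default_alpha_grid(E, f, n_alphas: int = 30, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced decreasing grid from the deactivation threshold down."""
    E = np.asarray(E, dtype=float)
    f = np.asarray(f, dtype=float)
    alpha_max = float(np.abs(E.T @ f).max() / len(f))
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.geomspace(alpha_max, alpha_max * ratio, n_alphas)


def kneedle(x: np.ndarray, y: np.ndarray):
    """Knee of a concave increasing curve (Kneedle, sensitivity 1).

    Both axes are normalized to [0, 1]; the knee is the local maximum of
    the difference curve y_n - x_n with the largest difference. Returns the
    index into x, or None when the difference curve has no local maximum
    (e.g. a perfectly straight line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("at least 4 grid points are required")
    xs = (x - x.min()) / (x.max() - x.min()) if x.max() > x.min() else np.zeros_like(x)
    ys = (y - y.min()) / (y.max() - y.min()) if y.max() > y.min() else np.zeros_like(y)
    d = ys - xs
    if np.allclose(d, d[0]):
        return None
    # local maxima of the difference curve
    is_lmax = np.zeros(len(d), dtype=bool)
    for i in range(1, len(d) - 1):
        if d[i] >= d[i - 1] and d[i] >= d[i + 1]:
            is_lmax[i] = True
    if not is_lmax.any():
        return None
    cand = np.where(is_lmax)[0]
    return int(cand[np.argmax(d[cand])])


def alpha_knee(alphas, r2, nnz):
    """Alpha at the knee of the (nnz, R^2) curve.

    Points are sorted by nnz; duplicate nnz values keep their best R^2.
    Falls back, with a warning, to the maximum-curvature point of the
    discrete second difference when the curve has no Kneedle knee.
    """
    alphas = np.asarray(alphas, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    nnz = np.asarray(nnz, dtype=float)
    if len(alphas) < 4:
        raise ValueError("at least 4 grid points are required")
    order = np.argsort(nnz, kind="stable")
    nnz_s, r2_s, a_s = nnz[order], r2[order], alphas[order]
    keep = []
    seen = {}
    for i in range(len(nnz_s)):
        key = nnz_s[i]
        if key not in seen or r2_s[i] > r2_s[seen[key]]:
            seen[key] = i
    keep = sorted(seen.values())
    nnz_u, r2_u, a_u = nnz_s[keep], r2_s[keep], a_s[keep]
    if len(nnz_u) < 4:
        return float(a_u[np.argmax(r2_u)])
    k = kneedle(nnz_u, r2_u)
    if k is None:
        warnings.warn("no Kneedle knee (straight curve); falling back to max curvature")
        ys = (r2_u - r2_u.min()) / max(r2_u.max() - r2_u.min(), 1e-300)
        curv = np.abs(np.diff(ys, 2))
        k = int(np.argmax(curv)) + 1
    return float(a_u[k])


def rank_regulators(
    X,
    gene_names,
    tf_mask,
    fates: pd.DataFrame,
    stages,
    alpha_grid=None,
    n_alphas: int = 30,
    min_cells: int = 50,
) -> dict:
    """Ranked signed TF coefficients per (stage, lineage).

    ``stages`` is a per-cell stage label array; the 'all' stage uses every
    cell. Stages with fewer than ``min_cells`` cells, and degenerate
    (constant-fate) regressions, are skipped with a warning.
    """
    gene_names = pd.Index(gene_names)
    tf_mask = np.asarray(tf_mask, dtype=bool)
    if tf_mask.sum() == 0:
        raise ValueError("no transcription factors in the gene space")
    En = log_normalize(X).toarray()[:, tf_mask]
    tf_names = gene_names[tf_mask]
    stages_arr = np.asarray(stages, dtype=object)

    results = {}
    for stage in STAGES:
        mask = np.ones(len(stages_arr), dtype=bool) if stage == "all" else stages_arr == stage
        if mask.sum() < min_cells:
            warnings.warn(f"stage {stage!r} has fewer than {min_cells} cells; skipped")
            continue
        Es = En[mask]
        for lineage in fates.columns:
            f = fates[lineage].to_numpy()[mask]
            if np.ptp(f) < 1e-12:
                warnings.warn(f"constant fates for ({stage}, {lineage}); skipped")
                continue
            ranker = FateLassoRanker(alpha_grid=alpha_grid, n_alphas=n_alphas)
            ranker.fit(Es, f, feature_names=tf_names)
            results[(stage, lineage)] = {
                "alpha_opt": ranker.alpha_opt_,
                "r2": ranker.r2_,
                "nnz": int(np.count_nonzero(ranker.coef_)),
                "ranking": ranker.ranking_,
            }
    return results


class FateLassoRanker(BaseEstimator, RegressorMixin):
    """Lasso over an alpha grid with knee-point model selection.

    After ``fit``: ``alphas_``, ``r2_path_``, ``nnz_path_``, ``alpha_opt_``,
    ``coef_``, ``r2_``, ``ranking_`` (DataFrame of nonzero signed
    coefficients sorted by |coefficient| descending).
    """

    def __init__(self, alpha_grid=None, n_alphas=30, alpha_ratio=1e-3):
        self.alpha_grid = alpha_grid
        self.n_alphas = n_alphas
        self.alpha_ratio = alpha_ratio

    def fit(self, E, f, feature_names=None):
        E = E.toarray() if sp.issparse(E) else np.asarray(E, dtype=float)
        f = np.asarray(f, dtype=float)
        alphas = (np.asarray(self.alpha_grid, dtype=float) if self.alpha_grid is not None
                  else default_alpha_grid(E, f, self.n_alphas, self.alpha_ratio))
        r2s, nnzs, ws = [], [], []
        # warm-started coordinate descent down the alpha path
        model = Lasso(alpha=alphas[0], fit_intercept=False, tol=1e-6,
                      max_iter=20_000, warm_start=True)
        ss_tot = float(((f - f.mean()) ** 2).sum())
        for a in alphas:
            model.set_params(alpha=a)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(E, f)
            w = model.coef_.copy()
            resid = f - E @ w
            r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
            ws.append(w)
            r2s.append(r2)
            nnzs.append(int(np.count_nonzero(w)))
        self.alphas_ = alphas
        self.r2_path_ = np.array(r2s)
        self.nnz_path_ = np.array(nnzs)
        self.alpha_opt_ = alpha_knee(alphas, self.r2_path_, self.nnz_path_)
        k = int(np.argmin(np.abs(alphas - self.alpha_opt_)))
        self.coef_ = ws[k]
        self.r2_ = r2s[k]
        names = (pd.Index(feature_names) if feature_names is not None
                 else pd.Index([f"x{j}" for j in range(E.shape[1])]))
        nz = np.nonzero(self.coef_)[0]
        order = nz[np.argsort(-np.abs(self.coef_[nz]), kind="stable")]
        self.ranking_ = pd.DataFrame(
            {"gene": names[order], "coefficient": self.coef_[order]}
        ).reset_index(drop=True)
        return self

    def predict(self, E):
        E = E.toarray() if sp.issparse(E) else np.asarray(E, dtype=float)
        return E @ self.coef_
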