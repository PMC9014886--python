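"""COPILOT-style quality filtering for droplet scRNA-seq count matrices.

The procedure: flag putative dying cells by mitochondrial UMI share (> 5% of
total by default), take the mode of the dying cells' count distribution as a
boundary separating low- from high-quality cells, refine the split by
correlating every high-quality cell against mean low/high expression
profiles (a single pass by default, to avoid over-filtering), then remove
dying + low-quality cells and the top 1% of high-quality cells by total UMI.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .preprocess import log_normalize, total_counts

__all__ = [
    "QCParams",
    "QCResult",
    "CopilotFilter",
    "flag_mito_dying",
    "count_mode_boundary",
    "correlation_refine",
    "remove_top_umi",
    "run_copilot",
]

STATUS_KEPT = "kept"
STATUS_DYING = "dying"
STATUS_LOW = "low_quality"
STATUS_TOP = "top_umi_outlier"


@dataclass(frozen=True)
class QCParams:
    mito_threshold: float = 0.05
    top_umi_fraction: float = 0.01
    iterate: bool = False
    histogram_bins: int | None = None

    def validate(self) -> None:
        if not (0 < self.mito_threshold < 1):
            raise ValueError("mito_threshold must be in (0, 1)")
        if not (0 <= self.top_umi_fraction < 0.5):
            raise ValueError("top_umi_fraction must be in [0, 0.5)")


@dataclass
class QCResult:
    status: np.ndarray  # per-cell status, one of the STATUS_* strings
    total_umi: np.ndarray
    mito_fraction: np.ndarray
    boundary: float | None
    n_passes: int
    kept_genes: np.ndarray = field(default=None)  # mask of genes with any counts

    @property
    def keep_mask(self) -> np.ndarray:
        return self.status == STATUS_KEPT


def flag_mito_dying(X, mito_mask, threshold: float = 0.05, barcodes=None) -> np.ndarray:
    """Flag cells whose mitochondrial UMI share strictly exceeds ``threshold``."""
    X = X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X))
    mito_mask = np.asarray(mito_mask, dtype=bool)
    if mito_mask.sum() == 0:
        raise ValueError("mitochondrial gene set is empty")
    totals = total_counts(X)
    if np.any(totals == 0):
        bad = np.where(totals == 0)[0]
        names = list(np.asarray(barcodes)[bad]) if barcodes is not None else list(bad)
        raise ValueError(f"cells with zero total UMI are not allowed: {names}")
    mito_totals = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    return (mito_totals / totals) > threshold


def count_mode_boundary(dying_totals, histogram_bins: int | None = None) -> float:
    """Mode of log10(total UMI) of dying cells, back-transformed.

    Histogram binning defaults to the Freedman-Diaconis rule; the estimator
    of the mode is unspecified upstream, so the bin count is a parameter.
    """
    totals = np.asarray(dying_totals, dtype=float)
    if totals.size == 0:
        raise ValueError("no dying cells: cannot estimate a count-mode boundary")
    if totals.size == 1:
        return float(totals[0])
    logt = np.log10(totals)
    smooth = histogram_bins is None
    if histogram_bins is None:
        edges = np.histogram_bin_edges(logt, bins="fd")
        if len(edges) < 2 or edges[0] == edges[-1]:
            edges = np.histogram_bin_edges(logt, bins=10)
    else:
        edges = np.histogram_bin_edges(logt, bins=histogram_bins)
    hist, edges = np.histogram(logt, bins=edges)
    if smooth and len(hist) >= 3:
        # a raw histogram mode is noisy at a few hundred cells; a 3-bin
        # moving average stabilizes the argmax without changing its scale
        hist = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    k = int(np.argmax(hist))
    center = 0.5 * (edges[k] + edges[k + 1])
    return float(10.0**center)


def _group_profile_corr(Xn_high: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of Xn_high against a profile vector."""
    Xc = Xn_high - Xn_high.mean(axis=1, keepdims=True)
    pc = profile - profile.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (pc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ pc) / denom
    return np.where(np.isfinite(r), r, -np.inf)


def correlation_refine(X, low_idx, high_idx, iterate: bool = False):
    """Move high-quality cells more correlated to the low-quality profile.

    Builds mean log-normalized profiles for both groups; any high cell with
    r(low profile) > r(high profile) (strict) is reassigned. A tie keeps the
    cell in the high group (removal requires positive evidence). With
    ``iterate`` the pass repeats until no reassignment; the low set grows
    monotonically so this terminates.
    """
    low = np.array(sorted(set(int(i) for i in low_idx)))
    high = np.array(sorted(set(int(i) for i in high_idx)))
    if low.size == 0 or high.size == 0:
        raise ValueError("both low- and high-quality sets must be non-empty")
    if np.intersect1d(low, high).size:
        raise ValueError("low and high sets must be disjoint")
    Xn = log_normalize(X).toarray()
    n_passes = 0
    while True:
        n_passes += 1
        low_profile = Xn[low].mean(axis=0)
        high_profile = Xn[high].mean(axis=0)
        r_low = _group_profile_corr(Xn[high], low_profile)
        r_high = _group_profile_corr(Xn[high], high_profile)
        move = r_low > r_high
        if not move.any():
            break
        low = np.sort(np.concatenate([low, high[move]]))
        high = high[~move]
        if high.size == 0 or not iterate:
            break
    return low, high, n_passes


def remove_top_umi(high_idx, totals, fraction: float = 0.01) -> np.ndarray:
    """Drop the ceil(fraction*n) highest-total cells; ties by barcode order."""
    if not (0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    high = np.asarray(sorted(set(int(i) for i in high_idx)))
    if fraction == 0 or high.size == 0:
        return high
    totals = np.asarray(totals, dtype=float)
    n_remove = int(np.ceil(fraction * high.size))
    # sort by descending total, ascending index on ties
    order = np.lexsort((high, -totals[high]))
    removed = set(high[order[:n_remove]].tolist())
    return np.array([i for i in high if i not in removed])


def run_copilot(X, mito_mask, params: QCParams | None = None, barcodes=None) -> QCResult:
    """Full filtering pipeline; statuses record the removal stage per cell."""
    params = params or QCParams()
    params.validate()
    X = X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X))
    mito_mask = np.asarray(mito_mask, dtype=bool)

    gene_keep = np.asarray((X > 0).sum(axis=0)).ravel() > 0
    Xg = X[:, gene_keep]
    mito_g = mito_mask[gene_keep]

    n = X.shape[0]
    totals = total_counts(Xg)
    dying = flag_mito_dying(Xg, mito_g, params.mito_threshold, barcodes=barcodes)
    mito_totals = np.asarray(Xg[:, mito_g].sum(axis=1)).ravel()
    mito_frac = mito_totals / totals

    status = np.full(n, STATUS_KEPT, dtype=object)
    status[dying] = STATUS_DYING
    boundary = None
    n_passes = 0
    if dying.any():
        boundary = count_mode_boundary(totals[dying], params.histogram_bins)
        nondying = np.where(~dying)[0]
        low0 = nondying[totals[nondying] < boundary]
        high0 = nondying[totals[nondying] >= boundary]
        if low0.size and high0.size:
            low, high, n_passes = correlation_refine(Xg, low0, high0, params.iterate)
        else:
            low, high = low0, high0
        status[low] = STATUS_LOW
        high_final = high
    else:
        high_final = np.where(~dying)[0]

    retained = remove_top_umi(high_final, totals, params.top_umi_fraction)
    outliers = np.setdiff1d(high_final, retained)
    status[outliers] = STATUS_TOP

    return QCResult(
        status=status,
        total_umi=totals,
        mito_fraction=mito_frac,
        boundary=boundary,
        n_passes=n_passes,
        kept_genes=gene_keep,
    )


class CopilotFilter(BaseEstimator):
    """Estimator wrapper around :func:`run_copilot`.

    Parameters mirror :class:`QCParams`; the mitochondrial gene mask is a
    constructor parameter because it is part of the filter's definition
    rather than of any single dataset's labels.

    After ``fit``: ``status_``, ``boundary_``, ``n_passes_``, ``keep_mask_``,
    ``gene_mask_``. ``transform`` subsets a matrix to the kept cells (and
    the non-empty genes seen at fit).
    """

    def __init__(self, mito_mask=None, mito_threshold=0.05, top_umi_fraction=0.01,
                 iterate=False, histogram_bins=None):
        self.mito_mask = mito_mask
        self.mito_threshold = mito_threshold
        self.top_umi_fraction = top_umi_fraction
        self.iterate = iterate
        self.histogram_bins = histogram_bins

    def fit(self, X, y=None):
        if self.mito_mask is None:
            raise ValueError("mito_mask must be provided")
        params = QCParams(self.mito_threshold, self.top_umi_fraction,
                          self.iterate, self.histogram_bins)
        res = run_copilot(X, self.mito_mask, params)
        self.result_ = res
        self.status_ = res.status
        self.boundary_ = res.boundary
        self.n_passes_ = res.n_passes
        self.keep_mask_ = res.keep_mask
        self.gene_mask_ = res.kept_genes
        return self

    def transform(self, X):
        if not hasattr(self, "keep_mask_"):
            raise ValueError("CopilotFilter is not fitted")
        X = X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X))
        return X[self.keep_mask_][:, self.gene_mask_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
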