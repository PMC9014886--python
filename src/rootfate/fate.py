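"""Stationary optimal-transport cell-fate inference.

A population of cells at steady state is modeled as transporting mass from
a growth-weighted source distribution to a uniform target over one time
step: the cost is squared Euclidean distance in a low-dimensional expression
embedding (normalized to unit mean), regularized either entropically
(Sinkhorn, epsilon = 0.025 by default) or quadratically. The row-normalized
coupling gives a Markov transition matrix; the most differentiated cells
per lineage (top 5% by pseudotime) are absorbing sinks, and per-cell fate
probabilities are the absorption probabilities of the chain into each
lineage's sinks, obtained from the linear system (I - Q) F = R.

For large datasets the fates are computed on random partitions of the cells
(10 subsets x 10 repeats by default) and averaged cell-by-cell into a
consensus fate matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = [
    "OTParams",
    "TransitionPlan",
    "select_sinks",
    "stationary_ot",
    "fate_probabilities",
    "consensus_fates",
    "barycentric_project",
    "max_fate",
    "default_dt",
    "sinkhorn_log",
    "quadratic_ot",
    "StationaryFateOT",
    "ConsensusFateOT",
]


@dataclass(frozen=True)
class OTParams:
    epsilon: float = 0.025
    regularization_kind: str = "entropic"  # or "quadratic"
    dt: float | None = None  # None -> growth balances absorption
    sink_fraction: float = 0.05
    cost_normalize: bool = True
    sinkhorn_max_iter: int = 30000
    sinkhorn_tol: float = 1e-4

    def validate(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0 < self.sink_fraction < 0.5):
            raise ValueError("sink_fraction must be in (0, 0.5)")
        if self.regularization_kind not in ("entropic", "quadratic"):
            raise ValueError("regularization_kind must be 'entropic' or 'quadratic'")


@dataclass
class TransitionPlan:
    coupling: np.ndarray  # gamma, cells x cells
    transition: np.ndarray  # P, row-stochastic, sink rows self-absorbing
    sink_mask: np.ndarray
    sink_classes: np.ndarray  # per-cell class for sinks, '' elsewhere
    mu: np.ndarray
    nu: np.ndarray
    cost_mean: float
    epsilon: float
    dt: float


def select_sinks(consensus_pt, lineage_labels, fraction: float = 0.05):
    """Top ``fraction`` most differentiated cells per lineage, with classes.

    Returns (sink_mask, sink_classes) over all cells; ties in pseudotime are
    broken by cell order (stable sort).
    """
    pt = np.asarray(consensus_pt, dtype=float)
    labels = np.asarray(lineage_labels, dtype=object)
    n = len(pt)
    sink_mask = np.zeros(n, dtype=bool)
    sink_classes = np.full(n, "", dtype=object)
    for lin in sorted(set(labels)):
        idx = np.where(labels == lin)[0]
        if idx.size == 0:
            raise ValueError(f"lineage {lin!r} has no cells")
        k = max(1, int(np.ceil(fraction * idx.size)))
        order = idx[np.argsort(-pt[idx], kind="stable")]
        chosen = order[:k]
        sink_mask[chosen] = True
        sink_classes[chosen] = lin
    return sink_mask, sink_classes


def default_dt(growth, sink_mask) -> float:
    """Time step making population growth balance sink absorption.

    Solves sum_{non-sink} exp(dt * g_i) = N: over one step the surviving
    (non-sink) population regrows exactly the mass that the sinks absorb.
    With uniform growth g and sink fraction f this is dt = -log(1-f)/g,
    i.e. about 0.25 day for f = 0.05 and g ≈ 0.2/day — a 6-hour step
    replacing ~5% of each lineage.
    """
    growth = np.asarray(growth, dtype=float)
    ns = growth[~np.asarray(sink_mask, dtype=bool)]
    n = len(growth)
    if len(ns) == n:
        raise ValueError("no sinks")
    f = lambda dt: np.exp(dt * ns).sum() - n
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("cannot bracket default dt")
    return float(brentq(f, 0.0, hi))


def sinkhorn_log(C, mu, nu, eps, max_iter=30000, tol=1e-4, omega=1.5):
    """Log-domain Sinkhorn for entropic OT; returns the coupling gamma.

    Uses epsilon scaling: the dual potentials are warm-started through a
    geometric sequence of regularization strengths ending at ``eps``, which
    cuts the iteration count by an order of magnitude at small epsilon.
    Zero-mass source rows are excluded (their coupling rows are zero).
    Raises on non-convergence, reporting the final marginal violation.
    """
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    active = mu > 0
    Ca = C[active]
    f = np.zeros(int(active.sum()))
    g = np.zeros(len(nu))

    mu_a = mu[active]
    eps_start = max(eps, Ca.max() / 50.0) if Ca.size else eps
    eps_list = [eps]
    e = eps
    while e < eps_start:
        e *= 4.0
        eps_list.append(min(e, eps_start))
    eps_list = eps_list[::-1]

    err = np.inf
    it_total = 0
    tiny = 1e-300
    omega = float(omega)
    for stage, e in enumerate(eps_list):
        K = np.exp(-(Ca - f[:, None] - g[None, :]) / e)
        u = np.ones(len(mu_a))
        v = np.ones(len(nu))
        last = stage == len(eps_list) - 1
        stage_tol = tol if last else max(tol, 1e-3)
        budget = max_iter if last else 200
        for it in range(budget):
            # over-relaxed scaling updates (omega = 1.5), in log space for
            # numerical safety
            u_new = mu_a / np.maximum(K @ v, tiny)
            u = np.exp((1 - omega) * np.log(np.maximum(u, tiny))
                       + omega * np.log(np.maximum(u_new, tiny)))
            v_new = nu / np.maximum(K.T @ u, tiny)
            v = np.exp((1 - omega) * np.log(np.maximum(v, tiny))
                       + omega * np.log(np.maximum(v_new, tiny)))
            it_total += 1
            if max(u.max(), v.max()) > 1e100 or min(u.min(), v.min()) < 1e-100:
                # absorb the scalings into the potentials to avoid overflow
                f = f + e * np.log(np.maximum(u, tiny))
                g = g + e * np.log(np.maximum(v, tiny))
                K = np.exp(-(Ca - f[:, None] - g[None, :]) / e)
                u = np.ones(len(mu_a))
                v = np.ones(len(nu))
                continue
            if it % 10 == 0 or it == budget - 1:
                Kv = K @ v
                row = u * Kv
                col = v * (K.T @ u)
                err = max(np.abs(row - mu_a).sum(), np.abs(col - nu).sum())
                if err < stage_tol:
                    break
        f = f + e * np.log(np.maximum(u, tiny))
        g = g + e * np.log(np.maximum(v, tiny))
        if last and err >= tol:
            raise RuntimeError(
                f"Sinkhorn did not converge in {it_total} iterations "
                f"(marginal violation {err:.3e})"
            )
    gamma = np.zeros_like(C)
    gamma[active] = np.exp(-(Ca - f[:, None] - g[None, :]) / eps)
    return gamma


def quadratic_ot(C, mu, nu, eps, max_iter=2000, tol=1e-8):
    """Quadratically regularized OT via its smooth concave dual.

    gamma = max(0, (u_i + v_j - C_ij)) / eps; the dual
    max mu.u + nu.v - (1/2 eps) sum (u+v-C)_+^2 is solved with L-BFGS.
    Produces sparse couplings, used for the robustness check against the
    entropic solution.
    """
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    n, m = C.shape

    def neg_dual(z):
        u, v = z[:n], z[n:]
        slack = u[:, None] + v[None, :] - C
        pos = np.maximum(slack, 0.0)
        val = mu @ u + nu @ v - (pos**2).sum() / (2 * eps)
        gu = mu - pos.sum(axis=1) / eps
        gv = nu - pos.sum(axis=0) / eps
        return -val, -np.concatenate([gu, gv])

    z0 = np.zeros(n + m)
    res = minimize(neg_dual, z0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol})
    u, v = res.x[:n], res.x[n:]
    gamma = np.maximum(u[:, None] + v[None, :] - C, 0.0) / eps
    return gamma


def stationary_ot(embedding, growth, sink_mask, sink_classes,
                  params: OTParams | None = None) -> TransitionPlan:
    """Solve the stationary transport problem and build the Markov chain.

    Cost: squared Euclidean distance in the embedding, scaled to unit mean
    when ``cost_normalize``. Source marginal: mu_i ∝ exp(dt * g_i) for
    non-sinks (each cell's unit of mass grown over dt); the residual mass is
    assigned equally to sinks. Target: uniform. Sink rows of the transition
    matrix are overwritten with self-absorption.
    """
    params = params or OTParams()
    params.validate()
    X = np.asarray(embedding, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("embedding contains non-finite values")
    growth = np.asarray(growth, dtype=float)
    if np.any(growth <= 0):
        raise ValueError("growth rates must be strictly positive")
    sink_mask = np.asarray(sink_mask, dtype=bool)
    n = X.shape[0]

    C = cdist(X, X, metric="sqeuclidean")
    if params.cost_normalize:
        C = C / C.mean()
    dt = params.dt if params.dt is not None else default_dt(growth, sink_mask)

    w = np.exp(dt * growth) / n
    mu = np.zeros(n)
    mu[~sink_mask] = w[~sink_mask]
    residual = 1.0 - mu.sum()
    n_sinks = int(sink_mask.sum())
    if n_sinks == 0:
        raise ValueError("no sinks selected")
    if residual > 0:
        mu[sink_mask] = residual / n_sinks
    else:
        # growth overshoots absorption at this dt: rescale the non-sink mass
        mu[sink_mask] = 0.0
    # masses far below the solver tolerance destabilize the scaling updates
    mu[mu < 1e-12 / n] = 0.0
    mu /= mu.sum()
    nu = np.full(n, 1.0 / n)

    if params.regularization_kind == "entropic":
        gamma = sinkhorn_log(C, mu, nu, params.epsilon,
                             params.sinkhorn_max_iter, params.sinkhorn_tol)
    else:
        gamma = quadratic_ot(C, mu, nu, params.epsilon,
                             params.sinkhorn_max_iter, params.sinkhorn_tol)

    P = np.zeros_like(gamma)
    rows = gamma.sum(axis=1)
    pos = rows > 0
    P[pos] = gamma[pos] / rows[pos, None]
    P[sink_mask] = 0.0
    P[sink_mask, np.where(sink_mask)[0]] = 1.0
    # any zero-mass non-sink row (cannot happen with positive growth) guards:
    dead = ~pos & ~sink_mask
    if dead.any():
        raise RuntimeError(f"{int(dead.sum())} transient cells received no mass")

    return TransitionPlan(
        coupling=gamma, transition=P, sink_mask=sink_mask,
        sink_classes=np.asarray(sink_classes, dtype=object),
        mu=mu, nu=nu, cost_mean=float(C.mean()), epsilon=params.epsilon, dt=dt,
    )


def fate_probabilities(plan: TransitionPlan, on_stranded: str = "raise") -> pd.DataFrame:
    """Absorption probabilities of the chain into each sink class.

    Solves (I - Q) F = R over the transient block; sink rows are one-hot on
    their own class. Cells with no path to any sink (possible with sparse
    quadratic couplings) either raise, listing the stranded cells
    (``on_stranded='raise'``), or are dropped from the system and returned
    as NaN rows with their indices in ``.attrs['stranded']``.
    """
    if on_stranded not in ("raise", "drop"):
        raise ValueError("on_stranded must be 'raise' or 'drop'")
    P = plan.transition
    sink = plan.sink_mask
    classes = sorted(set(plan.sink_classes[sink]))
    n = P.shape[0]
    t_idx = np.where(~sink)[0]
    s_idx = np.where(sink)[0]

    stranded = np.array([], dtype=int)
    if on_stranded == "drop":
        import scipy.sparse as _sp
        import scipy.sparse.csgraph as _csg

        adj = _sp.csr_matrix(P > 1e-12)
        distT = _csg.shortest_path(adj.T, method="D", indices=s_idx, unweighted=True)
        reachable = np.isfinite(distT).any(axis=0)
        stranded = t_idx[~reachable[t_idx]]
        t_idx = t_idx[reachable[t_idx]]
    Q = P[np.ix_(t_idx, t_idx)]
    R = np.zeros((len(t_idx), len(classes)))
    for j, c in enumerate(classes):
        cols = s_idx[plan.sink_classes[s_idx] == c]
        R[:, j] = P[np.ix_(t_idx, cols)].sum(axis=1)
    A = np.eye(len(t_idx)) - Q
    try:
        Ft = np.linalg.solve(A, R)
    except np.linalg.LinAlgError:
        # find the cells with no path to any sink (reverse reachability)
        import scipy.sparse as _sp
        import scipy.sparse.csgraph as _csg

        adj = _sp.csr_matrix(P > 0)
        distT = _csg.shortest_path(adj.T, method="D", indices=s_idx, unweighted=True)
        reachable = np.isfinite(distT).any(axis=0)
        stranded = [int(i) for i in t_idx if not reachable[i]]
        raise RuntimeError(
            f"absorbing system is singular; cells with no path to any sink: "
            f"{stranded[:20]}{'...' if len(stranded) > 20 else ''}"
        )
    total = Ft.sum(axis=1)
    weak = np.where(total < 1 - 1e-6)[0]
    if weak.size:
        if on_stranded == "raise":
            raise RuntimeError(
                f"cells with no path to any sink: {t_idx[weak][:20].tolist()}"
            )
        stranded = np.union1d(stranded, t_idx[weak])
        keep = np.setdiff1d(np.arange(len(t_idx)), weak)
        Ft = Ft[keep]
        t_idx = t_idx[keep]
    F = np.zeros((n, len(classes)))
    F[t_idx] = Ft
    for j, c in enumerate(classes):
        F[s_idx[plan.sink_classes[s_idx] == c], j] = 1.0
    F = np.clip(F, 0.0, None)
    good_rows = np.ones(n, dtype=bool)
    good_rows[stranded] = False
    F[good_rows] /= F[good_rows].sum(axis=1, keepdims=True)
    F[~good_rows] = np.nan
    out = pd.DataFrame(F, columns=classes)
    out.attrs["provenance"] = "single_run"
    out.attrs["stranded"] = stranded
    return out


def consensus_fates(embedding, growth, sink_mask, sink_classes,
                    params: OTParams | None = None, n_subsets: int = 10,
                    n_repeats: int = 10, seed: int = 0, max_retries: int = 100):
    """Partitioned stationary OT with cell-by-cell fate averaging.

    Each repeat partitions the cells into ``n_subsets`` random subsets
    (re-drawn, up to ``max_retries`` times, until every subset contains at
    least one sink of every class); stationary OT + absorption run per
    subset; the consensus is the per-cell mean over repeats. Returns
    (consensus DataFrame, list of per-run records, agreement report against
    the designated first subset run).
    """
    params = params or OTParams()
    X = np.asarray(embedding, dtype=float)
    growth = np.asarray(growth, dtype=float)
    sink_mask = np.asarray(sink_mask, dtype=bool)
    sink_classes = np.asarray(sink_classes, dtype=object)
    n = X.shape[0]
    classes = sorted(set(sink_classes[sink_mask]))
    rng = np.random.default_rng(seed)

    for c in classes:
        if (sink_classes == c).sum() < n_subsets:
            raise RuntimeError(
                f"class {c!r} has fewer sinks than subsets; every subset "
                "needs at least one sink of every class"
            )

    sums = np.zeros((n, len(classes)))
    counts = np.zeros(n)
    runs = []
    for rep in range(n_repeats):
        # stratified partition: each class's sinks are dealt round-robin over
        # the subsets (in random order) so absorption is well-posed in every
        # subset; remaining cells fill the subsets to near-equal size
        buckets = [[] for _ in range(n_subsets)]
        for c in classes:
            idx = rng.permutation(np.where(sink_mask & (sink_classes == c))[0])
            offset = int(rng.integers(n_subsets))
            for j, cell in enumerate(idx):
                buckets[(j + offset) % n_subsets].append(cell)
        rest = rng.permutation(np.where(~sink_mask)[0]).tolist()
        base, extra = divmod(n, n_subsets)
        want = [base + 1 if k < extra else base for k in range(n_subsets)]
        for b in range(n_subsets):
            while len(buckets[b]) < want[b] and rest:
                buckets[b].append(rest.pop())
        for b in range(n_subsets):  # overflow if some bucket was sink-heavy
            while rest:
                buckets[b].append(rest.pop())
                if len(buckets[b]) >= want[b]:
                    break
        subsets = [np.array(sorted(b)) for b in buckets]
        for si, sub in enumerate(subsets):
            sub = np.sort(sub)
            plan = stationary_ot(X[sub], growth[sub], sink_mask[sub],
                                 sink_classes[sub], params)
            F = fate_probabilities(plan).reindex(columns=classes, fill_value=0.0)
            sums[sub] += F.to_numpy()
            counts[sub] += 1
            runs.append({"repeat": rep, "subset": si, "cells": sub, "fates": F})

    consensus = pd.DataFrame(sums / counts[:, None], columns=classes)
    consensus.attrs["provenance"] = "consensus"

    ref = runs[0]
    sub = ref["cells"]
    Fs = ref["fates"].to_numpy()
    Fc = consensus.to_numpy()[sub]
    agree = float(np.mean(Fs.argmax(axis=1) == Fc.argmax(axis=1)))
    r_max = float(np.corrcoef(Fs.max(axis=1), Fc.max(axis=1))[0, 1])
    r_all = float(np.corrcoef(Fs.ravel(), Fc.ravel())[0, 1])
    report = {
        "argmax_agreement": agree,
        "max_fate_correlation": r_max,
        "all_fate_correlation": r_all,
        "n_cells": n,
        "n_runs": len(runs),
    }
    return consensus, runs, report


def barycentric_project(F: pd.DataFrame, classes, vertices=None, tol: float = 1e-6):
    """Map fate probabilities to positions in a triangle (or tetrahedron).

    ``classes`` names the first vertices' fate classes; the last vertex
    aggregates all remaining fates ("other"). Probability vectors are convex
    coefficients: position = p1*a + p2*b + p3*c, so one-hot rows sit exactly
    at their vertex and the uniform vector at the centroid.
    """
    classes = list(classes)
    k = len(classes) + 1
    if vertices is None:
        if k == 3:
            vertices = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        elif k == 4:
            vertices = np.array(
                [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                 [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3]], dtype=float
            )
        else:
            raise ValueError("2 or 3 named classes required")
    vertices = np.asarray(vertices, dtype=float)
    if vertices.shape[0] != k:
        raise ValueError("need one vertex per class plus one for 'other'")
    if k == 3:
        area = np.cross(vertices[1] - vertices[0], vertices[2] - vertices[0])
        if np.isclose(area, 0):
            raise ValueError("vertices are collinear")
    Fv = F[classes].to_numpy()
    other = 1.0 - Fv.sum(axis=1)
    p = np.column_stack([Fv, other])
    if np.any(p < -tol) or np.any(p > 1 + tol):
        raise ValueError("fate probabilities outside [0, 1]: invalid FateMatrix")
    p = np.clip(p, 0.0, 1.0)
    pos = p @ vertices
    out = pd.DataFrame(pos, columns=[f"coord_{i}" for i in range(vertices.shape[1])])
    out.attrs["vertices"] = vertices
    out.attrs["classes"] = classes + ["other"]
    return out


def max_fate(F: pd.DataFrame):
    """Per-cell (argmax class, max probability); lexicographic tie-break."""
    cols = sorted(F.columns)
    M = F[cols].to_numpy()
    best = M.argmax(axis=1)  # first max = lexicographic winner
    labels = np.array([cols[b] for b in best], dtype=object)
    return labels, M[np.arange(len(best)), best]


class StationaryFateOT(BaseEstimator):
    """Single-run stationary OT fate estimator.

    ``fit(X, growth=..., sink_mask=..., sink_classes=...)`` stores
    ``plan_`` (TransitionPlan) and ``fates_`` (cells x classes DataFrame).
    """

    def __init__(self, epsilon=0.025, regularization_kind="entropic", dt=None,
                 sink_fraction=0.05, cost_normalize=True,
                 sinkhorn_max_iter=30000, sinkhorn_tol=1e-4):
        self.epsilon = epsilon
        self.regularization_kind = regularization_kind
        self.dt = dt
        self.sink_fraction = sink_fraction
        self.cost_normalize = cost_normalize
        self.sinkhorn_max_iter = sinkhorn_max_iter
        self.sinkhorn_tol = sinkhorn_tol

    def _params(self):
        return OTParams(self.epsilon, self.regularization_kind, self.dt,
                        self.sink_fraction, self.cost_normalize,
                        self.sinkhorn_max_iter, self.sinkhorn_tol)

    def fit(self, X, growth=None, sink_mask=None, sink_classes=None,
            consensus_pt=None, lineage_labels=None):
        if sink_mask is None:
            if consensus_pt is None or lineage_labels is None:
                raise ValueError("provide sink_mask/sink_classes or pseudotime+lineages")
            sink_mask, sink_classes = select_sinks(consensus_pt, lineage_labels,
                                                   self.sink_fraction)
        self.plan_ = stationary_ot(X, growth, sink_mask, sink_classes, self._params())
        self.fates_ = fate_probabilities(self.plan_)
        return self

    def predict_proba(self, X=None):
        return self.fates_.to_numpy()

    def predict(self, X=None):
        labels, _ = max_fate(self.fates_)
        return labels


class ConsensusFateOT(StationaryFateOT):
    """Partition-consensus stationary OT (n_subsets x n_repeats)."""

    def __init__(self, epsilon=0.025, regularization_kind="entropic", dt=None,
                 sink_fraction=0.05, cost_normalize=True,
                 sinkhorn_max_iter=5000, sinkhorn_tol=1e-8,
                 n_subsets=10, n_repeats=10, seed=0):
        super().__init__(epsilon, regularization_kind, dt, sink_fraction,
                         cost_normalize, sinkhorn_max_iter, sinkhorn_tol)
        self.n_subsets = n_subsets
        self.n_repeats = n_repeats
        self.seed = seed

    def fit(self, X, growth=None, sink_mask=None, sink_classes=None,
            consensus_pt=None, lineage_labels=None):
        if sink_mask is None:
            if consensus_pt is None or lineage_labels is None:
                raise ValueError("provide sink_mask/sink_classes or pseudotime+lineages")
            sink_mask, sink_classes = select_sinks(consensus_pt, lineage_labels,
                                                   self.sink_fraction)
        self.fates_, self.runs_, self.report_ = consensus_fates(
            X, growth, sink_mask, sink_classes, self._params(),
            n_subsets=self.n_subsets, n_repeats=self.n_repeats, seed=self.seed,
        )
        return self
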