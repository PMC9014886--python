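import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import linprog

import rootfate as rf
from rootfate import fate
from rootfate import simulate as sim
from rootfate.fate import (
    OTParams,
    barycentric_project,
    consensus_fates,
    default_dt,
    fate_probabilities,
    max_fate,
    quadratic_ot,
    select_sinks,
    sinkhorn_log,
    stationary_ot,
)
from rootfate.preprocess import log_normalize, pca_embed


def lp_transport(C, mu, nu):
    """Exact linear-program optimal transport (oracle)."""
    n, m = C.shape
    Aeq = np.zeros((n + m, n * m))
    for i in range(n):
        Aeq[i, i * m : (i + 1) * m] = 1
    for j in range(m):
        Aeq[n + j, j::m] = 1
    res = linprog(C.ravel(), A_eq=Aeq, b_eq=np.concatenate([mu, nu]),
                  bounds=(0, None), method="highs")
    assert res.success
    return res.x.reshape(n, m)


class TestSelectSinks:
    def test_counts(self):
        pt = np.concatenate([np.linspace(0, 1, 100), np.linspace(0, 1, 200)])
        labels = np.array(["a"] * 100 + ["b"] * 200, dtype=object)
        mask, classes = select_sinks(pt, labels, 0.05)
        assert (classes[mask] == "a").sum() == 5
        assert (classes[mask] == "b").sum() == 10
        mask2, _ = select_sinks(pt, labels, 1e-9)
        assert mask2.sum() == 2  # ceil forces >= 1 per lineage

    def test_sinks_are_most_differentiated(self):
        pt = np.arange(40) / 40
        labels = np.array(["a"] * 40, dtype=object)
        mask, _ = select_sinks(pt, labels, 0.05)
        assert set(np.where(mask)[0]) == {38, 39}


class TestSolvers:
    def test_entropic_matches_lp_at_small_epsilon(self):
        rng = np.random.default_rng(1)
        for n in (2, 6, 10):
            C = np.abs(rng.normal(size=(n, n)))
            mu = rng.dirichlet(np.ones(n))
            nu = rng.dirichlet(np.ones(n))
            gamma = sinkhorn_log(C, mu, nu, 1e-6, max_iter=200_000, tol=1e-9)
            oracle = lp_transport(C, mu, nu)
            assert np.abs(gamma - oracle).max() <= 1e-4

    def test_marginal_feasibility(self):
        rng = np.random.default_rng(2)
        n = 40
        C = np.abs(rng.normal(size=(n, n)))
        C /= C.mean()
        mu = rng.dirichlet(np.ones(n))
        nu = rng.dirichlet(np.ones(n))
        tol = 1e-6
        gamma = sinkhorn_log(C, mu, nu, 0.025, tol=tol)
        assert np.abs(gamma.sum(1) - mu).sum() <= tol
        assert np.abs(gamma.sum(0) - nu).sum() <= tol

    def test_quadratic_marginals(self):
        rng = np.random.default_rng(3)
        n = 30
        C = np.abs(rng.normal(size=(n, n)))
        C /= C.mean()
        mu = rng.dirichlet(np.ones(n))
        nu = rng.dirichlet(np.ones(n))
        gamma = quadratic_ot(C, mu, nu, 0.05)
        assert np.abs(gamma.sum(1) - mu).sum() <= 1e-4
        assert np.abs(gamma.sum(0) - nu).sum() <= 1e-4
        assert np.all(gamma >= 0)


class TestStationaryOT:
    def _toy(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        growth = np.full(n, 0.2)
        sink = np.zeros(n, bool)
        sink[:6] = True
        classes = np.array(["a", "b", "c"] * 2 + [""] * (n - 6), dtype=object)
        return X, growth, sink, classes

    def test_cost_normalized_to_unit_mean(self):
        X, growth, sink, classes = self._toy()
        plan = stationary_ot(X, growth, sink, classes)
        assert plan.cost_mean == pytest.approx(1.0)

    def test_default_dt_balances_growth_and_absorption(self):
        growth = np.full(200, 0.205)
        sink = np.zeros(200, bool)
        sink[:10] = True  # 5% sinks
        dt = default_dt(growth, sink)
        assert np.exp(dt * 0.205) * 0.95 == pytest.approx(1.0, abs=1e-9)
        assert dt == pytest.approx(0.25, rel=0.02)  # the 6-hour step

    def test_symmetry(self):
        """A mirror-symmetric problem yields a mirror-symmetric coupling."""
        rng = np.random.default_rng(4)
        half = rng.normal(size=(20, 2)) + [5, 0]
        X = np.vstack([half, half * [-1, 1]])
        growth = np.full(40, 0.2)
        sink = np.zeros(40, bool)
        sink[[0, 20]] = True
        classes = np.full(40, "", dtype=object)
        classes[0] = "right"
        classes[20] = "left"
        plan = stationary_ot(X, growth, sink, classes)
        perm = np.r_[np.arange(20, 40), np.arange(0, 20)]
        np.testing.assert_allclose(
            plan.coupling, plan.coupling[np.ix_(perm, perm)], atol=1e-6
        )

    def test_transition_rows_stochastic_and_sinks_absorbing(self):
        X, growth, sink, classes = self._toy()
        plan = stationary_ot(X, growth, sink, classes)
        np.testing.assert_allclose(plan.transition.sum(1), 1.0, atol=1e-8)
        for i in np.where(sink)[0]:
            assert plan.transition[i, i] == 1.0


class TestFateProbabilities:
    def test_rows_sum_to_one_and_sinks_one_hot(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 4))
        growth = np.full(50, 0.2)
        sink = np.zeros(50, bool)
        sink[:4] = True
        classes = np.array(["a", "a", "b", "b"] + [""] * 46, dtype=object)
        F = fate_probabilities(stationary_ot(X, growth, sink, classes))
        np.testing.assert_allclose(F.sum(1), 1.0, atol=1e-8)
        np.testing.assert_allclose(F.to_numpy()[0], [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(F.to_numpy()[2], [0.0, 1.0], atol=1e-12)

    def test_matches_random_walk_oracle(self):
        """20-cell chain: linear-system absorption vs Monte-Carlo frequencies."""
        rng = np.random.default_rng(6)
        n = 20
        P = rng.dirichlet(np.ones(n), size=n)
        sink_idx = [0, 1, 2, 3]
        classes = np.array(["a", "a", "b", "b"] + [""] * 16, dtype=object)
        sink = np.zeros(n, bool)
        sink[sink_idx] = True
        P[sink] = 0.0
        P[sink_idx, sink_idx] = 1.0
        plan = fate.TransitionPlan(
            coupling=P, transition=P, sink_mask=sink, sink_classes=classes,
            mu=np.full(n, 1 / n), nu=np.full(n, 1 / n), cost_mean=1.0,
            epsilon=0.025, dt=0.25,
        )
        F = fate_probabilities(plan).to_numpy()

        n_walks = 100_000
        start = 10
        states = np.full(n_walks, start)
        cum = P.cumsum(axis=1)
        for _ in range(200):
            active = ~sink[states]
            if not active.any():
                break
            r = rng.random(active.sum())
            states[active] = np.array(
                [np.searchsorted(cum[s], x) for s, x in zip(states[active], r)]
            )
        freq_a = np.isin(states, [0, 1]).mean()
        assert abs(F[start, 0] - freq_a) <= 0.01

    def test_stranded_cells_reported(self):
        P = np.eye(4)
        P[2, 2] = 0.0
        P[2, 3] = 1.0  # cell 2 reaches only cell 3, which self-loops (not a sink)
        sink = np.array([True, False, False, False])
        classes = np.array(["a", "", "", ""], dtype=object)
        plan = fate.TransitionPlan(P, P, sink, classes, np.full(4, 0.25),
                                   np.full(4, 0.25), 1.0, 0.025, 0.25)
        with pytest.raises(RuntimeError, match="no path"):
            fate_probabilities(plan)
        F = fate_probabilities(plan, on_stranded="drop")
        assert np.isnan(F.to_numpy()[1]).all()  # cell 1 self-loops, stranded
        assert sorted(F.attrs["stranded"].tolist()) == [1, 2, 3]


class TestConsensus:
    def test_single_partition_equals_full_run(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 5))
        growth = np.full(80, 0.2)
        sink = np.zeros(80, bool)
        sink[:4] = True
        classes = np.array(["a", "a", "b", "b"] + [""] * 76, dtype=object)
        single = fate_probabilities(stationary_ot(X, growth, sink, classes))
        cons, runs, report = consensus_fates(X, growth, sink, classes,
                                             n_subsets=1, n_repeats=1, seed=0)
        np.testing.assert_allclose(cons.to_numpy(), single.to_numpy(), atol=1e-9)
        assert report["argmax_agreement"] == 1.0

    def test_consensus_rows_sum_to_one(self, clean_atlas, clean_embedding, lineage_rates):
        _, adata, truth = clean_atlas
        lin = truth["lineage"].to_numpy()
        growth = sim.simulate_growth_rates(truth, lineage_rates)
        mask, classes = select_sinks(truth["pseudotime"].to_numpy(), lin, 0.05)
        cons, _, _ = consensus_fates(clean_embedding, growth, mask, classes,
                                     n_subsets=2, n_repeats=2, seed=0)
        np.testing.assert_allclose(cons.sum(1), 1.0, atol=1e-8)

    def test_sink_shortage_error(self):
        pt = np.linspace(0, 1, 30)
        labels = np.array(["a"] * 30, dtype=object)
        mask, classes = select_sinks(pt, labels, 0.05)  # 2 sinks only
        X = np.random.default_rng(0).normal(size=(30, 3))
        with pytest.raises(RuntimeError, match="fewer sinks"):
            consensus_fates(X, np.full(30, 0.2), mask, classes,
                            n_subsets=5, n_repeats=1, seed=0)


class TestRobustness:
    def test_epsilon_and_dt_factor_two(self, clean_atlas, clean_embedding, lineage_rates):
        """Doubling/halving epsilon or dt barely moves the fate field."""
        _, adata, truth = clean_atlas
        lin = truth["lineage"].to_numpy()
        growth = sim.simulate_growth_rates(truth, lineage_rates)
        mask, classes = select_sinks(truth["pseudotime"].to_numpy(), lin, 0.05)
        base = fate_probabilities(
            stationary_ot(clean_embedding, growth, mask, classes, OTParams())
        ).to_numpy()
        dt0 = default_dt(growth, mask)
        variants = [OTParams(epsilon=0.05), OTParams(epsilon=0.0125),
                    OTParams(dt=2 * dt0), OTParams(dt=dt0 / 2)]
        for p in variants:
            F = fate_probabilities(
                stationary_ot(clean_embedding, growth, mask, classes, p)
            ).to_numpy()
            r = np.corrcoef(base.ravel(), F.ravel())[0, 1]
            assert r > 0.95

    def test_quadratic_regularization_agrees(self, clean_atlas, clean_embedding,
                                             lineage_rates):
        _, adata, truth = clean_atlas
        lin = truth["lineage"].to_numpy()
        growth = sim.simulate_growth_rates(truth, lineage_rates)
        mask, classes = select_sinks(truth["pseudotime"].to_numpy(), lin, 0.05)
        base = fate_probabilities(
            stationary_ot(clean_embedding, growth, mask, classes, OTParams())
        ).to_numpy()
        Fq = fate_probabilities(
            stationary_ot(clean_embedding, growth, mask, classes,
                          OTParams(regularization_kind="quadratic", epsilon=0.05)),
            on_stranded="drop",
        ).to_numpy()
        ok = ~np.isnan(Fq).any(axis=1)
        r = np.corrcoef(base[ok].ravel(), Fq[ok].ravel())[0, 1]
        assert r > 0.9

    def test_late_cells_committed(self, clean_atlas, clean_embedding, lineage_rates):
        _, adata, truth = clean_atlas
        lin = truth["lineage"].to_numpy()
        growth = sim.simulate_growth_rates(truth, lineage_rates)
        mask, classes = select_sinks(truth["pseudotime"].to_numpy(), lin, 0.05)
        F = fate_probabilities(
            stationary_ot(clean_embedding, growth, mask, classes, OTParams())
        )
        cols = list(F.columns)
        own = F.to_numpy()[np.arange(adata.n_obs), [cols.index(l) for l in lin]]
        late = truth["pseudotime"].to_numpy() > 0.7
        assert (own[late] >= 0.9).mean() >= 0.9


class TestBarycentric:
    def test_vertices_and_centroid(self):
        F = pd.DataFrame({"a": [1.0, 1 / 3], "b": [0.0, 1 / 3]})
        out = barycentric_project(F, ["a", "b"])
        v = out.attrs["vertices"]
        np.testing.assert_allclose(out.iloc[0].to_numpy(), v[0], atol=1e-12)
        np.testing.assert_allclose(out.iloc[1].to_numpy(), v.mean(axis=0), atol=1e-12)

    @given(st.integers(0, 10_000))
    def test_random_simplex_points_inside_triangle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(3), size=20)
        F = pd.DataFrame({"a": p[:, 0], "b": p[:, 1]})
        out = barycentric_project(F, ["a", "b"])
        v = out.attrs["vertices"]
        # recover barycentric coordinates: all must lie in [0, 1]
        T = np.column_stack([v[0] - v[2], v[1] - v[2]])
        for pos in out.to_numpy():
            lam = np.linalg.solve(T, pos - v[2])
            lam = np.append(lam, 1 - lam.sum())
            assert np.all(lam >= -1e-9) and np.all(lam <= 1 + 1e-9)

    def test_tetrahedral_variant(self):
        F = pd.DataFrame({"a": [1.0], "b": [0.0], "c": [0.0]})
        out = barycentric_project(F, ["a", "b", "c"])
        assert out.shape[1] == 3
        np.testing.assert_allclose(out.iloc[0].to_numpy(),
                                   out.attrs["vertices"][0], atol=1e-12)

    def test_invalid_probabilities_error(self):
        F = pd.DataFrame({"a": [0.9], "b": [0.9]})  # sums beyond 1
        with pytest.raises(ValueError, match="outside"):
            barycentric_project(F, ["a", "b"])

    def test_collinear_vertices_error(self):
        F = pd.DataFrame({"a": [1.0], "b": [0.0]})
        with pytest.raises(ValueError, match="collinear"):
            barycentric_project(F, ["a", "b"],
                                vertices=np.array([[0, 0], [1, 1], [2, 2]], float))


class TestMaxFate:
    def test_one_hot_and_tie(self):
        F = pd.DataFrame({"b": [1.0, 0.25], "a": [0.0, 0.25],
                          "d": [0.0, 0.25], "c": [0.0, 0.25]})
        labels, probs = max_fate(F)
        assert labels[0] == "b" and probs[0] == 1.0
        assert labels[1] == "a" and probs[1] == 0.25  # lexicographic tie-break

    def test_matches_truth_for_mature_cells(self, clean_atlas, clean_embedding,
                                            lineage_rates):
        _, adata, truth = clean_atlas
        lin = truth["lineage"].to_numpy()
        growth = sim.simulate_growth_rates(truth, lineage_rates)
        mask, classes = select_sinks(truth["pseudotime"].to_numpy(), lin, 0.05)
        F = fate_probabilities(
            stationary_ot(clean_embedding, growth, mask, classes, OTParams())
        )
        labels, _ = max_fate(F)
        post = truth["pseudotime"].to_numpy() > 0.5
        assert (labels[post] == lin[post]).mean() >= 0.95
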