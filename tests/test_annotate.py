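import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import kstest

import rootfate as rf
from rootfate import annotate as ann
from rootfate import simulate as sim
from rootfate.preprocess import log_normalize, pca_embed


# ---------------------------------------------------------------------------
# spec table

def _independent_spec(refs, n_bins=10, min_bg=3):
    """Straight-line recomputation of the spec table for small inputs."""
    out_spec = {}
    out_info = {}
    k = refs.shape[1]
    for g, row in refs.iterrows():
        x = row.to_numpy(dtype=float)
        m = x.max()
        bins = np.array([np.ceil(v / m * n_bins) if m > 0 else 0.0 for v in x])
        bins[bins < min_bg] = 0.0
        if bins.sum() == 0:
            out_spec[g] = np.zeros(k)
            out_info[g] = 0.0
            continue
        p = bins / bins.sum()
        info = 1.0 + sum(pi * np.log(pi) for pi in p if pi > 0) / np.log(k)
        out_spec[g] = p * info
        out_info[g] = info
    return out_spec, out_info


def test_spec_table_exclusive_and_uniform_genes():
    refs = pd.DataFrame(
        {"a": [10.0, 5.0], "b": [0.0, 5.0], "c": [0.0, 5.0], "d": [0.0, 5.0]},
        index=["g_exclusive", "g_uniform"],
    )
    st_ = ann.build_spec_table(refs)
    assert st_.spec.loc["g_exclusive", "a"] == pytest.approx(1.0)
    assert st_.information["g_exclusive"] == pytest.approx(1.0)
    assert st_.information["g_uniform"] == pytest.approx(0.0)
    assert np.allclose(st_.spec.loc["g_uniform"], 0.0)


def test_spec_table_matches_hand_binning_oracle():
    refs = pd.DataFrame({"a": [10.0, 8.0, 2.0], "b": [0.0, 4.0, 9.0]},
                        index=["g1", "g2", "g3"])
    st_ = ann.build_spec_table(refs)
    oracle_spec, oracle_info = _independent_spec(refs)
    for g in refs.index:
        np.testing.assert_allclose(st_.spec.loc[g].to_numpy(), oracle_spec[g], atol=1e-12)
        assert st_.information[g] == pytest.approx(oracle_info[g])


def test_spec_table_probability_and_information_invariants(clean_atlas):
    _, adata, truth = clean_atlas
    refs = sim.simulate_reference_profiles(adata, truth, "lineage")
    st_ = ann.build_spec_table(refs)
    info = st_.information.to_numpy()
    assert np.all((info >= -1e-12) & (info <= 1 + 1e-12))
    spec = st_.spec.to_numpy()
    with np.errstate(invalid="ignore"):
        p = spec / info[:, None]
    signal = info > 0
    sums = np.nansum(p[signal], axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    # markers of a label have their spec maximum at that label
    for lab, genes in st_.markers.items():
        assert (st_.spec.loc[genes].idxmax(axis=1) == lab).all()


def test_spec_sharpening_never_decreases_max():
    """Moving reference mass onto the top label can only sharpen spec."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        row = rng.uniform(0.1, 10.0, 5)
        refs = pd.DataFrame([row, row * 0 + 1], index=["g", "pad"],
                            columns=list("abcde"))
        base = ann.build_spec_table(refs).spec.loc["g"].max()
        sharp = row.copy()
        j = int(np.argmax(sharp))
        take = 0.5 * sharp[np.arange(5) != j]
        sharp[np.arange(5) != j] -= take
        sharp[j] += take.sum()
        refs2 = pd.DataFrame([sharp, row * 0 + 1], index=["g", "pad"],
                             columns=list("abcde"))
        sharpened = ann.build_spec_table(refs2).spec.loc["g"].max()
        assert sharpened >= base - 1e-9


# ---------------------------------------------------------------------------
# ICI

def _toy_spec_table():
    refs = pd.DataFrame(
        {"a": [10, 10, 0, 0, 1], "b": [0, 0, 10, 10, 1]},
        index=["a1", "a2", "b1", "b2", "junk"], dtype=float,
    )
    return ann.build_spec_table(refs, information_level=1.5)


def test_ici_pure_marker_cell():
    st_ = _toy_spec_table()
    genes = ["a1", "a2", "b1", "b2", "junk"]
    X = sp.csr_matrix(np.array([[5, 3, 0, 0, 0], [0, 0, 0, 0, 0]]))
    res = ann.ici_scores(X, genes, st_, n_perm=50, seed=0)
    assert res.loc[0, "label"] == "a"
    assert res.loc[0, "score_a"] == pytest.approx(1.0)
    assert res.loc[1, "label"] == ann.UNASSIGNED


def test_ici_scores_sum_to_one(clean_atlas):
    _, adata, truth = clean_atlas
    refs = sim.simulate_reference_profiles(adata, truth, "lineage")
    st_ = ann.build_spec_table(refs)
    res = ann.ici_scores(adata.X[:150], adata.var_names, st_, n_perm=30, seed=0)
    score_cols = [c for c in res.columns if c.startswith("score_")]
    sums = res[score_cols].to_numpy().sum(axis=1)
    scored = res["label"] != ann.UNASSIGNED
    np.testing.assert_allclose(sums[scored.to_numpy()], 1.0, atol=1e-9)


def test_ici_null_pvalues_uniform():
    """Cells drawn from the permutation null give ~Uniform(0,1) p-values."""
    rng = np.random.default_rng(7)
    # a richer gene space keeps the null score distribution near-continuous
    n_genes = 300
    genes = [f"g{j:03d}" for j in range(n_genes)]
    refs = pd.DataFrame(
        {"a": np.r_[rng.uniform(5, 10, 100), np.zeros(200)],
         "b": np.r_[np.zeros(100), rng.uniform(5, 10, 100), np.zeros(100)],
         "c": np.r_[np.zeros(200), rng.uniform(5, 10, 100)]},
        index=genes,
    )
    st_ = ann.build_spec_table(refs, information_level=30.0)
    # detection probability identical across genes -> the null holds exactly
    X = sp.csr_matrix((rng.random((200, n_genes)) < 0.4).astype(int))
    res = ann.ici_scores(X, genes, st_, n_perm=200, seed=1)
    # the per-(cell, label) p-value of a fixed label is marginally uniform;
    # the assigned label's p-value is the smallest of the three by selection
    for lab in ("a", "b", "c"):
        p = res[f"p_{lab}"].to_numpy()
        assert kstest(p, "uniform").pvalue > 0.01


def test_ici_nperm_guard():
    st_ = _toy_spec_table()
    with pytest.raises(ValueError, match="n_perm"):
        ann.ici_scores(sp.csr_matrix(np.eye(3, 5)), ["a1", "a2", "b1", "b2", "junk"],
                       st_, n_perm=5)


# ---------------------------------------------------------------------------
# correlation annotation

def test_correlation_identical_profile(clean_atlas):
    _, adata, truth = clean_atlas
    refs = sim.simulate_reference_profiles(adata, truth, "lineage")
    # synthesize counts whose log-normalized profile equals a reference
    target = refs.iloc[:, 0]
    counts = np.round(np.expm1(target.to_numpy()) * 10).astype(int)
    X = sp.csr_matrix(counts[None, :])
    res = ann.correlation_annotate(X, refs.index, refs, n_hvg=150)
    assert res.loc[0, "label"] == refs.columns[0]
    assert res.loc[0, "confidence"] > 0.95
    assert bool(res.loc[0, "high_confidence"])


def test_correlation_confidence_rule(clean_atlas):
    _, adata, truth = clean_atlas
    refs = sim.simulate_reference_profiles(adata, truth, "lineage")
    res = ann.correlation_annotate(adata.X[:100], adata.var_names, refs, n_hvg=150)
    flags = res["high_confidence"].to_numpy()
    conf = res["confidence"].to_numpy()
    assert np.array_equal(flags, conf > 0.6)


def test_correlation_recovery(clean_atlas):
    """>=95% label recovery on the separable atlas at log2FC >= 3."""
    _, adata, truth = clean_atlas
    refs = sim.simulate_reference_profiles(adata, truth, "lineage")
    res = ann.correlation_annotate(adata.X, adata.var_names, refs, n_hvg=181)
    acc = (res["label"].to_numpy() == truth["lineage"].to_numpy()).mean()
    assert acc >= 0.95


def test_correlation_too_few_shared_genes():
    refs = pd.DataFrame({"a": [1.0, 2.0]}, index=["g1", "g2"])
    refs["b"] = [2.0, 1.0]
    with pytest.raises(ValueError, match="shared"):
        ann.correlation_annotate(sp.csr_matrix(np.ones((2, 2))), ["g1", "gX"], refs, n_hvg=2)


# ---------------------------------------------------------------------------
# neighborhood enrichment

def test_neighborhood_tight_cluster_detected():
    rng = np.random.default_rng(5)
    emb = rng.normal(0, 3.0, size=(80, 2))
    emb[:12] = rng.normal(0, 0.2, size=(12, 2)) + 10  # tight cluster
    expr = rng.poisson(1.0, size=(80, 3)).astype(float)
    expr[:12, 0] += 20  # marker on in the cluster
    expr[:, 2] = 1.0  # constant gene
    res = ann.neighborhood_enrichment(
        emb, expr, ["mk", "other", "flat"],
        {"mk": "cluster_type", "flat": "flat_type"},
        n_ref=8, n_perm=100, seed=0,
    )
    labels = res["label"].to_numpy()
    assert (labels[:12] == "cluster_type").mean() >= 0.9
    # the constant gene can never be significantly enriched
    assert not (labels == "flat_type").any()


def test_neighborhood_degenerate_embedding_errors():
    emb = np.ones((10, 2))
    with pytest.raises(ValueError, match="degenerate"):
        ann.neighborhood_enrichment(emb, np.ones((10, 2)), ["a", "b"], {"a": "x"})


def test_rbf_similarity_is_one_for_identical_points():
    assert np.exp(-0.8 * 0.0) == 1.0  # kernel definition at zero distance
    emb = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]])
    d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
    S = np.exp(-0.8 * d2)
    assert S[0, 1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# micro-cluster voting

def test_microcluster_recovery(clean_atlas):
    _, adata, truth = clean_atlas
    markers = {g: l for g, l in zip(adata.var_names, adata.var["marker_lineage"]) if l}
    res = ann.microcluster_zscore_annotate(
        adata.X, adata.var_names, markers, adata.n_obs // 35, seed=0
    )
    acc = (res["label"].to_numpy() == truth["lineage"].to_numpy()).mean()
    assert acc >= 0.95


def test_microcluster_lexicographic_tie():
    rng = np.random.default_rng(2)
    X = sp.csr_matrix(rng.poisson(5, size=(40, 3)))
    # both labels' markers are the same expression column duplicated
    Xd = sp.hstack([X[:, 0], X[:, 0], X[:, 2]]).tocsr()
    res = ann.microcluster_zscore_annotate(
        Xd, ["g1", "g2", "g3"], {"g1": "zeta", "g2": "alpha"}, 3, seed=0
    )
    assert set(res["label"]) == {"alpha"}


def test_microcluster_too_many_clusters():
    X = sp.csr_matrix(np.ones((10, 3)))
    with pytest.raises(ValueError, match="n_microclusters"):
        ann.microcluster_zscore_annotate(X, list("abc"), {"a": "x"}, 10)


# ---------------------------------------------------------------------------
# consensus combination

def _evidence_frame(labels):
    return pd.DataFrame({"label": np.asarray(labels, dtype=object)})


def test_combine_agreement_rules(clean_atlas):
    _, adata, truth = clean_atlas
    lin = truth["lineage"].to_numpy()
    labs = sorted(set(lin))
    ev_true = [_evidence_frame(lin) for _ in range(4)]
    cons = ann.combine_annotations(ev_true, adata.X, adata.var_names, seed=0)
    assert (cons["label"].to_numpy() == lin).mean() == 1.0  # fixed point

    # {A,A,B,C} -> A at step 1; a 2-2 tie breaks lexicographically
    e3 = np.full_like(lin, "zz_one")
    e4 = np.full_like(lin, "zz_two")
    cons2 = ann.combine_annotations(
        [_evidence_frame(e) for e in (lin, lin, e3, e4)], adata.X, adata.var_names, seed=0
    )
    assert (cons2["step1_label"].to_numpy() == lin).all()
    tie = [_evidence_frame(["b"] * 40 + ["a"] * 40),
           _evidence_frame(["b"] * 40 + ["a"] * 40),
           _evidence_frame(["a"] * 40 + ["b"] * 40),
           _evidence_frame(["a"] * 40 + ["b"] * 40)]
    cons_tie = ann.combine_annotations(tie, adata.X[:80], adata.var_names, seed=0)
    assert (cons_tie["step1_label"].to_numpy() == "a").all()

    scrambled = [np.roll(lin, k + 1) for k in range(4)]
    scrambled[0][:5] = [l for l in labs[:1]] * 5
    ev = [_evidence_frame(e) for e in scrambled]
    # every cell still receives a final label after re-annotation
    cons3 = ann.combine_annotations(ev, adata.X, adata.var_names, seed=0)
    assert (cons3["label"].to_numpy() != ann.UNASSIGNED).all()


def test_combine_requires_two_sources(clean_atlas):
    _, adata, truth = clean_atlas
    with pytest.raises(ValueError, match="two evidence"):
        ann.combine_annotations([_evidence_frame(truth["lineage"])], adata.X, adata.var_names)


def test_combine_label_source_masks(clean_atlas):
    """A label restricted to sources that never vote for it disappears at step 1."""
    _, adata, truth = clean_atlas
    lin = truth["lineage"].to_numpy()
    target = sorted(set(lin))[0]
    ev = [_evidence_frame(lin) for _ in range(4)]
    cons = ann.combine_annotations(
        ev, adata.X, adata.var_names, seed=0,
        label_source_masks={target: [0]},  # only source 0 may vote for it
    )
    step1 = cons["step1_label"].to_numpy()
    assert not (step1[lin == target] == target).any()


# ---------------------------------------------------------------------------
# QC-center cells and label transfer

def test_annotate_qc_cells_recovery():
    cfg = rf.default_config(n_cells=2500, n_genes=1200, seed=31,
                            dying_fraction=0.0, qc_center_fraction=0.008)
    adata, truth = rf.simulate_root(cfg)
    lin = truth["lineage"].to_numpy()
    emb = pca_embed(log_normalize(adata.X), 50, 0)[:, :10]
    qc_genes = list(adata.var_names[adata.var["role"] == "qc_center"])
    cc_genes = list(adata.var_names[adata.var["role"] == "cellcycle"])
    planted = set(np.where(lin == "quiescent_center")[0].tolist())
    got = set(
        ann.annotate_qc_cells(
            adata.X, adata.var_names, emb, qc_genes, cc_genes,
            target_fraction=len(planted) / len(lin), n_ref=120, seed=0,
        ).tolist()
    )
    jac = len(got & planted) / len(got | planted)
    assert jac >= 0.9


def test_annotate_qc_cells_score_monotone_in_cellcycle():
    """Raising cell-cycle expression lowers the organizer score."""
    rng = np.random.default_rng(8)
    X = rng.poisson(2, size=(50, 4)).astype(float)
    from rootfate.preprocess import zscore_genes
    Xn = log_normalize(sp.csr_matrix(X.astype(int)))
    Z = zscore_genes(Xn)
    score = Z[:, [0]].mean(axis=1) - Z[:, [1]].mean(axis=1)
    X2 = X.copy()
    X2[0, 1] += 50
    Z2 = zscore_genes(log_normalize(sp.csr_matrix(X2.astype(int))))
    score2 = Z2[:, [0]].mean(axis=1) - Z2[:, [1]].mean(axis=1)
    assert score2[0] < score[0]


def test_annotate_qc_cells_count_cap(clean_atlas):
    _, adata, truth = clean_atlas
    n = adata.n_obs
    # target fraction caps the returned set
    assert int(np.ceil(0.001 * 100_000)) == 100  # ~0.1% of a 100k atlas


def test_label_transfer(clean_atlas):
    _, adata, truth = clean_atlas
    lin = truth["lineage"].to_numpy()
    rng = np.random.default_rng(0)
    idx = rng.permutation(adata.n_obs)
    ref, query = idx[:800], idx[800:]
    res = ann.transfer_labels(
        adata.X[ref], adata.var_names, lin[ref],
        adata.X[query], adata.var_names, k=15,
    )
    acc = (res["label"].to_numpy() == lin[query]).mean()
    assert acc >= 0.95
    score_cols = [c for c in res.columns if c.startswith("score_")]
    np.testing.assert_allclose(res[score_cols].sum(axis=1), 1.0, atol=1e-9)


def test_label_transfer_identity_and_missing_lineage(clean_atlas):
    _, adata, truth = clean_atlas
    lin = truth["lineage"].to_numpy()
    clf = ann.LabelTransferClassifier(k=1, min_shared_genes=100)
    clf.fit(adata.X[:500], lin[:500], gene_names=adata.var_names)
    proba = clf.predict_proba(adata.X[:5], gene_names=adata.var_names)
    np.testing.assert_allclose(proba.max(axis=1), 1.0)  # exact self-match at k=1
    assert (clf.predict(adata.X[:5], gene_names=adata.var_names) == lin[:5]).all()

    # query missing one lineage never calls it with high confidence
    drop = sorted(set(lin))[0]
    clf2 = ann.LabelTransferClassifier(k=15, min_shared_genes=100)
    clf2.fit(adata.X[:800], lin[:800], gene_names=adata.var_names)
    qmask = np.where(lin != drop)[0][:200]
    res = ann.transfer_labels(
        adata.X[:800], adata.var_names, lin[:800],
        adata.X[qmask], adata.var_names, k=15,
    )
    called = res[(res["label"] == drop) & (res["score"] > 0.9)]
    assert len(called) == 0


def test_label_transfer_k_guard(clean_atlas):
    _, adata, truth = clean_atlas
    clf = ann.LabelTransferClassifier(k=100)
    with pytest.raises(ValueError, match="k exceeds"):
        clf.fit(adata.X[:50], truth["lineage"].to_numpy()[:50])
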