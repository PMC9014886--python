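"""Multi-evidence cell-type/stage annotation and consensus combination.

Four evidence sources are implemented:

* **ICI** — an Index-of-Cell-Identity style score from a gene x label
  specificity ("spec") table built by binning reference expression (10 bins,
  minimum background bin 3) and weighting by a Shannon-style information
  content; permutation p-values, BH-adjusted, flag high-confidence calls.
* **Correlation** — Pearson correlation of each cell against
  whole-transcriptome reference profiles over the most variable genes;
  high confidence above r = 0.6.
* **Neighborhood enrichment** — cluster-free marker enrichment around
  reference cells using an RBF similarity kernel (gamma = 0.8) with a
  5-standard-deviation permutation cutoff.
* **Micro-cluster voting** — k-means micro-clusters (tens of cells each)
  labeled by average marker z-scores.

The consensus keeps any label supported by at least two sources, denoises by
coarse-cluster majority vote, rebuilds reference profiles from confidently
annotated cells, and re-annotates every cell by correlation to the rebuilt
references.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .preprocess import log_normalize, pca_embed, zscore_genes

__all__ = [
    "SpecTable",
    "build_spec_table",
    "ici_scores",
    "correlation_annotate",
    "neighborhood_enrichment",
    "microcluster_zscore_annotate",
    "combine_annotations",
    "annotate_qc_cells",
    "transfer_labels",
    "ICIAnnotator",
    "CorrelationAnnotator",
    "NeighborhoodAnnotator",
    "MicroclusterAnnotator",
    "ConsensusAnnotator",
    "LabelTransferClassifier",
]

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# spec table + ICI

@dataclass
class SpecTable:
    """Gene x label specificity scores with per-gene information content."""

    spec: pd.DataFrame  # genes x labels, spec(g,t) in [0,1]
    information: pd.Series  # I_g in [0,1]
    markers: dict = field(default_factory=dict)  # label -> ordered gene list
    n_bins: int = 10
    min_background_bin: int = 3
    information_level: float = 50.0

    @property
    def labels(self):
        return list(self.spec.columns)


def build_spec_table(
    refs: pd.DataFrame,
    n_bins: int = 10,
    min_background_bin: int = 3,
    information_level: float = 50.0,
) -> SpecTable:
    """Bin reference expression per gene and derive specificity scores.

    Per gene: expression across labels is binned into ``n_bins`` equal-width
    bins on [0, max]; bin indices below ``min_background_bin`` are zeroed;
    p(g,t) = bin/sum(bin); I_g = 1 + sum_t p log p / log(n_labels) (0 for a
    uniform gene, 1 for an exclusive one); spec = p * I_g. The marker set of
    a label collects genes whose spec is maximal at that label, ranked by
    spec descending, until the cumulative spec reaches ``information_level``.
    """
    if refs.shape[1] < 2:
        raise ValueError("at least two reference labels are required")
    V = refs.to_numpy(dtype=float)
    if np.any(V < 0):
        raise ValueError("reference profiles must be non-negative")
    if not np.any(V > 0):
        raise ValueError("all-zero reference matrix")
    n_labels = V.shape[1]
    vmax = V.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        bins = np.ceil(np.where(vmax > 0, V / vmax, 0.0) * n_bins)
    bins[~np.isfinite(bins)] = 0.0
    bins[bins < min_background_bin] = 0.0
    tot = bins.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, bins / tot, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    info = 1.0 + plogp.sum(axis=1) / np.log(n_labels)
    info = np.where(tot.ravel() > 0, info, 0.0)
    spec = p * info[:, None]

    spec_df = pd.DataFrame(spec, index=refs.index, columns=refs.columns)
    info_s = pd.Series(info, index=refs.index, name="information")

    markers = {}
    argmax = spec.argmax(axis=1)
    for j, label in enumerate(refs.columns):
        cand = np.where((argmax == j) & (spec[:, j] > 0))[0]
        order = cand[np.lexsort((refs.index[cand], -spec[cand, j]))]
        cum = np.cumsum(spec[order, j])
        k = int(np.searchsorted(cum, information_level) + 1)
        markers[label] = list(refs.index[order[:k]])
    return SpecTable(spec_df, info_s, markers, n_bins, min_background_bin, information_level)


def ici_scores(
    X,
    gene_names,
    spec_table: SpecTable,
    n_perm: int = 200,
    alpha: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """ICI label scores with permutation p-values per cell.

    Raw score(c,t) = mean over markers of spec(g,t) * 1[x_{c,g} > 0];
    normalized per cell to sum 1. The null permutes each cell's detection
    vector over genes (one shared permutation per repeat); p-values use the
    (count+1)/(n_perm+1) convention and are BH-adjusted across cells.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20 for a usable null")
    X = X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X))
    gene_names = pd.Index(gene_names)
    labels = spec_table.labels

    present = {}
    for lab in labels:
        genes = [g for g in spec_table.markers[lab] if g in gene_names]
        if len(genes) < len(spec_table.markers[lab]):
            warnings.warn(f"ICI: {len(spec_table.markers[lab]) - len(genes)} markers of "
                          f"{lab!r} absent from counts; subsetting")
        present[lab] = genes

    D = (X > 0).astype(np.float64)  # cells x genes detection
    n_cells = X.shape[0]
    # weight matrix: genes x labels with spec/|markers| at marker positions
    W = np.zeros((len(gene_names), len(labels)))
    for j, lab in enumerate(labels):
        genes = present[lab]
        if not genes:
            continue
        gi = gene_names.get_indexer(genes)
        W[gi, j] = spec_table.spec.loc[genes, lab].to_numpy() / len(genes)
    scores = np.asarray(D @ W)  # cells x labels

    row_tot = scores.sum(axis=1)
    scored = row_tot > 0
    norm = np.zeros_like(scores)
    norm[scored] = scores[scored] / row_tot[scored, None]

    # null: permuted detection vectors, compared on the per-cell normalized
    # (label-share) scale, which is what the label call is based on
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(scores)
    for _ in range(n_perm):
        perm = rng.permutation(len(gene_names))
        s_perm = np.asarray(D @ W[perm])
        tot = s_perm.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            s_perm = np.where(tot > 0, s_perm / tot, 0.0)
        exceed += s_perm >= norm
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    best = np.argmax(norm, axis=1)
    label_arr = np.array([labels[b] for b in best], dtype=object)
    label_arr[~scored] = UNASSIGNED
    p_best = pvals[np.arange(n_cells), best]
    adj = np.full(n_cells, 1.0)
    if scored.any():
        adj[scored] = multipletests(p_best[scored], method="fdr_bh")[1]

    out = pd.DataFrame(norm, columns=[f"score_{l}" for l in labels])
    for j, l in enumerate(labels):
        out[f"p_{l}"] = pvals[:, j]
    out["label"] = label_arr
    out["p_value"] = p_best
    out["adj_p_value"] = adj
    out["high_confidence"] = scored & (adj < alpha)
    out["confidence"] = norm[np.arange(n_cells), best]
    return out


# ---------------------------------------------------------------------------
# correlation annotation

def _rows_vs_profiles_pearson(Xn: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Pearson r of each row of Xn (cells x genes) vs each column of P."""
    Xc = Xn - Xn.mean(axis=1, keepdims=True)
    Pc = P - P.mean(axis=0, keepdims=True)
    xn = np.sqrt((Xc**2).sum(axis=1))
    pn = np.sqrt((Pc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc @ Pc) / np.outer(xn, pn)
    return R


def correlation_annotate(
    X,
    gene_names,
    refs: pd.DataFrame,
    n_hvg: int = 181,
    confidence_threshold: float = 0.6,
) -> pd.DataFrame:
    """Label each cell by its best-correlated reference profile.

    Restricted to the ``n_hvg`` genes most variable across reference labels.
    The same operation serves cell type, developmental zone/section, and
    ploidy references. Cells with a constant expression vector on the HVG
    set are unassigned.
    """
    gene_names = pd.Index(gene_names)
    shared = refs.index.intersection(gene_names)
    if len(shared) < n_hvg:
        raise ValueError(
            f"only {len(shared)} genes shared between counts and references (< n_hvg={n_hvg})"
        )
    refs_s = refs.loc[shared]
    var = refs_s.to_numpy().var(axis=1)
    order = np.lexsort((shared, -var))
    hvg = shared[order[:n_hvg]]

    Xn = log_normalize(X).toarray()[:, gene_names.get_indexer(hvg)]
    R = _rows_vs_profiles_pearson(Xn, refs.loc[hvg].to_numpy())
    finite = np.isfinite(R).all(axis=1)
    R_safe = np.where(np.isfinite(R), R, -np.inf)
    best = np.argmax(R_safe, axis=1)
    labels = np.array([refs.columns[b] for b in best], dtype=object)
    best_r = R_safe[np.arange(len(labels)), best]
    labels[~finite & ~np.isfinite(best_r)] = UNASSIGNED
    labels[~np.isfinite(best_r)] = UNASSIGNED
    out = pd.DataFrame(R_safe, columns=[f"r_{c}" for c in refs.columns])
    out["label"] = labels
    out["confidence"] = np.where(np.isfinite(best_r), best_r, np.nan)
    out["high_confidence"] = np.isfinite(best_r) & (best_r > confidence_threshold)
    return out


# ---------------------------------------------------------------------------
# neighborhood enrichment

def _select_reference_cells(embedding: np.ndarray, gamma: float, n_ref: int, seed: int):
    """One reference cell per k-means region: the cell with highest average
    RBF similarity to its region (a density medoid)."""
    n_ref = min(n_ref, embedding.shape[0])
    km = KMeans(n_clusters=n_ref, n_init=4, random_state=seed).fit(embedding)
    refs = []
    for c in range(n_ref):
        idx = np.where(km.labels_ == c)[0]
        sub = embedding[idx]
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
        sim = np.exp(-gamma * d2).mean(axis=1)
        refs.append(idx[int(np.argmax(sim))])
    return np.array(sorted(refs))


def neighborhood_enrichment(
    embedding: np.ndarray,
    expr,
    gene_names,
    markers: dict,
    gamma: float = 0.8,
    n_perm: int = 100,
    sd_cutoff: float = 5.0,
    n_ref: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster-free marker-enrichment annotation (RBF-kernel similarity).

    For each reference cell r the similarity of every cell is
    ``s_i = exp(-gamma * ||x_i - x_r||^2)``; the enrichment score of gene g
    at r is the least-squares slope of expr(g, .) on s. The null permutes
    the cell order of the expression matrix ``n_perm`` times; a gene is
    significantly enriched when its score exceeds the null mean by
    ``sd_cutoff`` standard deviations. Each cell takes the label of the
    top-scoring significant marker at its most similar reference cell.

    ``markers`` maps gene -> label.
    """
    embedding = np.asarray(embedding, dtype=float)
    if np.allclose(embedding, embedding[0]):
        raise ValueError("degenerate embedding: all cells identical")
    gene_names = pd.Index(gene_names)
    marker_genes = [g for g in markers if g in gene_names]
    if not marker_genes:
        raise ValueError("no marker genes present in the expression matrix")
    E = expr.toarray() if sp.issparse(expr) else np.asarray(expr, dtype=float)
    E = E[:, gene_names.get_indexer(marker_genes)]  # cells x markers
    n_cells = E.shape[0]

    ref_idx = _select_reference_cells(embedding, gamma, n_ref, seed)
    d2 = ((embedding[:, None, :] - embedding[None, ref_idx, :]) ** 2).sum(-1)
    S = np.exp(-gamma * d2)  # cells x refs
    Sc = S - S.mean(axis=0, keepdims=True)
    denom = (Sc**2).sum(axis=0)
    if np.any(denom == 0):
        raise ValueError("degenerate similarity vector (constant) for a reference cell")

    def slopes(M):
        return (M.T @ Sc) / denom  # markers x refs

    obs = slopes(E)
    rng = np.random.default_rng(seed)
    mean = np.zeros_like(obs)
    m2 = np.zeros_like(obs)
    for k in range(n_perm):
        perm = rng.permutation(n_cells)
        s = slopes(E[perm])
        delta = s - mean
        mean += delta / (k + 1)
        m2 += delta * (s - mean)
    sd = np.sqrt(m2 / max(n_perm - 1, 1))
    sig = obs > mean + sd_cutoff * sd

    nearest_ref = np.argmax(S, axis=1)
    labels = np.full(n_cells, UNASSIGNED, dtype=object)
    conf = np.zeros(n_cells)
    marker_labels = np.array([markers[g] for g in marker_genes], dtype=object)
    for r in range(len(ref_idx)):
        ok = np.where(sig[:, r])[0]
        if ok.size == 0:
            continue
        best = ok[int(np.argmax(obs[ok, r]))]
        cells = nearest_ref == r
        labels[cells] = marker_labels[best]
        conf[cells] = obs[best, r]
    out = pd.DataFrame({"label": labels, "confidence": conf})
    out["high_confidence"] = labels != UNASSIGNED
    out.attrs["reference_cells"] = ref_idx
    out.attrs["enrichment_scores"] = pd.DataFrame(obs, index=marker_genes)
    out.attrs["significant"] = pd.DataFrame(sig, index=marker_genes)
    return out


# ---------------------------------------------------------------------------
# micro-cluster z-score voting

def microcluster_zscore_annotate(
    X,
    gene_names,
    markers: dict,
    n_microclusters: int,
    n_pcs: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Fine k-means clusters labeled by average marker z-scores.

    ``markers`` maps gene -> label. Clusters (tens of cells each at the
    default resolution) vote as a unit: the cluster and all its cells take
    the label whose markers have the highest mean z-score; ties break
    lexicographically.
    """
    X = X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X))
    n_cells = X.shape[0]
    if n_microclusters >= n_cells:
        raise ValueError("n_microclusters must be smaller than the number of cells")
    gene_names = pd.Index(gene_names)
    Xn = log_normalize(X)
    Z = zscore_genes(Xn)
    emb = pca_embed(Xn, n_comps=n_pcs, random_state=seed)
    km = KMeans(n_clusters=n_microclusters, n_init=4, random_state=seed).fit(emb)

    labels_sorted = sorted(set(markers.values()))
    marker_idx = {
        lab: gene_names.get_indexer([g for g, l in markers.items() if l == lab and g in gene_names])
        for lab in labels_sorted
    }
    cell_labels = np.empty(n_cells, dtype=object)
    cluster_label = {}
    for c in range(n_microclusters):
        cells = km.labels_ == c
        means = np.array(
            [Z[np.ix_(cells, idx)].mean() if len(idx) else -np.inf for lab, idx in marker_idx.items()]
        )
        lab = labels_sorted[int(np.argmax(means))]  # argmax -> first = lexicographic tie-break
        cluster_label[c] = lab
        cell_labels[cells] = lab
    out = pd.DataFrame({"label": cell_labels, "cluster": km.labels_})
    score = np.ones(n_cells)
    out["confidence"] = score
    out["high_confidence"] = True
    out.attrs["cluster_label"] = cluster_label
    return out


# ---------------------------------------------------------------------------
# consensus

def _coarse_majority(emb: np.ndarray, labels: np.ndarray, apply_mask: np.ndarray,
                     n_clusters: int, seed: int) -> np.ndarray:
    """Cluster-majority denoising: relabel cells in ``apply_mask`` with their
    coarse k-means cluster's majority label (majority among labeled cells)."""
    labels = labels.copy()
    km = KMeans(n_clusters=min(n_clusters, emb.shape[0]), n_init=4, random_state=seed).fit(emb)
    for c in range(km.n_clusters):
        cells = km.labels_ == c
        lab_here = labels[cells]
        lab_here = lab_here[lab_here != UNASSIGNED]
        if lab_here.size == 0:
            continue
        vals, counts = np.unique(lab_here, return_counts=True)
        maj = vals[np.lexsort((vals, -counts))][0]
        if counts.max() <= lab_here.size / 2:
            continue  # no strict majority: leave as-is
        labels[cells & apply_mask] = maj
    return labels


def combine_annotations(
    evidence: list[pd.DataFrame],
    X,
    gene_names,
    min_agree: int = 2,
    n_hvg: int = 500,
    confidence_threshold: float = 0.6,
    n_denoise_factor: int = 4,
    seed: int = 0,
    label_source_masks: dict | None = None,
) -> pd.DataFrame:
    """Consensus annotation from >=2 evidence sources.

    Step 1: a cell keeps a label voted by at least ``min_agree`` sources
    (modal label, lexicographic tie-break). Step 2: coarse k-means
    cluster-majority denoising applied to weakly supported cells. Step 3:
    reference profiles rebuilt as mean log-normalized expression of
    confidently annotated cells. Step 4: every cell (including unassigned)
    re-annotated by correlation to the rebuilt references, followed by a
    final denoising pass on low-confidence cells.

    ``label_source_masks`` optionally maps a label to the list of evidence
    indices allowed to vote for it (for labels that only some sources can
    see).
    """
    if len(evidence) < 2:
        raise ValueError("at least two evidence sources are required")
    n_cells = len(evidence[0])
    votes = np.stack([ev["label"].to_numpy(dtype=object) for ev in evidence])
    if label_source_masks:
        for lab, allowed in label_source_masks.items():
            for s in range(votes.shape[0]):
                if s not in allowed:
                    votes[s][votes[s] == lab] = UNASSIGNED

    step1 = np.full(n_cells, UNASSIGNED, dtype=object)
    agreement = np.zeros(n_cells, dtype=int)
    for i in range(n_cells):
        v = votes[:, i]
        v = v[v != UNASSIGNED]
        if v.size == 0:
            continue
        vals, counts = np.unique(v, return_counts=True)
        order = np.lexsort((vals, -counts))
        agreement[i] = int(counts[order[0]])
        if counts[order[0]] >= min_agree:
            step1[i] = vals[order[0]]

    if not (step1 != UNASSIGNED).any():
        raise ValueError("no cell reached the agreement threshold; cannot build references")

    Xn = log_normalize(X)
    emb = pca_embed(Xn, n_comps=50, random_state=seed)
    n_labels = len(set(step1) - {UNASSIGNED})
    weak = agreement <= min_agree
    step2 = _coarse_majority(emb, step1, weak, n_denoise_factor * n_labels, seed)

    confident = step2 != UNASSIGNED
    refs = {}
    for lab in sorted(set(step2[confident])):
        cells = step2 == lab
        refs[lab] = np.asarray(Xn[cells].mean(axis=0)).ravel()
    refs_df = pd.DataFrame(refs, index=pd.Index(gene_names))

    corr = correlation_annotate(X, gene_names, refs_df,
                                n_hvg=min(n_hvg, len(refs_df)),
                                confidence_threshold=confidence_threshold)
    final = corr["label"].to_numpy(dtype=object)
    low_conf = ~corr["high_confidence"].to_numpy()
    final = _coarse_majority(emb, final, low_conf, n_denoise_factor * n_labels, seed)

    out = pd.DataFrame(
        {
            "label": final,
            "agreement": agreement,
            "step1_label": step1,
            "confidence": corr["confidence"].to_numpy(),
        }
    )
    out.attrs["rebuilt_references"] = refs_df
    return out


# ---------------------------------------------------------------------------
# QC-center cells and label transfer

def annotate_qc_cells(
    X,
    gene_names,
    embedding: np.ndarray,
    qc_markers,
    cellcycle_genes,
    target_fraction: float = 0.001,
    gamma: float = 0.8,
    n_perm: int = 100,
    sd_cutoff: float = 5.0,
    n_ref: int = 150,
    seed: int = 0,
) -> np.ndarray:
    """Identify quiescent-center-like organizer cells.

    Candidates are cells in neighborhoods where QC-center markers are
    significantly enriched; among candidates, score = mean z(QC markers) -
    mean z(cell-cycle genes), and the top ``target_fraction`` of the atlas
    is returned (indices).
    """
    gene_names = pd.Index(gene_names)
    qc_markers = [g for g in qc_markers if g in gene_names]
    cellcycle_genes = [g for g in cellcycle_genes if g in gene_names]
    if not qc_markers or not cellcycle_genes:
        raise ValueError("both QC-marker and cell-cycle gene sets must be non-empty")
    Xn = log_normalize(X)
    marker_map = {g: "qc_center" for g in qc_markers}
    enr = neighborhood_enrichment(
        embedding, Xn, gene_names, marker_map, gamma=gamma, n_perm=n_perm,
        sd_cutoff=sd_cutoff, n_ref=n_ref, seed=seed,
    )
    candidates = np.where(enr["label"].to_numpy() == "qc_center")[0]
    if candidates.size == 0:
        warnings.warn("no neighborhood shows significant QC-marker enrichment")
        return np.array([], dtype=int)
    Z = zscore_genes(Xn)
    score = (
        Z[:, gene_names.get_indexer(qc_markers)].mean(axis=1)
        - Z[:, gene_names.get_indexer(cellcycle_genes)].mean(axis=1)
    )
    n_take = min(int(np.ceil(target_fraction * X.shape[0])), candidates.size)
    order = candidates[np.argsort(-score[candidates], kind="stable")]
    return np.sort(order[:n_take])


def transfer_labels(
    ref_X,
    ref_gene_names,
    ref_labels,
    query_X,
    query_gene_names,
    k: int = 30,
    n_pcs: int = 50,
    min_shared_genes: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-weighted k-NN label transfer in a joint PCA space.

    The PCA is fitted on reference log-normalized expression over the shared
    gene space; query cells are projected in and classified by a
    distance-weighted vote of their k nearest reference cells. Per-class
    scores sum to one; score differences between two classes (e.g.
    endodermis minus cortex) can be read off directly.
    """
    clf = LabelTransferClassifier(k=k, n_pcs=n_pcs, min_shared_genes=min_shared_genes, seed=seed)
    clf.fit(ref_X, np.asarray(ref_labels, dtype=object), gene_names=ref_gene_names)
    proba = clf.predict_proba(query_X, gene_names=query_gene_names)
    out = pd.DataFrame(proba, columns=[f"score_{c}" for c in clf.classes_])
    best = proba.argmax(axis=1)
    out["label"] = [clf.classes_[b] for b in best]
    out["score"] = proba[np.arange(len(best)), best]
    return out


# ---------------------------------------------------------------------------
# estimator classes

class ICIAnnotator(BaseEstimator, ClassifierMixin):
    """ICI classifier: ``fit`` builds the spec table from reference profiles
    (genes x labels DataFrame); ``predict`` labels count matrices."""

    def __init__(self, n_bins=10, min_background_bin=3, information_level=50.0,
                 n_perm=200, alpha=0.01, seed=0):
        self.n_bins = n_bins
        self.min_background_bin = min_background_bin
        self.information_level = information_level
        self.n_perm = n_perm
        self.alpha = alpha
        self.seed = seed

    def fit(self, refs: pd.DataFrame, y=None):
        self.spec_table_ = build_spec_table(
            refs, self.n_bins, self.min_background_bin, self.information_level
        )
        self.classes_ = np.array(self.spec_table_.labels, dtype=object)
        return self

    def annotate(self, X, gene_names) -> pd.DataFrame:
        return ici_scores(X, gene_names, self.spec_table_,
                          n_perm=self.n_perm, alpha=self.alpha, seed=self.seed)

    def predict(self, X, gene_names=None):
        return self.annotate(X, gene_names)["label"].to_numpy()


class CorrelationAnnotator(BaseEstimator, ClassifierMixin):
    def __init__(self, n_hvg=181, confidence_threshold=0.6):
        self.n_hvg = n_hvg
        self.confidence_threshold = confidence_threshold

    def fit(self, refs: pd.DataFrame, y=None):
        self.refs_ = refs
        self.classes_ = np.array(refs.columns, dtype=object)
        return self

    def annotate(self, X, gene_names) -> pd.DataFrame:
        return correlation_annotate(X, gene_names, self.refs_,
                                    n_hvg=self.n_hvg,
                                    confidence_threshold=self.confidence_threshold)

    def predict(self, X, gene_names=None):
        return self.annotate(X, gene_names)["label"].to_numpy()


class NeighborhoodAnnotator(BaseEstimator, ClassifierMixin):
    def __init__(self, markers=None, gamma=0.8, n_perm=100, sd_cutoff=5.0,
                 n_ref=50, seed=0):
        self.markers = markers
        self.gamma = gamma
        self.n_perm = n_perm
        self.sd_cutoff = sd_cutoff
        self.n_ref = n_ref
        self.seed = seed

    def fit(self, X=None, y=None):
        if not self.markers:
            raise ValueError("markers (gene -> label) must be provided")
        self.classes_ = np.array(sorted(set(self.markers.values())), dtype=object)
        return self

    def annotate(self, embedding, expr, gene_names) -> pd.DataFrame:
        return neighborhood_enrichment(
            embedding, expr, gene_names, self.markers, gamma=self.gamma,
            n_perm=self.n_perm, sd_cutoff=self.sd_cutoff, n_ref=self.n_ref,
            seed=self.seed,
        )


class MicroclusterAnnotator(BaseEstimator, ClassifierMixin):
    def __init__(self, markers=None, n_microclusters=None, n_pcs=50, seed=0):
        self.markers = markers
        self.n_microclusters = n_microclusters
        self.n_pcs = n_pcs
        self.seed = seed

    def fit(self, X=None, y=None):
        if not self.markers:
            raise ValueError("markers (gene -> label) must be provided")
        self.classes_ = np.array(sorted(set(self.markers.values())), dtype=object)
        return self

    def annotate(self, X, gene_names) -> pd.DataFrame:
        n_mc = self.n_microclusters or max(2, X.shape[0] // 35)
        return microcluster_zscore_annotate(
            X, gene_names, self.markers, n_mc, n_pcs=self.n_pcs, seed=self.seed
        )


class ConsensusAnnotator(BaseEstimator):
    """Combines a list of per-cell evidence tables into the consensus."""

    def __init__(self, min_agree=2, n_hvg=500, confidence_threshold=0.6,
                 n_denoise_factor=4, seed=0, label_source_masks=None):
        self.min_agree = min_agree
        self.n_hvg = n_hvg
        self.confidence_threshold = confidence_threshold
        self.n_denoise_factor = n_denoise_factor
        self.seed = seed
        self.label_source_masks = label_source_masks

    def fit(self, evidence, X, gene_names):
        res = combine_annotations(
            evidence, X, gene_names, min_agree=self.min_agree, n_hvg=self.n_hvg,
            confidence_threshold=self.confidence_threshold,
            n_denoise_factor=self.n_denoise_factor, seed=self.seed,
            label_source_masks=self.label_source_masks,
        )
        self.result_ = res
        self.labels_ = res["label"].to_numpy()
        self.references_ = res.attrs["rebuilt_references"]
        return self


class LabelTransferClassifier(BaseEstimator, ClassifierMixin):
    """Weighted-vote k-NN classifier in a reference-fitted PCA space."""

    def __init__(self, k=30, n_pcs=50, min_shared_genes=500, seed=0):
        self.k = k
        self.n_pcs = n_pcs
        self.min_shared_genes = min_shared_genes
        self.seed = seed

    def fit(self, X, y, gene_names=None):
        y = np.asarray(y, dtype=object)
        if self.k > X.shape[0]:
            raise ValueError("k exceeds the number of reference cells")
        self.gene_names_ = pd.Index(gene_names) if gene_names is not None else None
        Xn = log_normalize(X).toarray()
        self.pca_ = PCA(n_components=min(self.n_pcs, min(Xn.shape) - 1),
                        svd_solver="randomized", random_state=self.seed)
        emb = self.pca_.fit_transform(Xn)
        self._mean = Xn.mean(axis=0)
        self.nn_ = NearestNeighbors(n_neighbors=self.k).fit(emb)
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        self._y = y
        return self

    def _project(self, X, gene_names=None):
        if self.gene_names_ is not None and gene_names is not None:
            gene_names = pd.Index(gene_names)
            shared = self.gene_names_.intersection(gene_names)
            if len(shared) < self.min_shared_genes:
                raise ValueError(
                    f"shared gene space too small: {len(shared)} < {self.min_shared_genes}"
                )
            ref_ix = self.gene_names_.get_indexer(shared)
            q_ix = gene_names.get_indexer(shared)
            Xn = log_normalize(X).toarray()
            full = np.tile(self._mean, (X.shape[0], 1))
            full[:, ref_ix] = Xn[:, q_ix]
            Xn = full
        else:
            Xn = log_normalize(X).toarray()
        return self.pca_.transform(Xn)

    def predict_proba(self, X, gene_names=None):
        emb = self._project(X, gene_names)
        dist, idx = self.nn_.kneighbors(emb)
        w = 1.0 / np.maximum(dist, 1e-12)
        w /= w.sum(axis=1, keepdims=True)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        class_ix = {c: j for j, c in enumerate(self.classes_)}
        neigh_labels = self._y[idx]
        for j, c in enumerate(self.classes_):
            proba[:, j] = (w * (neigh_labels == c)).sum(axis=1)
        return proba

    def predict(self, X, gene_names=None):
        proba = self.predict_proba(X, gene_names)
        return self.classes_[proba.argmax(axis=1)]
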