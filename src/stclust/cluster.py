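"""PCA -> sNN -> Leiden (resolution-tuned, multi-seed) and kmeans clustering,
plus expression-profile matching of predicted clusters to truth classes.

The Leiden path mirrors the common transcriptomics recipe: a shared-nearest-
neighbor (sNN) graph with Jaccard edge weights over k=15 nearest neighbors in
PC space, Leiden community detection (modularity with a resolution parameter),
a grid search over resolutions keeping those that reproduce the ground-truth
cluster count, and a majority/medoid choice among the qualifying runs.

Estimator classes follow scikit-learn conventions (``fit`` sets ``labels_``);
the module functions are thin wrappers used by the benchmark driver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .containers import (
    ExpressionMatrix,
    GeneSelection,
    LabelSet,
    MatchedLabels,
    ValidationError,
)

DEFAULT_RESOLUTION_GRID = tuple(np.round(np.arange(0.1, 2.01, 0.1), 2))
DEFAULT_SEEDS = tuple(range(10))


@dataclass
class Embedding:
    cell_ids: np.ndarray
    coordinates: np.ndarray
    n_pcs: int
    selection: GeneSelection | None = None
    explained_variance_ratio: np.ndarray | None = None


@dataclass
class ClusteringResult:
    cell_ids: np.ndarray
    cluster_labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(pd.unique(self.cluster_labels))


def compute_pca(
    matrix: ExpressionMatrix,
    selection: GeneSelection,
    n_pcs: int = 50,
    scale: bool = False,
) -> Embedding:
    """PCA of the selection's genes with a deterministic sign convention.

    Components are flipped so the loading with the largest magnitude is
    positive.  ``n_pcs`` is capped at min(50, n_genes - 1, n_cells - 1).
    """
    if len(selection) == 0:
        raise ValidationError("cannot embed an empty gene selection")
    sub = matrix.subset_genes(selection.gene_ids)
    X = sub.to_dense()
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    k = max(1, min(n_pcs, 50, X.shape[1] - 1 if X.shape[1] > 1 else 1, X.shape[0] - 1))
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(k), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    coords = coords * flip[None, :]
    return Embedding(
        cell_ids=matrix.cell_ids.copy(),
        coordinates=coords,
        n_pcs=k,
        selection=selection,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def build_snn(embedding: Embedding | np.ndarray, k_neighbors: int = 15) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    kNN by euclidean distance (self excluded, ties broken by cell index);
    weight(i, j) = |kNN(i) ∩ kNN(j)| / |kNN(i) ∪ kNN(j)|; zero-weight edges
    pruned.  Returned as a symmetric sparse adjacency matrix.
    """
    from .metrics import _knn_indices

    X = embedding.coordinates if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = X.shape[0]
    if n <= k_neighbors:
        raise ValidationError(f"need more than k_neighbors={k_neighbors} cells, got {n}")
    nbr = _knn_indices(X, k_neighbors, include_self=False)
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sp.csr_matrix((np.ones(rows.size), (rows, nbr.ravel())), shape=(n, n))
    shared = (A @ A.T).tocoo()
    mask = shared.row != shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jacc = s / (2 * k_neighbors - s)
    keep = jacc > 0
    W = sp.csr_matrix((jacc[keep], (r[keep], c[keep])), shape=(n, n))
    return W


def _snn_to_igraph(W: sp.csr_matrix) -> ig.Graph:
    coo = sp.triu(W, k=1).tocoo()
    g = ig.Graph(
        n=W.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    return g


def _run_leiden(g: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership)


def leiden_tuned(
    graph: sp.csr_matrix,
    target_k: int,
    resolution_grid=DEFAULT_RESOLUTION_GRID,
    n_runs: int = 10,
    seeds=DEFAULT_SEEDS,
    max_expansions: int = 3,
    cell_ids: np.ndarray | None = None,
) -> ClusteringResult:
    """Resolution-tuned multi-seed Leiden clustering.

    Each resolution is run ``n_runs`` times (one run per seed); the resolution
    with the most runs yielding exactly ``target_k`` clusters wins (ties go to
    the smallest resolution), and the returned partition is the medoid (highest
    mean pairwise adjusted Rand agreement) of that resolution's target_k runs.
    If no resolution ever yields ``target_k``, the grid is expanded
    geometrically up to ``max_expansions`` times before erroring.
    """
    if target_k < 2:
        raise ValidationError("target_k must be >= 2")
    seeds = list(seeds)[:n_runs]
    if len(seeds) < n_runs:
        seeds = seeds + list(range(max(seeds, default=0) + 1, max(seeds, default=0) + 1 + n_runs - len(seeds)))
    g = _snn_to_igraph(graph)
    grid = sorted(float(r) for r in resolution_grid)
    attempted: list[float] = []
    for expansion in range(max_expansions + 1):
        best_res, best_count, best_runs = None, 0, None
        for res in grid:
            runs = [_run_leiden(g, res, s) for s in seeds]
            hits = [lab for lab in runs if len(np.unique(lab)) == target_k]
            if len(hits) > best_count:
                best_res, best_count, best_runs = res, len(hits), hits
        attempted.extend(grid)
        if best_count > 0:
            if len(best_runs) == 1:
                labels = best_runs[0]
            else:
                agree = np.zeros(len(best_runs))
                for i, li in enumerate(best_runs):
                    agree[i] = np.mean(
                        [adjusted_rand_score(li, lj) for j, lj in enumerate(best_runs) if j != i]
                    )
                labels = best_runs[int(np.argmax(agree))]
            ids = (
                cell_ids
                if cell_ids is not None
                else np.array([f"c{i}" for i in range(graph.shape[0])])
            )
            return ClusteringResult(
                cell_ids=np.asarray(ids, dtype=str),
                cluster_labels=np.array([f"k{l}" for l in labels], dtype=str),
                method="leiden",
                params={
                    "resolution": best_res,
                    "n_target_runs": best_count,
                    "n_runs": n_runs,
                    "seeds": seeds,
                    "target_k": target_k,
                },
            )
        # expand: halve the smallest step below, double the upper bound
        lo, hi = grid[0], grid[-1]
        grid = sorted(set([lo / 2] + grid + [hi * 1.5, hi * 2]))
    raise ValidationError(
        f"no resolution in {min(attempted):.3g}..{max(attempted):.3g} "
        f"yielded {target_k} clusters"
    )


def _distance_transform(X: np.ndarray, distance: str) -> np.ndarray:
    """Row transforms making euclidean kmeans optimize correlation objectives.

    Pearson: center and unit-scale each row (cosine of centered rows equals
    Pearson r, and euclidean distance of the scaled rows is a monotone
    function of 1 - r).  Spearman: rank-transform each row first.
    """
    X = np.asarray(X, dtype=float)
    if distance == "euclidean":
        return X
    if distance == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)
    elif distance != "pearson":
        raise ValidationError(f"unknown distance {distance!r}")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    return Xc / np.where(norms > 0, norms, 1.0)


def kmeans_cluster(
    embedding: Embedding | np.ndarray,
    k: int,
    distance: str = "euclidean",
    seed: int = 0,
    n_init: int = 10,
    cell_ids: np.ndarray | None = None,
) -> ClusteringResult:
    """Kmeans on the embedding under euclidean / pearson / spearman distance."""
    X = embedding.coordinates if isinstance(embedding, Embedding) else np.asarray(embedding)
    if k > X.shape[0]:
        raise ValidationError(f"k={k} exceeds n_cells={X.shape[0]}")
    Xt = _distance_transform(X, distance)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed))
    labels = km.fit_predict(Xt)
    if cell_ids is None:
        cell_ids = (
            embedding.cell_ids
            if isinstance(embedding, Embedding)
            else np.array([f"c{i}" for i in range(X.shape[0])])
        )
    return ClusteringResult(
        cell_ids=np.asarray(cell_ids, dtype=str),
        cluster_labels=np.array([f"k{l}" for l in labels], dtype=str),
        method="kmeans",
        params={"k": k, "distance": distance, "seed": int(seed),
                "n_init": n_init, "inertia": float(km.inertia_)},
    )


def match_labels(
    clustering: ClusteringResult,
    truth: LabelSet,
    matrix: ExpressionMatrix,
    selection: GeneSelection,
) -> MatchedLabels:
    """Map predicted clusters onto truth classes by expression-profile correlation.

    Profiles are mean expression over ``selection``'s genes (by convention the
    experiment's union-level gene space, so all gene sets are matched in a
    common space).  With equal cluster/class counts the mapping is the
    maximum-total-correlation one-to-one assignment; otherwise each cluster
    maps to its best-correlated class.  Zero-variance profiles fall back to
    smallest euclidean profile distance, with a warning.
    """
    idx = pd.Index(truth.cell_ids)
    pos = idx.get_indexer(clustering.cell_ids)
    if np.any(pos < 0) or len(truth.cell_ids) != len(clustering.cell_ids):
        raise ValidationError("clustering and truth do not share the same cells")
    u = truth.labels[pos]

    sub = matrix.subset_genes(selection.gene_ids)
    midx = pd.Index(sub.cell_ids)
    mpos = midx.get_indexer(clustering.cell_ids)
    if np.any(mpos < 0):
        raise ValidationError("clustering and matrix do not share the same cells")
    X = sub.to_dense()[mpos]

    pred = clustering.cluster_labels
    pred_classes = pd.unique(pred)
    true_classes = pd.unique(u)
    prof_pred = np.vstack([X[pred == c].mean(axis=0) for c in pred_classes])
    prof_true = np.vstack([X[u == c].mean(axis=0) for c in true_classes])

    sd_pred = prof_pred.std(axis=1)
    sd_true = prof_true.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        zp = (prof_pred - prof_pred.mean(axis=1, keepdims=True))
        zt = (prof_true - prof_true.mean(axis=1, keepdims=True))
        corr = (zp @ zt.T) / np.outer(
            np.linalg.norm(zp, axis=1), np.linalg.norm(zt, axis=1)
        )
    degenerate = (sd_pred == 0)[:, None] | (sd_true == 0)[None, :]
    if degenerate.any():
        warnings.warn(
            "zero-variance expression profile; falling back to euclidean matching",
            stacklevel=2,
        )
        d = cdist(prof_pred, prof_true)
        # strictly below any correlation, ordered by closeness
        corr = np.where(degenerate, -2.0 - d / (1.0 + d.max()), corr)
    corr = np.nan_to_num(corr, nan=-3.0)

    mapping: dict[str, str] = {}
    if len(pred_classes) == len(true_classes):
        ri, ci = linear_sum_assignment(-corr)
        for r, c in zip(ri, ci):
            mapping[pred_classes[r]] = true_classes[c]
    else:
        for r, c in enumerate(np.argmax(corr, axis=1)):
            mapping[pred_classes[r]] = true_classes[c]
    u_star = np.array([mapping[c] for c in pred], dtype=str)
    return MatchedLabels(
        cell_ids=clustering.cell_ids.copy(), u=u, u_star=u_star, mapping=mapping
    )


# ---------------------------------------------------------------------------
# sklearn-style estimators


class SNNLeiden(ClusterMixin, BaseEstimator):
    """sNN-graph Leiden clustering tuned to a target cluster count.

    Parameters follow the common transcriptomics recipe: ``n_neighbors=15``
    for the sNN graph, 10 Leiden runs per resolution on a 0.1..2.0 grid.
    ``fit(X)`` expects an embedding (cells x PCs) and sets ``labels_``,
    ``resolution_`` and ``n_clusters_``.
    """

    def __init__(self, target_k: int = 2, n_neighbors: int = 15,
                 resolution_grid=DEFAULT_RESOLUTION_GRID, n_runs: int = 10,
                 seeds=DEFAULT_SEEDS):
        self.target_k = target_k
        self.n_neighbors = n_neighbors
        self.resolution_grid = resolution_grid
        self.n_runs = n_runs
        self.seeds = seeds

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        W = build_snn(X, k_neighbors=self.n_neighbors)
        res = leiden_tuned(
            W,
            target_k=self.target_k,
            resolution_grid=self.resolution_grid,
            n_runs=self.n_runs,
            seeds=self.seeds,
        )
        codes = pd.factorize(res.cluster_labels)[0]
        self.labels_ = codes
        self.resolution_ = res.params["resolution"]
        self.n_clusters_ = res.n_clusters
        self.n_features_in_ = X.shape[1]
        return self


class CorrelationKMeans(ClusterMixin, BaseEstimator):
    """KMeans under euclidean, pearson or spearman distance.

    Correlation distances are realized by per-row standardization (pearson) or
    rank transformation then standardization (spearman) followed by euclidean
    kmeans, equivalent up to scale to optimizing the correlation objective.
    """

    def __init__(self, n_clusters: int = 2, distance: str = "euclidean",
                 n_init: int = 10, random_state: int = 0):
        self.n_clusters = n_clusters
        self.distance = distance
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        res = kmeans_cluster(
            X,
            k=self.n_clusters,
            distance=self.distance,
            seed=self.random_state,
            n_init=self.n_init,
        )
        self.labels_ = pd.factorize(res.cluster_labels)[0]
        self.inertia_ = res.params["inertia"]
        self.n_features_in_ = X.shape[1]
        return self
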