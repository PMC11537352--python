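"""Clustering evaluation metrics, including the entropy-weighted spatial ones.

Conventional metrics: adjusted mutual information (AMI, arithmetic-mean
normalization), weighted F1 after label matching, and Pearson Gamma (the
correlation between pairwise distances and a binary different-cluster
indicator).

Spatially adjusted metrics weight each cell by the Shannon entropy e_i of
ground-truth labels in its local spatial neighborhood, normalized to
w_i = e_i / sum_j e_j, so agreement at spatially heterogeneous positions
(domain borders) counts more than agreement deep inside homogeneous regions:

* Spatial Concordance  SC = sum_i 1[u_i == u*_i] * w_i
* Mean Spatial AMI     sum_i w_i * AMI(u|_{N_i}, u*|_{N_i})

Neighborhoods are self-inclusive k-nearest-neighbor sets (k_spatial = 15 by
default).  If every neighborhood is label-pure (sum_j e_j = 0) the weights
fall back to uniform 1/n, so SC reduces to plain per-cell accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_mutual_info_score, f1_score

from .containers import (
    MatchedLabels,
    MetricRecord,
    SpatialCoords,
    ValidationError,
    _sub_rng,
)


# ---------------------------------------------------------------------------
# neighborhoods and entropy weights


def _knn_indices(X: np.ndarray, k: int, include_self: bool) -> np.ndarray:
    """k nearest neighbors by euclidean distance, ties broken by cell index.

    Returns an (n, k) or (n, k+1) index array (the latter when the focal point
    is included).  Chunked O(n^2) computation keeps tie-breaking exact.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    m = k + 1  # always rank self first, drop it if excluded
    if m > n:
        raise ValidationError(f"need at least {m} points for k={k}")
    out = np.empty((n, m), dtype=int)
    sq = (X**2).sum(axis=1)
    chunk = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] - 2 * X[start:stop] @ X.T + sq[None, :]
        d2[np.arange(stop - start), np.arange(start, stop)] = -np.inf  # self first
        order = np.lexsort((np.broadcast_to(np.arange(n), d2.shape), d2), axis=1)
        out[start:stop] = order[:, :m]
    return out if include_self else out[:, 1:]


@dataclass
class SpatialNeighborhood:
    """Per-cell self-inclusive spatial neighborhoods (k nearest + self)."""

    members: np.ndarray  # (n, k_spatial + 1) index array, column 0 = self
    k_spatial: int


@dataclass
class EntropyWeights:
    e: np.ndarray  # raw per-cell neighborhood entropy
    w: np.ndarray  # normalized weights, sum to 1


def build_neighborhoods(
    coords: SpatialCoords | np.ndarray, k_spatial: int = 15
) -> SpatialNeighborhood:
    """Self-inclusive euclidean kNN neighborhoods with index tie-breaking."""
    xy = coords.xy if isinstance(coords, SpatialCoords) else np.asarray(coords, dtype=float)
    if xy.ndim == 1:
        xy = xy[:, None]
    if xy.shape[0] <= k_spatial:
        raise ValidationError(
            f"need more than k_spatial={k_spatial} cells, got {xy.shape[0]}"
        )
    members = _knn_indices(xy, k_spatial, include_self=True)
    return SpatialNeighborhood(members=members, k_spatial=k_spatial)


def entropy_weights(truth, nb: SpatialNeighborhood) -> EntropyWeights:
    """Shannon entropy (natural log) of truth labels per neighborhood.

    w_i = e_i / sum_j e_j; when every neighborhood is pure the weights fall
    back to uniform 1/n.
    """
    labels = np.asarray(truth, dtype=object)
    codes = pd.factorize(labels)[0]
    n_classes = codes.max() + 1
    member_codes = codes[nb.members]
    n, m = member_codes.shape
    e = np.zeros(n)
    counts = np.zeros((n, n_classes))
    for j in range(m):
        np.add.at(counts, (np.arange(n), member_codes[:, j]), 1.0)
    p = counts / m
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    e = terms.sum(axis=1)
    total = e.sum()
    w = e / total if total > 0 else np.full(n, 1.0 / n)
    return EntropyWeights(e=e, w=w)


# ---------------------------------------------------------------------------
# conventional metrics


def ami(u, u_star) -> float:
    """Adjusted mutual information with arithmetic-mean normalization."""
    u = np.asarray(u)
    u_star = np.asarray(u_star)
    if u.shape != u_star.shape:
        raise ValidationError("label vectors differ in length")
    if u.size < 2:
        raise ValidationError("need at least 2 cells")
    return float(adjusted_mutual_info_score(u, u_star, average_method="arithmetic"))


def weighted_f1(matched: MatchedLabels) -> float:
    """Per-truth-class F1, weighted by truth-class frequency (0 when undefined)."""
    classes = pd.unique(matched.u)
    return float(
        f1_score(
            matched.u, matched.u_star, labels=classes, average="weighted", zero_division=0
        )
    )


def pearson_gamma(
    labels,
    points: np.ndarray | None = None,
    *,
    dists: np.ndarray | None = None,
    max_n: int = 2000,
    random_state: int = 0,
) -> float:
    """Correlation between pairwise distances and a different-cluster indicator.

    ``dists`` may supply a precomputed condensed distance vector; otherwise
    euclidean distances of ``points`` are used.  Above ``max_n`` points a
    seeded uniform subsample of ``max_n`` is scored (only possible with
    ``points``).  A single cluster leaves the indicator constant: returns NaN
    with a warning.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < 3:
        raise ValidationError("pearson_gamma needs at least 3 points")
    if dists is None:
        points = np.asarray(points, dtype=float)
        if points.ndim == 1:
            points = points[:, None]
        if n > max_n:
            rng = _sub_rng(random_state, 21)
            keep = np.sort(rng.choice(n, size=max_n, replace=False))
            labels, points = labels[keep], points[keep]
            n = max_n
        d = pdist(points)
    else:
        d = np.asarray(dists, dtype=float)
        if d.size != n * (n - 1) // 2:
            raise ValidationError("condensed distance vector has the wrong length")
    codes = pd.factorize(labels)[0].astype(float)
    m = (pdist(codes[:, None]) != 0).astype(float)
    if m.min() == m.max():
        warnings.warn("single cluster: Pearson Gamma undefined", stacklevel=2)
        return float("nan")
    if d.min() == d.max():
        warnings.warn("constant distances: Pearson Gamma undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(d, m)[0, 1])


# ---------------------------------------------------------------------------
# spatially adjusted metrics


def spatial_concordance(matched: MatchedLabels, weights: EntropyWeights) -> float:
    """Entropy-weighted label-match rate: SC = sum_i 1[u_i == u*_i] * w_i."""
    hit = matched.u == matched.u_star
    if hit.size != weights.w.size:
        raise ValidationError("weights and labels differ in length")
    return float(weights.w[hit].sum())


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.array_equal(pd.factorize(a)[0], pd.factorize(b)[0]))


def _local_ami(u: np.ndarray, v: np.ndarray) -> float:
    """AMI on a restricted neighborhood with small-sample conventions.

    Identical partitions (including both single-label) score 1; a zero
    normalizer scores 0; otherwise standard AMI.
    """
    if _same_partition(u, v):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = adjusted_mutual_info_score(u, v, average_method="arithmetic")
    if not np.isfinite(val):
        return 0.0
    return float(val)


def mean_spatial_ami(
    matched: MatchedLabels, nb: SpatialNeighborhood, weights: EntropyWeights
) -> float:
    """Entropy-weighted mean of per-neighborhood AMI values, clipped to [0, 1]."""
    u, v = matched.u, matched.u_star
    vals = np.zeros(weights.w.size)
    for i, members in enumerate(nb.members):
        if weights.w[i] == 0:
            continue
        vals[i] = _local_ami(u[members], v[members])
    return float(np.clip((weights.w * vals).sum(), 0.0, 1.0))


# ---------------------------------------------------------------------------
# composite


def evaluate_all(
    matched: MatchedLabels,
    embedding,
    coords: SpatialCoords,
    *,
    dataset: str = "dataset",
    gene_set: str = "all",
    threshold: str = "low",
    method: str = "leiden",
    k_spatial: int = 15,
    gamma_distance: str = "euclidean",
    random_state: int = 0,
) -> list[MetricRecord]:
    """Compute the five benchmark metrics for one (dataset, gene set, method).

    Pearson Gamma uses euclidean distance on the embedding for Leiden-derived
    clusterings and the method-appropriate distance for kmeans variants
    (pearson / spearman correlation distances of the embedding rows).
    """
    from .cluster import _distance_transform

    X = embedding.coordinates if hasattr(embedding, "coordinates") else np.asarray(embedding)
    nb = build_neighborhoods(coords, k_spatial=min(k_spatial, len(matched.u) - 1))
    ew = entropy_weights(matched.u, nb)

    if gamma_distance in ("pearson", "spearman"):
        Xg = _distance_transform(X, gamma_distance)
    else:
        Xg = X
    gamma = pearson_gamma(matched.u_star, Xg, random_state=random_state)

    values = {
        "ami": float(np.clip(ami(matched.u, matched.u_star), 0.0, 1.0)),
        "weighted_f1": weighted_f1(matched),
        "pearson_gamma": gamma,
        "spatial_concordance": spatial_concordance(matched, ew),
        "mean_spatial_ami": mean_spatial_ami(matched, nb, ew),
    }
    return [
        MetricRecord(
            dataset=dataset,
            gene_set=gene_set,
            threshold=threshold,
            method=method,
            metric=name,
            value=val,
        )
        for name, val in values.items()
    ]
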