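"""HV and SV gene selection and their union (concatenation).

HV genes come either from a LOESS fit of coefficient-of-variation against log
mean expression (small-panel / imaging path; the statistic is observed CV
minus fitted CV) or from the per-gene variance of NB Pearson residuals
(candidacy: variance > 1).  SV genes come from per-gene p-values produced by
an external spatial detector, or from the built-in Moran's-I permutation
scorer when no external p-values are available.

Stringency levels: HV low/medium/high keep candidates at or above the
50th/70th/90th percentile of the candidate statistics.  SV low is p < 0.05;
medium and high nest sequentially (medium = low genes with p at or below the
25th percentile of low's p-values; high = medium genes at or below the 50th
percentile of medium's), which keeps high ⊆ medium ⊆ low.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import (
    ExpressionMatrix,
    GeneSelection,
    GeneStatTable,
    SpatialCoords,
    ValidationError,
    align,
    _sub_rng,
)

HV_PERCENTILES = {"low": 50.0, "medium": 70.0, "high": 90.0}


# ---------------------------------------------------------------------------
# per-gene statistics


def hv_loess_cv(matrix: ExpressionMatrix, loess_span: float = 0.3) -> GeneStatTable:
    """CV excess over a LOESS mean-CV trend (statistic = observed - fitted CV).

    Genes with zero mean receive -inf and can never become candidates.
    """
    X = matrix.to_dense()
    if X.shape[1] < 10:
        raise ValidationError("LOESS trend needs at least 10 genes")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    stat = np.full(means.shape, -np.inf)
    pos = means > 0
    if pos.sum() < 10:
        raise ValidationError("LOESS trend needs at least 10 genes with positive mean")
    cv = sds[pos] / means[pos]
    log_mean = np.log(means[pos])
    # no robustness iterations: genes above the trend are the signal the
    # statistic must expose, not outliers to absorb into the fit
    fitted = lowess(
        cv, log_mean, frac=loess_span, it=0, return_sorted=False
    )
    stat[pos] = cv - fitted
    return GeneStatTable(matrix.gene_ids.copy(), stat, statistic_kind="cv_excess")


def hv_residual_variance(matrix: ExpressionMatrix) -> GeneStatTable:
    """Per-gene variance of Pearson residuals (candidacy downstream: > 1)."""
    if matrix.layer != "pearson":
        raise ValidationError("hv_residual_variance expects the pearson layer")
    var = matrix.to_dense().var(axis=0, ddof=1)
    return GeneStatTable(matrix.gene_ids.copy(), var, statistic_kind="residual_variance")


def _moran_setup(matrix: ExpressionMatrix, coords: SpatialCoords, k_neighbors: int):
    """Centered expression and symmetrized binary kNN spatial weights."""
    from .metrics import _knn_indices  # deterministic tie-breaking shared helper
    import scipy.sparse as sp

    matrix, coords = align(matrix, coords=coords)
    X = matrix.to_dense()
    n = X.shape[0]
    nbr = _knn_indices(coords.xy, k_neighbors, include_self=False)
    rows = np.repeat(np.arange(n), k_neighbors)
    W = sp.csr_matrix((np.ones(rows.size), (rows, nbr.ravel())), shape=(n, n))
    W = ((W + W.T) > 0).astype(float)
    Z = X - X.mean(axis=0)
    denom = (Z**2).sum(axis=0)
    constant = denom <= 0
    denom_safe = np.where(constant, 1.0, denom)

    def moran(Zm: np.ndarray) -> np.ndarray:
        return (n / W.sum()) * np.einsum("ij,ij->j", Zm, W @ Zm) / denom_safe

    return matrix, Z, moran, constant


def moran_i(
    matrix: ExpressionMatrix, coords: SpatialCoords, k_neighbors: int = 6
) -> GeneStatTable:
    """Observed Moran's I per gene on the symmetrized kNN spatial graph.

    Constant genes get I = 0.
    """
    matrix, Z, moran, constant = _moran_setup(matrix, coords, k_neighbors)
    i_obs = moran(Z)
    i_obs[constant] = 0.0
    return GeneStatTable(matrix.gene_ids.copy(), i_obs, statistic_kind="morans_i")


def sv_score_moran(
    matrix: ExpressionMatrix,
    coords: SpatialCoords,
    k_neighbors: int = 6,
    n_perm: int = 999,
    seed: int = 0,
) -> GeneStatTable:
    """Permutation p-values for Moran's I on a symmetrized kNN spatial graph.

    One-sided (positive autocorrelation), with the add-one correction
    p = (1 + #{permuted I >= observed I}) / (1 + n_perm).  All genes share the
    same permutations of cell positions.  Constant genes get p = 1.
    """
    matrix, Z, moran, constant = _moran_setup(matrix, coords, k_neighbors)
    n = Z.shape[0]
    i_obs = moran(Z)
    rng = _sub_rng(seed, 11)
    exceed = np.zeros(Z.shape[1], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += moran(Z[perm]) >= i_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[constant] = 1.0
    return GeneStatTable(matrix.gene_ids.copy(), p, statistic_kind="p_value")


# ---------------------------------------------------------------------------
# thresholding


def threshold_hv(table: GeneStatTable, level: str) -> GeneSelection:
    """Select HV candidates at or above the level's percentile of candidates.

    Candidacy: statistic > 0 for CV excess, > 1 for residual variance.  The
    percentile (linear interpolation) is taken over candidate statistics only;
    ties at the cutoff are included.
    """
    if level not in HV_PERCENTILES:
        raise ValidationError(f"unknown level {level!r}")
    if table.statistic_kind == "cv_excess":
        cand = table.statistic > 0
    elif table.statistic_kind == "residual_variance":
        cand = table.statistic > 1
    else:
        raise ValidationError(
            f"threshold_hv expects cv_excess or residual_variance, got {table.statistic_kind}"
        )
    prov = {"statistic_kind": table.statistic_kind, "percentile": HV_PERCENTILES[level]}
    if not cand.any():
        warnings.warn("no HV candidate genes; selection is empty", stacklevel=2)
        return GeneSelection("hv", level, np.empty(0, dtype=str), prov)
    cutoff = np.percentile(table.statistic[cand], HV_PERCENTILES[level])
    keep = cand & (table.statistic >= cutoff)
    prov["cutoff"] = float(cutoff)
    return GeneSelection("hv", level, table.gene_ids[keep], prov)


def threshold_sv(table: GeneStatTable, level: str) -> GeneSelection:
    """Select SV genes: low = p < 0.05; medium/high nest sequentially within low."""
    if table.statistic_kind != "p_value":
        raise ValidationError("threshold_sv expects a p-value table")
    if level not in HV_PERCENTILES:
        raise ValidationError(f"unknown level {level!r}")
    p = table.statistic
    low = p < 0.05
    prov: dict = {"statistic_kind": "p_value", "low_cutoff": 0.05}
    keep = low
    if level in ("medium", "high") and low.any():
        med_cut = np.percentile(p[low], 25.0)
        keep = low & (p <= med_cut)
        prov["medium_cutoff"] = float(med_cut)
    if level == "high" and keep.any():
        high_cut = np.percentile(p[keep], 50.0)
        keep = keep & (p <= high_cut)
        prov["high_cutoff"] = float(high_cut)
    return GeneSelection("sv", level, table.gene_ids[keep], prov)


def concatenate(hv: GeneSelection, sv: GeneSelection) -> GeneSelection:
    """Set union, hv order first then sv-only genes, duplicates removed."""
    hv_set = set(hv.gene_ids.tolist())
    sv_only = [g for g in sv.gene_ids.tolist() if g not in hv_set]
    genes = np.asarray(list(hv.gene_ids) + sv_only, dtype=str)
    level = hv.level if hv.level == sv.level else f"{hv.level}/{sv.level}"
    return GeneSelection(
        "union",
        level,
        genes,
        {"hv": hv.provenance, "sv": sv.provenance, "n_overlap": len(hv) + len(sv) - len(genes)},
    )


def all_genes_selection(matrix: ExpressionMatrix, level: str = "low") -> GeneSelection:
    """The 'all genes' baseline: every gene surviving preprocessing."""
    return GeneSelection("all", level, matrix.gene_ids.copy(), {"rule": "all genes"})


# ---------------------------------------------------------------------------
# sklearn-style selectors


class HighlyVariableGenes(SelectorMixin, BaseEstimator):
    """Select HV genes from a cells x genes array.

    Parameters
    ----------
    method : {"loess_cv", "residual_variance"}
        ``loess_cv`` scores raw/rescaled expression by CV excess over a LOESS
        mean-CV trend; ``residual_variance`` expects Pearson residuals.
    level : {"low", "medium", "high"}
        Percentile stringency over candidate genes (50 / 70 / 90).
    """

    def __init__(self, method: str = "residual_variance", level: str = "low",
                 loess_span: float = 0.3):
        self.method = method
        self.level = level
        self.loess_span = loess_span

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        gene_ids = np.array([f"g{j}" for j in range(X.shape[1])])
        layer = "pearson" if self.method == "residual_variance" else "raw"
        if layer == "raw" and X.min() < 0:
            raise ValidationError("loess_cv method expects non-negative expression")
        em = ExpressionMatrix(X if layer == "raw" else np.abs(X),
                              np.array([f"c{i}" for i in range(X.shape[0])]),
                              gene_ids, layer="raw")
        if self.method == "loess_cv":
            table = hv_loess_cv(em, loess_span=self.loess_span)
        elif self.method == "residual_variance":
            table = GeneStatTable(gene_ids, X.var(axis=0, ddof=1), "residual_variance")
        else:
            raise ValidationError(f"unknown method {self.method!r}")
        self.scores_ = table.statistic
        sel = threshold_hv(table, self.level)
        self.support_ = np.isin(gene_ids, sel.gene_ids)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_


class SpatiallyVariableGenes(SelectorMixin, BaseEstimator):
    """Select SV genes by Moran's-I permutation p-values (or supplied p-values).

    ``fit(X, coords=...)`` scores genes with the built-in Moran scorer;
    ``fit(X, pvalues=...)`` consumes p-values from an external detector.
    """

    def __init__(self, level: str = "low", k_neighbors: int = 6,
                 n_perm: int = 999, random_state: int = 0):
        self.level = level
        self.k_neighbors = k_neighbors
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y=None, *, coords=None, pvalues=None):
        X = np.asarray(X, dtype=float)
        gene_ids = np.array([f"g{j}" for j in range(X.shape[1])])
        if pvalues is not None:
            table = GeneStatTable(gene_ids, np.asarray(pvalues, dtype=float), "p_value")
        elif coords is not None:
            cell_ids = np.array([f"c{i}" for i in range(X.shape[0])])
            em = ExpressionMatrix(X - X.min() if X.min() < 0 else X, cell_ids,
                                  gene_ids, layer="raw")
            sc = SpatialCoords(cell_ids, np.asarray(coords)[:, 0], np.asarray(coords)[:, 1])
            table = sv_score_moran(em, sc, self.k_neighbors, self.n_perm,
                                   self.random_state)
        else:
            raise ValidationError("fit requires coords= or pvalues=")
        self.pvalues_ = table.statistic
        sel = threshold_sv(table, self.level)
        self.support_ = np.isin(gene_ids, sel.gene_ids)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_
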