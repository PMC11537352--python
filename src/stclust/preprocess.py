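"""Filtering, rescaling and normalization ahead of feature selection.

Two normalization paths are supported, matching common practice per platform:
library-size scaling + log1p (``lognormalize``, used with a raw-count rescale
for imaging platforms with small panels) and analytic negative-binomial
Pearson residuals (``pearson_residuals``) under the offset model
mu_ij = (row_i total * col_j total) / grand total with fixed dispersion theta.

The array-level transforms are exposed as scikit-learn transformers
(:class:`LogNormalize`, :class:`PearsonResiduals`); the module functions wrap
them for :class:`~stclust.containers.ExpressionMatrix` inputs and keep the
layer bookkeeping.  The filters drop genes/cells and therefore stay functions.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    ExpressionMatrix,
    LabelSet,
    PreprocessReport,
    ValidationError,
    align,
)


def _tukey_keep(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Inclusive Tukey-fence mask: keep Q1 - k*IQR <= v <= Q3 + k*IQR.

    With IQR = 0 the fence collapses to [Q1, Q3], so constant distributions
    keep everything while gross outliers are still removed.
    """
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


def filter_outliers(
    matrix: ExpressionMatrix, k: float = 1.5
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Remove genes, then cells, whose mean expression is a Tukey-fence outlier.

    Gene means are screened first; cell means are recomputed on the retained
    genes before the cell screen.  Retained genes/cells keep their order.
    """
    if matrix.layer != "raw":
        raise ValidationError("filter_outliers expects raw counts")
    dense = matrix.to_dense()
    gene_means = dense.mean(axis=0)
    keep_genes = _tukey_keep(gene_means, k)
    if not keep_genes.any():
        raise ValidationError("outlier filter removed every gene")
    dense = dense[:, keep_genes]
    cell_means = dense.mean(axis=1)
    keep_cells = _tukey_keep(cell_means, k)
    if not keep_cells.any():
        raise ValidationError("outlier filter removed every cell")
    out = ExpressionMatrix(
        dense[keep_cells, :],
        matrix.cell_ids[keep_cells],
        matrix.gene_ids[keep_genes],
        layer="raw",
    )
    report = PreprocessReport(
        n_genes_removed=int((~keep_genes).sum()),
        n_cells_removed=int((~keep_cells).sum()),
        parameters={"rule": "tukey", "k": k},
    )
    return out, report


def filter_small_celltypes(
    matrix: ExpressionMatrix,
    truth: LabelSet,
    min_fraction: float = 0.05,
) -> tuple[ExpressionMatrix, LabelSet, PreprocessReport]:
    """Drop cells of truth classes holding strictly less than ``min_fraction``.

    Class frequencies are evaluated once on the input (not iteratively); a
    class at exactly the threshold is retained.
    """
    matrix, truth = align(matrix, labels=truth)
    labels = truth.labels
    n = labels.size
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts / n < min_fraction]
    keep = ~np.isin(labels, small)
    if not keep.any():
        raise ValidationError("cell-type filter removed every cell")
    report = PreprocessReport(
        n_cells_removed=int((~keep).sum()),
        removed_celltypes=sorted(small.tolist()),
        parameters={"min_fraction": min_fraction},
    )
    return matrix.subset_cells_mask(keep), truth.subset_mask(keep), report


def rescale(matrix: ExpressionMatrix, factor: float = 1000.0) -> ExpressionMatrix:
    """Multiply every entry by ``factor`` (panel-scale boost before log1p)."""
    if matrix.layer != "raw":
        raise ValidationError("rescale expects the raw layer")
    if factor <= 0:
        raise ValidationError("rescale factor must be > 0")
    values = matrix.values * factor if sp.issparse(matrix.values) else matrix.to_dense() * factor
    return matrix.with_values(values, layer="raw")


class LogNormalize(BaseEstimator, TransformerMixin):
    """Scale each cell's counts to the median cell total, then log1p.

    A stateless per-matrix transform (like :class:`sklearn.preprocessing.Normalizer`):
    the median total is taken from the matrix being transformed.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1)
        if np.any(totals <= 0):
            bad = np.flatnonzero(totals <= 0)[:5]
            raise ValidationError(f"cells with zero total counts at rows {bad.tolist()}")
        target = np.median(totals)
        return np.log1p(X * (target / totals)[:, None])


class PearsonResiduals(BaseEstimator, TransformerMixin):
    """Analytic NB Pearson residuals under the offset model.

    r_ij = (x_ij - mu_ij) / sqrt(mu_ij + mu_ij^2 / theta) with
    mu_ij = (row total_i * column total_j) / grand total, clipped to
    +/- sqrt(n_cells) (``clip=None``) or +/- ``clip``.
    """

    def __init__(self, theta: float = 100.0, clip: float | None = None):
        self.theta = theta
        self.clip = clip

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        grand = X.sum()
        if grand <= 0:
            raise ValidationError("zero grand total")
        row = X.sum(axis=1, keepdims=True)
        col = X.sum(axis=0, keepdims=True)
        mu = row @ col / grand
        denom = np.sqrt(mu + mu**2 / self.theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (X - mu) / denom, 0.0)
        clip = np.sqrt(X.shape[0]) if self.clip is None else self.clip
        return np.clip(r, -clip, clip)


def lognormalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    if np.min(matrix.to_dense()) < 0:
        raise ValidationError("lognormalize expects non-negative values")
    try:
        values = LogNormalize().fit_transform(matrix.to_dense())
    except ValidationError as exc:
        # report offending cells by id, not row index
        totals = matrix.to_dense().sum(axis=1)
        bad = matrix.cell_ids[totals <= 0][:5].tolist()
        raise ValidationError(f"cells with zero total counts: {bad}") from exc
    return matrix.with_values(values, layer="lognorm")


def pearson_residuals(
    matrix: ExpressionMatrix, theta: float = 100.0, clip: float | None = None
) -> ExpressionMatrix:
    if matrix.layer != "raw":
        raise ValidationError("pearson_residuals expects raw counts")
    values = PearsonResiduals(theta=theta, clip=clip).fit_transform(matrix.to_dense())
    return matrix.with_values(values, layer="pearson")
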