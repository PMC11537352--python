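"""Core in-memory containers shared across the pipeline.

All containers are lightweight dataclasses carrying explicit cell / gene
identifiers.  Alignment between files is always done by identifier with an
explicit join (see :func:`align`), never by row order: silent misalignment
between a count matrix and its coordinate or label table would corrupt every
downstream metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


LAYERS = ("raw", "lognorm", "pearson")
STAT_KINDS = ("cv_excess", "residual_variance", "p_value", "morans_i")
GENE_SET_SOURCES = ("hv", "sv", "union", "all")
LEVELS = ("low", "medium", "high")
METRIC_NAMES = (
    "ami",
    "weighted_f1",
    "pearson_gamma",
    "spatial_concordance",
    "mean_spatial_ami",
)


def _check_unique(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{what} must be a non-empty 1-d sequence")
    if len(pd.unique(arr)) != arr.size:
        dupes = pd.Series(arr).value_counts()
        dupes = list(dupes[dupes > 1].index[:5])
        raise ValidationError(f"duplicate {what}: {dupes}")
    return arr.astype(str)


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with a layer tag.

    ``layer`` records what the values mean: ``raw`` counts, ``lognorm``
    (library-size scaled, log1p) or ``pearson`` (negative-binomial Pearson
    residuals).  Raw layers must be finite and non-negative.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.shape != (self.cell_ids.size, self.gene_ids.size):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{self.cell_ids.size} cells x {self.gene_ids.size} genes"
            )
        if self.layer == "raw":
            data = self.values.data if sp.issparse(self.values) else np.asarray(self.values)
            if data.size and (not np.all(np.isfinite(data)) or np.min(data) < 0):
                raise ValidationError("raw counts must be finite and non-negative")

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.gene_ids)
        gene_ids = np.asarray(gene_ids, dtype=object)
        pos = idx.get_indexer(gene_ids)
        if np.any(pos < 0):
            missing = list(gene_ids[pos < 0][:5])
            raise ValidationError(f"genes not present in matrix: {missing}")
        return ExpressionMatrix(
            values=self.values[:, pos],
            cell_ids=self.cell_ids.copy(),
            gene_ids=np.asarray(gene_ids, dtype=str),
            layer=self.layer,
        )

    def subset_cells_mask(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionMatrix(
            values=self.values[mask, :],
            cell_ids=self.cell_ids[mask],
            gene_ids=self.gene_ids.copy(),
            layer=self.layer,
        )

    def with_values(self, values, layer: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            cell_ids=self.cell_ids.copy(),
            gene_ids=self.gene_ids.copy(),
            layer=layer,
        )


@dataclass
class SpatialCoords:
    """Per-cell 2-d tissue coordinates (arbitrary units)."""

    cell_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.cell_ids.shape or self.y.shape != self.cell_ids.shape:
            raise ValidationError("coordinate arrays must match cell ids in length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("coordinates must be finite")

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def subset_mask(self, mask: np.ndarray) -> "SpatialCoords":
        mask = np.asarray(mask, dtype=bool)
        return SpatialCoords(self.cell_ids[mask], self.x[mask], self.y[mask])


@dataclass
class LabelSet:
    """Per-cell categorical labels; class order is first-appearance order."""

    cell_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        labels = np.asarray(self.labels, dtype=object)
        if labels.shape != self.cell_ids.shape:
            raise ValidationError("labels must match cell ids in length")
        if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in labels):
            raise ValidationError("missing labels are not allowed")
        self.labels = labels.astype(str)
        if self.classes.size < 1:
            raise ValidationError("at least one label class required")

    @property
    def classes(self) -> np.ndarray:
        return pd.unique(self.labels)

    def subset_mask(self, mask: np.ndarray) -> "LabelSet":
        mask = np.asarray(mask, dtype=bool)
        return LabelSet(self.cell_ids[mask], self.labels[mask])


@dataclass
class GeneStatTable:
    """A per-gene statistic (CV excess, residual variance, p-value, Moran's I)."""

    gene_ids: np.ndarray
    statistic: np.ndarray
    statistic_kind: str

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.statistic = np.asarray(self.statistic, dtype=float)
        if self.statistic.shape != self.gene_ids.shape:
            raise ValidationError("statistic must match gene ids in length")
        if self.statistic_kind not in STAT_KINDS:
            raise ValidationError(
                f"unknown statistic_kind {self.statistic_kind!r}; expected one of {STAT_KINDS}"
            )
        if self.statistic_kind == "p_value":
            if np.any(np.isnan(self.statistic)) or np.any(
                (self.statistic < 0) | (self.statistic > 1)
            ):
                raise ValidationError("p-values must lie in [0, 1]")


@dataclass
class GeneSelection:
    """A named gene set (hv | sv | union | all) at a stringency level."""

    source: str
    level: str
    gene_ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in GENE_SET_SOURCES:
            raise ValidationError(f"unknown gene-set source {self.source!r}")
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        if gene_ids.size and len(pd.unique(gene_ids)) != gene_ids.size:
            raise ValidationError("gene selection contains duplicates")
        self.gene_ids = gene_ids.astype(str) if gene_ids.size else np.empty(0, dtype=str)

    def __len__(self) -> int:
        return int(self.gene_ids.size)


@dataclass
class MatchedLabels:
    """Ground-truth labels u and predicted labels u* mapped onto u's vocabulary."""

    cell_ids: np.ndarray
    u: np.ndarray
    u_star: np.ndarray
    mapping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        self.u = np.asarray(self.u, dtype=str)
        self.u_star = np.asarray(self.u_star, dtype=str)
        if self.u.shape != self.cell_ids.shape or self.u_star.shape != self.cell_ids.shape:
            raise ValidationError("u and u_star must match cell ids in length")


@dataclass
class MetricRecord:
    """One (dataset, gene set, method, metric, value) observation."""

    dataset: str
    gene_set: str
    threshold: str
    method: str
    metric: str
    value: float

    def __post_init__(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ValidationError(f"unknown metric {self.metric!r}")
        self.value = float(self.value)


@dataclass
class PreprocessReport:
    n_genes_removed: int = 0
    n_cells_removed: int = 0
    removed_celltypes: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)


@dataclass
class PairedTestResult:
    metric: str
    pair: tuple
    mean_difference: float
    p_value: float
    n_datasets: int
    n_permutations: int
    seed: int | None = None
    stars: str = ""


def align(
    matrix: ExpressionMatrix,
    coords: SpatialCoords | None = None,
    labels: LabelSet | None = None,
) -> tuple:
    """Reorder ``coords`` / ``labels`` to the matrix's cell order, by id.

    Unmatched ids on either side are an error, never silently dropped.
    """
    out = [matrix]
    idx = pd.Index(matrix.cell_ids)
    for other, name in ((coords, "coords"), (labels, "labels")):
        if other is None:
            continue
        other_idx = pd.Index(other.cell_ids)
        if len(other_idx) != len(idx) or not idx.sort_values().equals(
            other_idx.sort_values()
        ):
            raise ValidationError(
                f"cell ids of {name} do not match the expression matrix "
                f"({len(other_idx)} vs {len(idx)} cells)"
            )
        pos = other_idx.get_indexer(idx)
        if isinstance(other, SpatialCoords):
            out.append(SpatialCoords(other.cell_ids[pos], other.x[pos], other.y[pos]))
        else:
            out.append(LabelSet(other.cell_ids[pos], other.labels[pos]))
    return tuple(out)


def _sub_rng(seed: int, *stream: int) -> np.random.Generator:
    """Independent, reproducible RNG stream keyed on (seed, stream...)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *stream]))
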