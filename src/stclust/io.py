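"""Readers and writers for the plain-text formats the pipeline touches.

Counts travel either as MatrixMarket coordinate files with gene/cell id
sidecars (the common CellRanger-style layout, genes x cells on disk) or as
dense CSV (cells x genes, first column = cell id).  Coordinates, labels,
per-gene p-values and metric reports are all header-ed CSV.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    ExpressionMatrix,
    GeneStatTable,
    LabelSet,
    MetricRecord,
    SpatialCoords,
    ValidationError,
)

METRIC_COLUMNS = ["dataset", "gene_set", "threshold", "method", "metric", "value"]


def _read_id_file(path: str, what: str) -> np.ndarray:
    with open(path, "r", encoding="utf-8") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise ValidationError(f"empty {what} sidecar: {path}")
    return np.asarray(ids, dtype=str)


def read_counts(
    path: str,
    format: str = "mtx_triplet",
    *,
    genes_path: str | None = None,
    cells_path: str | None = None,
    orientation: str | None = None,
) -> ExpressionMatrix:
    """Read a raw count matrix.

    For ``mtx_triplet`` the sidecars default to ``genes.txt`` / ``cells.txt``
    next to the .mtx file and the on-disk orientation defaults to
    ``genes_by_cells``; for ``dense_csv`` the on-disk orientation defaults to
    ``cells_by_genes``.  The returned matrix is always cells x genes.
    """
    if format == "mtx_triplet":
        orientation = orientation or "genes_by_cells"
        base = os.path.dirname(path)
        genes_path = genes_path or os.path.join(base, "genes.txt")
        cells_path = cells_path or os.path.join(base, "cells.txt")
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ValidationError(f"malformed MatrixMarket file {path}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        gene_ids = _read_id_file(genes_path, "gene id")
        cell_ids = _read_id_file(cells_path, "cell id")
        if orientation == "genes_by_cells":
            mat = mat.T.tocsr()
        elif orientation != "cells_by_genes":
            raise ValidationError(f"unknown orientation {orientation!r}")
        if mat.shape != (cell_ids.size, gene_ids.size):
            raise ValidationError(
                f"matrix of shape {mat.shape} does not match sidecars "
                f"({cell_ids.size} cells, {gene_ids.size} genes)"
            )
        return ExpressionMatrix(mat, cell_ids, gene_ids, layer="raw")
    if format == "dense_csv":
        df = pd.read_csv(path, index_col=0)
        if df.shape[1] == 0 or df.shape[0] == 0:
            raise ValidationError(f"empty count CSV: {path}")
        try:
            values = df.to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric count in {path}: {exc}") from exc
        if orientation == "genes_by_cells":
            values = values.T
            cell_ids = df.columns.to_numpy(dtype=str)
            gene_ids = df.index.to_numpy(dtype=str)
        else:
            cell_ids = df.index.to_numpy(dtype=str)
            gene_ids = df.columns.to_numpy(dtype=str)
        return ExpressionMatrix(values, cell_ids, gene_ids, layer="raw")
    raise ValidationError(f"unknown counts format {format!r}")


def write_counts(matrix: ExpressionMatrix, path: str, format: str = "mtx_triplet") -> None:
    """Write counts in the layout :func:`read_counts` expects (genes x cells mtx)."""
    if format == "mtx_triplet":
        base = os.path.dirname(path)
        coo = sp.coo_matrix(matrix.values).T  # genes x cells on disk
        scipy.io.mmwrite(path, coo)
        with open(os.path.join(base, "genes.txt"), "w", encoding="utf-8") as fh:
            fh.write("\n".join(matrix.gene_ids) + "\n")
        with open(os.path.join(base, "cells.txt"), "w", encoding="utf-8") as fh:
            fh.write("\n".join(matrix.cell_ids) + "\n")
    elif format == "dense_csv":
        df = pd.DataFrame(matrix.to_dense(), index=matrix.cell_ids, columns=matrix.gene_ids)
        df.to_csv(path, index_label="cell_id")
    else:
        raise ValidationError(f"unknown counts format {format!r}")


def read_coords(path: str) -> SpatialCoords:
    """Read a coordinate table (CSV columns: id, x, y; order preserved)."""
    df = pd.read_csv(path)
    required = {"id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValidationError(f"coordinate file {path} must have columns id,x,y")
    try:
        x = pd.to_numeric(df["x"], errors="raise").to_numpy(dtype=float)
        y = pd.to_numeric(df["y"], errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric coordinate in {path}: {exc}") from exc
    if df["x"].isna().any() or df["y"].isna().any():
        raise ValidationError(f"missing coordinate in {path}")
    return SpatialCoords(df["id"].to_numpy(dtype=str), x, y)


def write_coords(coords: SpatialCoords, path: str) -> None:
    pd.DataFrame({"id": coords.cell_ids, "x": coords.x, "y": coords.y}).to_csv(
        path, index=False
    )


def read_labels(path: str) -> LabelSet:
    """Read a label table (CSV columns: id, label)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty label file {path}") from exc
    if not {"id", "label"}.issubset(df.columns):
        raise ValidationError(f"label file {path} must have columns id,label")
    if len(df) == 0:
        raise ValidationError(f"label file {path} has no rows")
    if df["label"].isna().any():
        missing = df.loc[df["label"].isna(), "id"].tolist()[:5]
        raise ValidationError(f"cells without labels in {path}: {missing}")
    return LabelSet(df["id"].to_numpy(dtype=str), df["label"].to_numpy(dtype=str))


def write_labels(labels: LabelSet, path: str) -> None:
    pd.DataFrame({"id": labels.cell_ids, "label": labels.labels}).to_csv(path, index=False)


def read_gene_pvalues(path: str) -> GeneStatTable:
    """Read per-gene p-values (CSV columns: gene, p), e.g. from an SV detector."""
    df = pd.read_csv(path)
    if not {"gene", "p"}.issubset(df.columns):
        raise ValidationError(f"p-value file {path} must have columns gene,p")
    p = pd.to_numeric(df["p"], errors="coerce").to_numpy(dtype=float)
    return GeneStatTable(df["gene"].to_numpy(dtype=str), p, statistic_kind="p_value")


def write_gene_pvalues(table: GeneStatTable, path: str) -> None:
    if table.statistic_kind != "p_value":
        raise ValidationError("table is not a p-value table")
    pd.DataFrame({"gene": table.gene_ids, "p": table.statistic}).to_csv(path, index=False)


def write_metric_records(records: Sequence[MetricRecord], path: str) -> None:
    """Write metric records as a long-format CSV with deterministic row order."""
    records = list(records)
    if not records:
        raise ValidationError("no metric records to write")
    df = pd.DataFrame([vars(r) for r in records])[METRIC_COLUMNS]
    df = df.sort_values(METRIC_COLUMNS[:-1], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False)


def read_metric_records(path: str) -> list[MetricRecord]:
    df = pd.read_csv(path)
    missing = set(METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"metric report {path} is missing columns {sorted(missing)}")
    return [
        MetricRecord(
            dataset=str(r.dataset),
            gene_set=str(r.gene_set),
            threshold=str(r.threshold),
            method=str(r.method),
            metric=str(r.metric),
            value=float(r.value),
        )
        for r in df.itertuples(index=False)
    ]
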