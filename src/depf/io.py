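"""Expression-matrix input/output and preprocessing.

Reads 10x-style Matrix Market triplets (matrix.mtx + barcodes.tsv +
features.tsv, plain or gzipped) or dense CSV/TSV, applies Seurat-style QC
filtering, log transform, and the per-cell min-max rescaling that feeds the
autoencoder stage.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "qc_filter",
    "log_transform",
    "minmax_normalize",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers.

    ``values`` may be a dense ndarray or a scipy sparse matrix; rows are
    cells, columns are genes, entries are non-negative counts or expression.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != m:
            raise ValueError(
                f"id lists ({len(self.cell_ids)}, {len(self.gene_ids)}) do not "
                f"match matrix shape {self.values.shape}"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids")
        if self.min() < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def min(self) -> float:
        v = self.values
        return float(v.min()) if not sp.issparse(v) else float(v.min())

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)


@dataclass
class NormalizedMatrix:
    """Per-cell rescaled matrix in [0, 1] plus a provenance trail."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    provenance: list[str] = field(default_factory=list)


def _open_maybe_gz(path: str):
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def _find_companion(directory: str, stems: tuple[str, ...]) -> str | None:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = os.path.join(directory, stem + suffix)
            if os.path.exists(cand):
                return cand
    return None


def _read_tsv_column(path: str) -> list[str]:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_matrix(
    path: str,
    format: str = "mtx_triplet",
    orientation: str = "cells_rows",
) -> ExpressionMatrix:
    """Read an expression matrix, returning it oriented cells x genes.

    Parameters
    ----------
    path
        For ``mtx_triplet``: the .mtx file (companion barcodes/features files
        must sit in the same directory under their standard 10x names). For
        ``csv_dense``: a CSV/TSV with a header row and an id column.
    format
        ``mtx_triplet`` or ``csv_dense``.
    orientation
        ``cells_rows`` or ``genes_rows`` — how the file on disk is laid out.
        10x triplets are conventionally genes x cells (``genes_rows``).
    """
    if format not in ("mtx_triplet", "csv_dense"):
        raise ValueError(f"unknown format {format!r}")
    if orientation not in ("cells_rows", "genes_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if format == "mtx_triplet":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001 - report offending file
            raise FormatError(f"malformed Matrix Market file {path}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        directory = os.path.dirname(os.path.abspath(path))
        bc = _find_companion(directory, ("barcodes.tsv",))
        ft = _find_companion(directory, ("features.tsv", "genes.tsv"))
        n_rows, n_cols = mat.shape
        if orientation == "genes_rows":
            mat = sp.csr_matrix(mat.T)
            n_rows, n_cols = mat.shape
        cell_ids = _read_tsv_column(bc) if bc else [f"cell{i}" for i in range(n_rows)]
        gene_ids = _read_tsv_column(ft) if ft else [f"gene{j}" for j in range(n_cols)]
        if len(cell_ids) != n_rows or len(gene_ids) != n_cols:
            raise FormatError(
                f"companion files ({len(cell_ids)} barcodes, {len(gene_ids)} "
                f"features) inconsistent with matrix shape {mat.shape}"
            )
        return ExpressionMatrix(mat, cell_ids, gene_ids)

    sep = "\t" if path.endswith((".tsv", ".tsv.gz", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes_rows":
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_matrix(X: ExpressionMatrix, path: str, format: str = "csv_dense") -> None:
    """Write a matrix; inverse of :func:`read_matrix` for both formats."""
    if format == "csv_dense":
        pd.DataFrame(X.dense(), index=X.cell_ids, columns=X.gene_ids).to_csv(path)
    elif format == "mtx_triplet":
        directory = os.path.dirname(os.path.abspath(path))
        scipy.io.mmwrite(path, sp.coo_matrix(X.values).T)  # genes x cells on disk
        with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(X.cell_ids) + "\n")
        with open(os.path.join(directory, "features.tsv"), "w") as fh:
            fh.write("\n".join(X.gene_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str, cell_ids: list[str] | None = None) -> np.ndarray:
    """Read a one-label-per-cell file (single column, optional cell_id column,
    optional header row)."""
    df = pd.read_csv(path, header=None)
    first = str(df.iloc[0, df.shape[1] - 1]).strip().lower()
    if first in ("label", "labels", "cluster", "cell_type"):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] == 2:
        series = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
        if cell_ids is not None:
            series = series.reindex(cell_ids)
        labels = series.to_numpy()
    else:
        labels = df.iloc[:, 0].to_numpy()
    codes, _ = pd.factorize(labels)
    return codes.astype(int)


def qc_filter(
    X: ExpressionMatrix,
    min_cells: int = 3,
    min_features: int = 200,
    max_mito_frac: float = 0.05,
    mito_prefix: str = "MT-",
) -> ExpressionMatrix:
    """Seurat-convention quality control.

    Genes expressed in fewer than ``min_cells`` cells are removed first; then
    cells with fewer than ``min_features`` expressed genes, and cells whose
    fraction of counts on genes matching ``mito_prefix`` (case-insensitive)
    exceeds ``max_mito_frac``, are removed.
    """
    if min_cells < 0 or min_features < 0 or not 0 <= max_mito_frac <= 1:
        raise ValueError("QC thresholds out of range")
    v = sp.csr_matrix(X.values) if sp.issparse(X.values) else np.asarray(X.values)

    nonzero = (v > 0).sum(axis=0)
    nonzero = np.asarray(nonzero).ravel()
    gene_keep = nonzero >= min_cells
    v = v[:, gene_keep]
    gene_ids = [g for g, k in zip(X.gene_ids, gene_keep) if k]

    feats = np.asarray((v > 0).sum(axis=1)).ravel()
    total = np.asarray(v.sum(axis=1)).ravel()
    mito = np.array([g.upper().startswith(mito_prefix.upper()) for g in gene_ids])
    mito_counts = np.asarray(v[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(v.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1e-300), 0.0)
    cell_keep = (feats >= min_features) & (mito_frac <= max_mito_frac)
    if not cell_keep.any():
        raise ValueError(
            "QC removed every cell; relax min_features / max_mito_frac thresholds"
        )
    v = v[cell_keep, :]
    cell_ids = [c for c, k in zip(X.cell_ids, cell_keep) if k]
    return ExpressionMatrix(v, cell_ids, gene_ids)


def log_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log(1 + x); zeros map to zero."""
    if X.min() < 0:
        raise ValueError("log transform requires non-negative values")
    v = X.values.copy()
    if sp.issparse(v):
        v = v.tocsr()
        v.data = np.log1p(v.data)
    else:
        v = np.log1p(np.asarray(v, dtype=float))
    return ExpressionMatrix(v, list(X.cell_ids), list(X.gene_ids))


def minmax_normalize(X: ExpressionMatrix, provenance: list[str] | None = None) -> NormalizedMatrix:
    """Per-cell min-max rescaling to [0, 1].

    M[i, j] = (X[i, j] - min_j X[i, j]) / (max_j X[i, j] - min_j X[i, j]).
    A cell whose values are all equal carries no contrast and maps to zeros.
    """
    v = X.dense().astype(float)
    if v.size == 0:
        raise ValueError("empty matrix")
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    rng = hi - lo
    out = np.where(rng > 0, (v - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    prov = list(provenance or []) + ["minmax"]
    return NormalizedMatrix(out, list(X.cell_ids), list(X.gene_ids), prov)
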