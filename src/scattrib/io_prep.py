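"""Expression-matrix containers, IO, preprocessing and normalization.

The package works on dense gene x cell matrices.  Two containers are used
throughout: :class:`CountMatrix` holds raw non-negative integer counts with
gene/cell identifiers and a per-cell cell-type label, and
:class:`LogNormMatrix` holds library-size-normalized log2 expression derived
from a count matrix.

On-disk formats are the Matrix Market coordinate triplet (genes as rows) with
``genes.tsv`` / ``cells.tsv`` sidecars, or a dense delimited file with a
header row of cell ids and a first column of gene ids.  Both sidecar files
carry a header row; ``cells.tsv`` must have columns ``cell_id`` and
``cell_type`` and may carry extra columns (e.g. ``sample``, ``condition``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class MatrixFormatError(ValueError):
    """Raised when on-disk files are malformed or mutually inconsistent."""


class EmptyResultError(ValueError):
    """Raised when a filtering stage empties the matrix; names the stage."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class CountMatrix:
    """Integer gene x cell count matrix with identifiers and labels.

    Parameters
    ----------
    counts
        Non-negative integer array of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique string identifiers for the rows / columns.
    cell_type
        Cell-type label per cell (same length as ``cell_ids``).
    cell_meta
        Optional extra per-cell columns (sample, condition, ...) indexed
        like ``cell_ids``.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_type: np.ndarray
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if sparse.issparse(self.counts):  # pragma: no cover - defensive
            self.counts = self.counts.toarray()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(self.cell_type) != len(self.cell_ids):
            raise ValueError("cell_type must label every cell")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            if not np.all(as_float == np.floor(as_float)):
                raise ValueError("counts must be integer-valued")
            self.counts = as_float.astype(np.int64)
        if self.counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_types(self) -> list:
        """Distinct cell-type labels in first-appearance order."""
        return list(pd.unique(self.cell_type))

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            self.counts[idx, :], self.gene_ids[idx], self.cell_ids,
            self.cell_type, self.cell_meta,
        )

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        meta = None
        if self.cell_meta is not None:
            meta = self.cell_meta.iloc[np.arange(self.n_cells)[idx] if idx.dtype == bool else idx]
            meta = meta.reset_index(drop=True)
        return CountMatrix(
            self.counts[:, idx], self.gene_ids, self.cell_ids[idx],
            self.cell_type[idx], meta,
        )

    def __eq__(self, other) -> bool:  # value semantics, used by round-trip tests
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.cell_type, other.cell_type)
        )


@dataclass
class LogNormMatrix:
    """Log2 library-size-normalized expression (genes x cells).

    ``values[g, c] = log2(counts[g, c] / size_factors[c] + 1)`` where the
    size factors are per-cell library sizes scaled to mean 1.  Zero counts
    map to exactly zero and the transform is monotone within a cell.
    """

    values: np.ndarray
    size_factors: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_type: np.ndarray
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_types(self) -> list:
        return list(pd.unique(self.cell_type))

    def subset_genes(self, mask_or_idx) -> "LogNormMatrix":
        idx = np.asarray(mask_or_idx)
        return replace(self, values=self.values[idx, :], gene_ids=self.gene_ids[idx])


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _read_cells_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise MatrixFormatError(f"cell file {path!r} is empty")
    if "cell_id" not in df.columns or "cell_type" not in df.columns:
        raise MatrixFormatError("cells.tsv needs 'cell_id' and 'cell_type' columns")
    return df


def read_matrix(path: str, *, genes: str | None = None, cells: str | None = None) -> CountMatrix:
    """Read a count matrix from disk.

    ``path`` is either a Matrix Market ``.mtx`` file (genes as rows, with
    ``genes``/``cells`` sidecar TSVs, defaulting to ``genes.tsv`` and
    ``cells.tsv`` next to the matrix) or a dense delimited ``.csv``/``.tsv``
    whose header row holds cell ids and whose first column holds gene ids
    (cell types still come from the ``cells`` sidecar).
    """
    if path.endswith(".mtx"):
        base = os.path.dirname(path)
        genes = genes or os.path.join(base, "genes.tsv")
        cells = cells or os.path.join(base, "cells.tsv")
        mat = spio.mmread(path)
        counts = np.asarray(mat.todense()) if sparse.issparse(mat) else np.asarray(mat)
        gdf = pd.read_csv(genes, sep="\t", dtype=str)
        if gdf.empty:
            raise MatrixFormatError(f"gene file {genes!r} is empty")
        cdf = _read_cells_tsv(cells)
        gene_ids = gdf.iloc[:, 0].to_numpy()
    else:
        sep = "," if path.endswith(".csv") else "\t"
        dense = pd.read_csv(path, sep=sep, index_col=0)
        counts = dense.to_numpy()
        gene_ids = dense.index.to_numpy(dtype=object)
        if cells is None:
            raise MatrixFormatError("dense format needs a cells sidecar for cell types")
        cdf = _read_cells_tsv(cells)
        order = {c: i for i, c in enumerate(cdf["cell_id"])}
        if list(dense.columns) != list(cdf["cell_id"]):
            if set(dense.columns) != set(order):
                raise MatrixFormatError("cell ids in matrix header and cells file differ")
            cdf = cdf.set_index("cell_id").loc[list(dense.columns)].reset_index()
    if counts.shape[0] != len(gene_ids):
        raise MatrixFormatError(
            f"matrix has {counts.shape[0]} rows but {len(gene_ids)} gene ids"
        )
    if counts.shape[1] != len(cdf):
        raise MatrixFormatError(
            f"matrix has {counts.shape[1]} columns but {len(cdf)} cell records"
        )
    if not np.all(counts == np.floor(np.asarray(counts, dtype=float))):
        raise MatrixFormatError("non-integer counts in matrix file")
    if np.asarray(counts, dtype=float).min(initial=0) < 0:
        raise MatrixFormatError("negative counts in matrix file")
    meta_cols = [c for c in cdf.columns if c not in ("cell_id", "cell_type")]
    meta = cdf[meta_cols].reset_index(drop=True) if meta_cols else None
    return CountMatrix(
        counts=np.asarray(counts, dtype=float).astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=cdf["cell_id"].to_numpy(dtype=object),
        cell_type=cdf["cell_type"].to_numpy(dtype=object),
        cell_meta=meta,
    )


def write_matrix(m: CountMatrix, out_dir: str, *, name: str = "matrix") -> str:
    """Write a CountMatrix as an MTX + TSV bundle; returns the .mtx path."""
    os.makedirs(out_dir, exist_ok=True)
    mtx_path = os.path.join(out_dir, f"{name}.mtx")
    spio.mmwrite(mtx_path, sparse.coo_matrix(m.counts))
    # scipy may append .mtx again if missing; we passed it explicitly
    pd.DataFrame({"gene_id": m.gene_ids}).to_csv(
        os.path.join(out_dir, "genes.tsv"), sep="\t", index=False
    )
    cdf = pd.DataFrame({"cell_id": m.cell_ids, "cell_type": m.cell_type})
    if m.cell_meta is not None:
        cdf = pd.concat([cdf, m.cell_meta.reset_index(drop=True)], axis=1)
    cdf.to_csv(os.path.join(out_dir, "cells.tsv"), sep="\t", index=False)
    return mtx_path


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(m: CountMatrix, min_cells_per_type: int = 300) -> CountMatrix:
    """Apply the atlas preprocessing rules.

    In order: drop cells with zero total expression, drop genes with zero
    expression in all cells, drop cell types with fewer than
    ``min_cells_per_type`` cells (strict), then re-check for genes that
    became all-zero after the type removal.  Idempotent.
    """
    cell_mask = m.counts.sum(axis=0) > 0
    if not cell_mask.any():
        raise EmptyResultError("all cells removed at zero-cell stage")
    m = m.subset_cells(cell_mask)
    gene_mask = m.counts.sum(axis=1) > 0
    if not gene_mask.any():
        raise EmptyResultError("all genes removed at zero-gene stage")
    m = m.subset_genes(gene_mask)
    sizes = pd.Series(m.cell_type).value_counts()
    keep_types = set(sizes.index[sizes >= min_cells_per_type])
    type_mask = np.array([t in keep_types for t in m.cell_type])
    if not type_mask.any():
        raise EmptyResultError("all cells removed at small-cell-type stage")
    m = m.subset_cells(type_mask)
    gene_mask = m.counts.sum(axis=1) > 0
    if not gene_mask.any():  # pragma: no cover - cannot happen with cells kept
        raise EmptyResultError("all genes removed after cell-type removal")
    return m.subset_genes(gene_mask)


def log_norm(m: CountMatrix) -> LogNormMatrix:
    """Library-size log-normalization.

    Size factor of a cell is its library size divided by the mean library
    size (so factors have mean 1); values are ``log2(count / sf + 1)``.
    """
    lib = m.counts.sum(axis=0).astype(float)
    if np.any(lib == 0):
        raise ValueError("cell with zero library size; run preprocess first")
    sf = lib / lib.mean()
    values = np.log2(m.counts / sf[np.newaxis, :] + 1.0)
    return LogNormMatrix(
        values=values, size_factors=sf, gene_ids=m.gene_ids,
        cell_ids=m.cell_ids, cell_type=m.cell_type, cell_meta=m.cell_meta,
    )


def filter_low_expression(m: LogNormMatrix, frac: float = 0.01) -> LogNormMatrix:
    """Drop genes expressed in less than ``frac`` of cells of every cell type.

    A gene survives if in at least one cell type the fraction of cells with
    nonzero expression is >= ``frac`` (removal requires strictly less than
    ``frac`` in each of all cell types).
    """
    types = m.cell_types()
    keep = np.zeros(m.n_genes, dtype=bool)
    for t in types:
        cols = m.cell_type == t
        frac_expr = (m.values[:, cols] > 0).mean(axis=1)
        keep |= frac_expr >= frac
    return m.subset_genes(keep)
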