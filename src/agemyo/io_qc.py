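"""Sparse count-matrix container, readers/writers, QC filtering, normalization
and the two downsampling primitives used throughout the pipeline.

Matrices are stored genes x cells (rows are genes), mirroring the MatrixMarket
fixtures on disk.  Counts are nonnegative integers; normalized matrices hold
log1p-transformed, depth-scaled reals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "NormMatrix",
    "QCThresholds",
    "read_matrix",
    "write_matrix",
    "qc_filter",
    "normalize_log1p",
    "downsample_cells",
    "downsample_counts",
]


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")
    return ids


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of nonnegative integer counts."""

    genes: np.ndarray
    cells: np.ndarray
    X: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = _check_ids(self.genes, "gene")
        self.cells = _check_ids(self.cells, "cell")
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match id lists "
                f"({len(self.genes)} genes, {len(self.cells)} cells)"
            )
        if self.X.nnz:
            if self.X.data.min() < 0:
                raise ValueError("negative counts")
            if not np.issubdtype(self.X.dtype, np.integer):
                if not np.allclose(self.X.data, np.round(self.X.data)):
                    raise ValueError("non-integer counts")
                self.X = self.X.astype(np.int64)
        self.X.sort_indices()

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.asarray((self.X > 0).sum(axis=0)).ravel()

    def cell_index(self, cell_ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cells)}
        try:
            return np.array([lookup[c] for c in cell_ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown cell id {err.args[0]!r}") from None

    def subset_cells(self, cell_ids) -> "CountMatrix":
        idx = self.cell_index(cell_ids)
        return CountMatrix(self.genes.copy(), np.asarray(cell_ids, dtype=object),
                           self.X[:, idx])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        lookup = {g: i for i, g in enumerate(self.genes)}
        idx = np.array([lookup[g] for g in gene_ids], dtype=int)
        return CountMatrix(np.asarray(gene_ids, dtype=object), self.cells.copy(),
                           self.X[idx, :])


@dataclass
class NormMatrix:
    """Gene x cell matrix of log-normalized expression (nonnegative reals)."""

    genes: np.ndarray
    cells: np.ndarray
    X: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = _check_ids(self.genes, "gene")
        self.cells = _check_ids(self.cells, "cell")
        self.X = sp.csr_matrix(self.X, dtype=np.float64)
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError("matrix shape does not match id lists")
        if self.X.nnz and not np.all(np.isfinite(self.X.data)):
            raise ValueError("non-finite normalized values")
        self.X.sort_indices()

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def subset_genes(self, gene_ids) -> "NormMatrix":
        lookup = {g: i for i, g in enumerate(self.genes)}
        idx = np.array([lookup[g] for g in gene_ids], dtype=int)
        return NormMatrix(np.asarray(gene_ids, dtype=object), self.cells.copy(),
                          self.X[idx, :])


@dataclass
class QCThresholds:
    """Cell QC bounds; all three are strict inequalities.

    A cell is kept when total counts > ``min_umi`` AND detected genes >
    ``min_genes`` AND mitochondrial fraction < ``max_mito_frac``.
    """

    min_umi: int = 1000
    min_genes: int = 500
    max_mito_frac: float = 0.05
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_umi < 0 or self.min_genes < 0:
            raise ValueError("QC thresholds must be nonnegative")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must lie in [0, 1]")


# ---------------------------------------------------------------------------
# I/O


def write_matrix(m: CountMatrix, path) -> None:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv`` into directory *path*."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(path / "matrix.mtx"), m.X.tocoo(), field="integer")
    pd.DataFrame({"gene_id": m.genes}).to_csv(path / "genes.tsv", sep="\t", index=False)
    pd.DataFrame({"cell_id": m.cells}).to_csv(path / "cells.tsv", sep="\t", index=False)


def _read_ids(path: Path, column: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column in df.columns:
        return df[column].to_numpy(dtype=object)
    # headerless single-column fallback
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def read_matrix(path) -> CountMatrix:
    """Read a MatrixMarket fixture directory (or a ``.h5`` container).

    The HDF5 layout holds COO triplets under ``/matrix`` (``row``, ``col``,
    ``data``, ``shape``) and id vectors under ``/genes`` and ``/cells``.
    """
    path = Path(path)
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "r") as f:
            row = f["/matrix/row"][:]
            col = f["/matrix/col"][:]
            data = f["/matrix/data"][:]
            shape = tuple(f["/matrix/shape"][:])
            genes = f["/genes"].asstr()[:]
            cells = f["/cells"].asstr()[:]
        X = sp.coo_matrix((data, (row, col)), shape=shape).tocsr()
        return CountMatrix(genes, cells, X)

    X = mmread(str(path / "matrix.mtx"))
    genes = _read_ids(path / "genes.tsv", "gene_id")
    cells = _read_ids(path / "cells.tsv", "cell_id")
    if X.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix.mtx dims {X.shape} disagree with sidecars "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    return CountMatrix(genes, cells, X.tocsr())


def write_matrix_h5(m: CountMatrix, path) -> None:
    import h5py

    coo = m.X.tocoo()
    with h5py.File(path, "w") as f:
        f.create_dataset("/matrix/row", data=coo.row)
        f.create_dataset("/matrix/col", data=coo.col)
        f.create_dataset("/matrix/data", data=coo.data)
        f.create_dataset("/matrix/shape", data=np.array(coo.shape))
        f.create_dataset("/genes", data=np.asarray(m.genes, dtype="S"))
        f.create_dataset("/cells", data=np.asarray(m.cells, dtype="S"))


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter(
    m: CountMatrix,
    cell_meta: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[CountMatrix, pd.DataFrame | None, dict]:
    """Drop cells failing any of the three strict QC bounds.

    Returns the filtered matrix, filtered metadata (rows of *cell_meta* whose
    ``cell_id`` survives, matrix order preserved) and a report dict with
    per-criterion removal counts.
    """
    t = thresholds or QCThresholds()
    totals = m.cell_totals()
    detected = m.genes_detected()
    mito_mask = np.array([str(g).startswith(t.mito_prefix) for g in m.genes])
    mito_counts = np.asarray(m.X[mito_mask, :].sum(axis=0)).ravel() if mito_mask.any() else np.zeros(len(m.cells))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    pass_umi = totals > t.min_umi
    pass_genes = detected > t.min_genes
    pass_mito = mito_frac < t.max_mito_frac
    keep = pass_umi & pass_genes & pass_mito

    report = {
        "n_input": int(len(m.cells)),
        "n_retained": int(keep.sum()),
        "fail_umi": int((~pass_umi).sum()),
        "fail_genes": int((~pass_genes).sum()),
        "fail_mito": int((~pass_mito).sum()),
        "thresholds": {
            "min_umi": t.min_umi,
            "min_genes": t.min_genes,
            "max_mito_frac": t.max_mito_frac,
        },
    }
    if keep.sum() == 0:
        warnings.warn("qc_filter removed every cell", stacklevel=2)

    kept_ids = m.cells[keep]
    out = CountMatrix(m.genes.copy(), kept_ids, m.X[:, keep])
    meta_out = None
    if cell_meta is not None:
        meta_out = cell_meta[cell_meta["cell_id"].isin(set(kept_ids))].copy()
        meta_out = meta_out.set_index("cell_id").loc[kept_ids].reset_index()
    return out, meta_out, report


def normalize_log1p(m: CountMatrix, target_sum: float = 1e4) -> NormMatrix:
    """Depth-normalize to *target_sum* counts per cell, then log1p.

    value = ln(1 + count * target_sum / cell_total).  Zero counts stay zero.
    """
    totals = m.cell_totals()
    if np.any(totals == 0):
        raise ValueError("normalize_log1p: zero-total cell (run qc_filter first)")
    X = m.X.tocsc(copy=True).astype(np.float64)
    scale = target_sum / totals
    # scale each column, then log1p on stored entries only
    X = X @ sp.diags(scale)
    X = X.tocsr()
    X.data = np.log1p(X.data)
    return NormMatrix(m.genes.copy(), m.cells.copy(), X)


# ---------------------------------------------------------------------------
# Downsampling primitives


def downsample_cells(cell_ids, n_max: int, seed) -> np.ndarray:
    """Simple random sample without replacement of min(n_max, len) cell ids.

    Original ordering is preserved in the returned subset; deterministic
    given *seed* (an int or a numpy Generator).
    """
    if n_max <= 0:
        raise ValueError("n_max must be positive")
    cell_ids = np.asarray(cell_ids, dtype=object)
    if len(cell_ids) <= n_max:
        return cell_ids.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cell_ids), size=n_max, replace=False)
    return cell_ids[np.sort(idx)]


def downsample_counts(m: CountMatrix, target_total: int, seed) -> CountMatrix:
    """Downsample every cell to exactly *target_total* counts without replacement.

    Each cell's count vector is replaced by a multivariate-hypergeometric draw
    of ``target_total`` molecules from its observed molecules, so per-cell
    totals are exactly equal afterwards and no entry exceeds the original.
    """
    if target_total < 0:
        raise ValueError("target_total must be nonnegative")
    totals = m.cell_totals()
    if np.any(totals < target_total):
        short = m.cells[totals < target_total][:3]
        raise ValueError(
            f"target_total {target_total} exceeds the total of cells {list(short)}"
        )
    rng = np.random.default_rng(seed)
    X = m.X.tocsc()
    indptr = X.indptr
    indices = X.indices
    data = X.data
    new_data = np.empty_like(data)
    for j in range(X.shape[1]):
        lo, hi = indptr[j], indptr[j + 1]
        col = data[lo:hi]
        if totals[j] == target_total:
            new_data[lo:hi] = col
        else:
            new_data[lo:hi] = rng.multivariate_hypergeometric(
                col.astype(np.int64), target_total
            )
    out = sp.csc_matrix((new_data, indices.copy(), indptr.copy()), shape=X.shape)
    out.eliminate_zeros()
    return CountMatrix(m.genes.copy(), m.cells.copy(), out.tocsr())
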