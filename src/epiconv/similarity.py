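"""Library-size-normalized cell-cell similarity from binary accessibility.

The similarity between two cells is the dot product of their binary peak
vectors — the number of co-accessible peaks — computed as the sparse matrix
product M^T M.  Because deeply sequenced cells share more peaks with
everything, the raw similarity is normalized by the product of the two
cells' library sizes, with a pseudocount and (by default) a log transform:

    s_ij = log((raw_ij + pseudocount) / (L_i * L_j))

The log tempers library-size-driven scale differences before the
eigendecomposition; a linear mode (no log) is exposed for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix_io import BinaryMatrix

logger = logging.getLogger(__name__)

__all__ = ["SimilarityMatrix", "raw_similarity", "normalize_similarity"]

#: above this many cells, dense S is refused; use the sampling path instead
DENSE_CELL_LIMIT = 20_000


@dataclass
class SimilarityMatrix:
    """Dense symmetric cell-cell similarity with per-cell metadata."""

    values: np.ndarray  # n x n
    cell_barcodes: np.ndarray
    batch_labels: np.ndarray | None
    library_sizes: np.ndarray | None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if len(self.cell_barcodes) != n:
            raise ValueError("barcode count must equal matrix dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric within 1e-10")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def raw_similarity(M: BinaryMatrix, max_cells: int = DENSE_CELL_LIMIT) -> SimilarityMatrix:
    """Raw co-accessibility counts: S = M^T M via a sparse product.

    The diagonal equals the per-cell library size.  Refuses inputs above
    ``max_cells`` cells — at that scale compute the decomposition on a cell
    sample and project the rest (see :mod:`epiconv.decomposition`).
    """
    if M.n_cells > max_cells:
        raise ValueError(
            f"{M.n_cells} cells exceeds the dense similarity limit {max_cells}; "
            "use the sampled decomposition path"
        )
    lib = M.library_sizes
    if (lib == 0).any():
        raise ValueError(
            "cells with zero accessible peaks present; run filter_cells first"
        )
    Mf = M.matrix.astype(np.float64)  # avoid int8 overflow in the product
    S = np.asarray((Mf.T @ Mf).todense())
    return SimilarityMatrix(S, M.cell_barcodes, M.batch_labels, lib)


def normalize_similarity(
    S_raw: SimilarityMatrix,
    pseudocount: float = 1.0,
    log_transform: bool = True,
) -> SimilarityMatrix:
    """Normalize raw co-accessibility by library-size products.

    ``(raw + pseudocount) / (L_i * L_j)``, log-transformed by default.
    Symmetry is preserved exactly; the diagonal is normalized like any other
    entry so the result stays a well-defined symmetric matrix for
    eigendecomposition.
    """
    if S_raw.library_sizes is None:
        raise ValueError("library_sizes required for normalization")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    L = S_raw.library_sizes.astype(np.float64)
    vals = (S_raw.values + pseudocount) / np.outer(L, L)
    if log_transform:
        vals = np.log(vals)
    logger.debug(
        "normalized similarity: pseudocount=%g log=%s", pseudocount, log_transform
    )
    return SimilarityMatrix(vals, S_raw.cell_barcodes, S_raw.batch_labels, S_raw.library_sizes)


def cross_similarity(
    M_ref: BinaryMatrix,
    M_query: BinaryMatrix,
    pseudocount: float = 1.0,
    log_transform: bool = True,
) -> np.ndarray:
    """Normalized similarity block between two cell sets (ref x query).

    Same formula as :func:`normalize_similarity`, applied to the
    rectangular cross block; used by the sampled-decomposition projection
    and by sequential integration.
    """
    lib_r = M_ref.library_sizes.astype(np.float64)
    lib_q = M_query.library_sizes.astype(np.float64)
    if (lib_r == 0).any() or (lib_q == 0).any():
        raise ValueError("zero-library cells present; run filter_cells first")
    raw = np.asarray(
        (M_ref.matrix.astype(np.float64).T @ M_query.matrix.astype(np.float64)).todense()
    )
    vals = (raw + pseudocount) / np.outer(lib_r, lib_q)
    return np.log(vals) if log_transform else vals


def save_similarity(S: SimilarityMatrix, path: str) -> None:
    """Persist a similarity matrix to HDF5 with barcode/batch attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=S.values, compression="gzip")
        fh.create_dataset(
            "cell_barcodes", data=np.asarray(S.cell_barcodes, dtype="S")
        )
        if S.batch_labels is not None:
            fh.create_dataset("batch_labels", data=np.asarray(S.batch_labels, dtype="S"))
        if S.library_sizes is not None:
            fh.create_dataset("library_sizes", data=S.library_sizes)


def load_similarity(path: str) -> SimilarityMatrix:
    import h5py

    with h5py.File(path, "r") as fh:
        values = fh["values"][...]
        barcodes = fh["cell_barcodes"][...].astype(str).astype(object)
        batches = (
            fh["batch_labels"][...].astype(str).astype(object)
            if "batch_labels" in fh
            else None
        )
        lib = fh["library_sizes"][...] if "library_sizes" in fh else None
    return SimilarityMatrix(values, barcodes, batches, lib)
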