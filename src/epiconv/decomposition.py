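"""Truncated eigendecomposition of the similarity matrix with residuals.

The normalized similarity S is symmetric but in general indefinite, so the
r retained eigenpairs are those of *largest absolute* eigenvalue.  The
residual R = S - X diag(L) X^T is stored explicitly and added back when the
similarity is reconstructed: the residual carries fine-grained (including
biological) structure outside the kept eigenspace, and batch correction
operates on X only, leaving R intact.

For datasets too large for a dense S, the decomposition is computed on a
cell sample and extended to the remaining cells by the least-squares
solution of S' = X_sample diag(L) X_unsample^T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityDecomposition",
    "eigen_decompose",
    "project_unsampled",
    "reconstruct",
    "scaled_coords",
]


@dataclass
class SimilarityDecomposition:
    """Eigenpairs X, eigenvalues, and residual R of a similarity matrix."""

    X: np.ndarray  # n x r, rows = cells
    eigenvalues: np.ndarray  # r, sorted by |value| descending
    R: np.ndarray  # n x n residual
    r: int
    cell_barcodes: np.ndarray
    batch_labels: np.ndarray | None = None
    library_sizes: np.ndarray | None = None
    sampled_mask: np.ndarray | None = None  # True where the cell was in the eigensolve
    corrected: bool = False

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each eigenvector positive."""
    idx = np.abs(V).argmax(axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def eigen_decompose(S: SimilarityMatrix, r: int = 30) -> SimilarityDecomposition:
    """Keep the r eigenpairs of largest |eigenvalue|; store the residual.

    S may be indefinite, so large negative eigenvalues are eligible.  The
    eigenvector sign convention (largest-magnitude component positive) makes
    results reproducible across solvers.
    """
    n = S.n_cells
    if not 1 <= r <= n:
        raise ValueError(f"r={r} must satisfy 1 <= r <= n={n}")
    try:
        w, V = scipy.linalg.eigh(S.values)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - solver failure
        raise RuntimeError(
            "eigendecomposition failed to converge; try a smaller r or a "
            "full decomposition with a different driver"
        ) from exc
    order = np.argsort(-np.abs(w), kind="stable")[:r]
    w = w[order]
    V = _fix_signs(V[:, order])
    R = S.values - (V * w) @ V.T
    logger.debug("kept %d/%d eigenvalues, |lambda| in [%g, %g]", r, n,
                 np.abs(w).min(), np.abs(w).max())
    return SimilarityDecomposition(
        X=V,
        eigenvalues=w,
        R=R,
        r=r,
        cell_barcodes=np.asarray(S.cell_barcodes, dtype=object),
        batch_labels=S.batch_labels,
        library_sizes=S.library_sizes,
        sampled_mask=np.ones(n, dtype=bool),
    )


def project_unsampled(
    decomp: SimilarityDecomposition,
    S_cross: np.ndarray,
    unsampled_barcodes: np.ndarray | None = None,
    unsampled_batches: np.ndarray | None = None,
) -> SimilarityDecomposition:
    """Extend a sampled decomposition to unsampled cells by least squares.

    ``S_cross`` (m1 sampled x m2 unsampled) is the normalized similarity
    between the sampled and unsampled cells.  Because X_sample has
    orthonormal columns, the least-squares solution of
    S' = X_sample diag(L) X_unsample^T is

        X_unsample = S'^T X_sample diag(L)^-1.

    Residuals for the cross block are S' - X_sample diag(L) X_unsample^T;
    unsampled x unsampled residuals are not representable without the full
    similarity and are set to 0 (the approximation's accepted loss).
    """
    S_cross = np.asarray(S_cross, dtype=np.float64)
    m1, m2 = S_cross.shape
    if m1 != decomp.n_cells:
        raise ValueError(
            f"S_cross has {m1} sampled rows but decomposition covers "
            f"{decomp.n_cells} cells"
        )
    if m2 == 0:
        return decomp
    w = decomp.eigenvalues
    if np.any(np.abs(w) < 1e-12):
        raise ValueError(
            "a kept eigenvalue is numerically zero; reduce r before projecting"
        )
    X_un = S_cross.T @ decomp.X / w  # divide column-wise by eigenvalues

    X = np.vstack([decomp.X, X_un])
    C = S_cross - (decomp.X * w) @ X_un.T  # cross-block residual
    n = m1 + m2
    R = np.zeros((n, n))
    R[:m1, :m1] = decomp.R
    R[:m1, m1:] = C
    R[m1:, :m1] = C.T

    if unsampled_barcodes is None:
        unsampled_barcodes = np.array(
            [f"unsampled_{i}" for i in range(m2)], dtype=object
        )
    barcodes = np.concatenate([decomp.cell_barcodes, np.asarray(unsampled_barcodes, dtype=object)])
    batches = None
    if decomp.batch_labels is not None and unsampled_batches is not None:
        batches = np.concatenate(
            [decomp.batch_labels, np.asarray(unsampled_batches, dtype=object)]
        )
    mask = np.zeros(n, dtype=bool)
    mask[:m1] = True
    return SimilarityDecomposition(
        X=X,
        eigenvalues=w,
        R=R,
        r=decomp.r,
        cell_barcodes=barcodes,
        batch_labels=batches,
        library_sizes=None,
        sampled_mask=mask,
    )


def reconstruct(
    decomp: SimilarityDecomposition, with_residuals: bool = True
) -> SimilarityMatrix:
    """Rebuild the similarity X diag(L) X^T (+ R unless disabled).

    After batch correction the residual added back is the one stored from
    the pre-correction decomposition — retaining it is what lets the
    correction preserve fine structure outside the kept eigenspace.
    """
    vals = (decomp.X * decomp.eigenvalues) @ decomp.X.T
    if with_residuals:
        vals = vals + decomp.R
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry
    return SimilarityMatrix(
        vals, decomp.cell_barcodes, decomp.batch_labels, decomp.library_sizes
    )


def scaled_coords(decomp: SimilarityDecomposition) -> np.ndarray:
    """Eigenvalue-weighted coordinates X * sqrt(|lambda|).

    Distances in this space weight each eigenvector by its contribution to
    the similarity matrix; used for cross-batch neighbor search.
    """
    return decomp.X * np.sqrt(np.abs(decomp.eigenvalues))


def sample_cells(n: int, m1: int, seed: int = 1) -> np.ndarray:
    """Uniform without-replacement cell sample for the large-data path."""
    rng = np.random.default_rng(seed)
    m1 = min(n, m1)
    return np.sort(rng.choice(n, size=m1, replace=False))


def save_decomposition(decomp: SimilarityDecomposition, path: str) -> None:
    """Persist a decomposition (X, eigenvalues, R, masks) to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("X", data=decomp.X)
        fh.create_dataset("eigenvalues", data=decomp.eigenvalues)
        fh.create_dataset("R", data=decomp.R, compression="gzip")
        fh.attrs["r"] = decomp.r
        fh.attrs["corrected"] = decomp.corrected
        fh.create_dataset("cell_barcodes", data=np.asarray(decomp.cell_barcodes, dtype="S"))
        if decomp.batch_labels is not None:
            fh.create_dataset("batch_labels", data=np.asarray(decomp.batch_labels, dtype="S"))
        if decomp.library_sizes is not None:
            fh.create_dataset("library_sizes", data=decomp.library_sizes)
        if decomp.sampled_mask is not None:
            fh.create_dataset("sampled_mask", data=decomp.sampled_mask)


def load_decomposition(path: str) -> SimilarityDecomposition:
    import h5py

    with h5py.File(path, "r") as fh:
        return SimilarityDecomposition(
            X=fh["X"][...],
            eigenvalues=fh["eigenvalues"][...],
            R=fh["R"][...],
            r=int(fh.attrs["r"]),
            cell_barcodes=fh["cell_barcodes"][...].astype(str).astype(object),
            batch_labels=(
                fh["batch_labels"][...].astype(str).astype(object)
                if "batch_labels" in fh else None
            ),
            library_sizes=fh["library_sizes"][...] if "library_sizes" in fh else None,
            sampled_mask=fh["sampled_mask"][...] if "sampled_mask" in fh else None,
            corrected=bool(fh.attrs["corrected"]),
        )
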