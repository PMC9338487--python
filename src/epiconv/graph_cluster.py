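"""SNN graph construction, distance transform, embedding and clustering.

The similarity matrix is denoised into a shared-nearest-neighbor (SNN)
graph: each cell keeps its k most similar cells (k = 1% of total cells,
floored at 5 for tiny inputs) and the edge weight between two cells is the
Jaccard overlap of their neighbor sets.  The elementwise transform
``max(S_snn) - S_snn`` turns the SNN weights into a distance matrix fed to
UMAP as precomputed input, and Louvain community detection runs on the
fuzzy graph UMAP builds from that distance matrix, so embedding and
clustering see the same topology.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .decomposition import SimilarityDecomposition, reconstruct
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SNNGraph",
    "ClusterLabels",
    "build_snn",
    "snn_from_affinity",
    "snn_from_coords",
    "snn_to_distance",
    "embed_and_cluster",
    "umap_graph",
    "cluster_graph",
]


@dataclass
class SNNGraph:
    """Symmetric sparse Jaccard-weighted shared-nearest-neighbor graph."""

    weights: sp.csr_matrix  # n x n, weights in [0, 1], zero diagonal
    k: int

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]


@dataclass
class ClusterLabels:
    """Integer cluster assignment per cell, labels contiguous from 0."""

    labels: np.ndarray
    resolution: float
    method: str = "louvain"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            # re-map to contiguous 0..k-1 preserving first-appearance order
            remap = {old: new for new, old in enumerate(pd_unique(self.labels))}
            self.labels = np.array([remap[v] for v in self.labels], dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def pd_unique(arr: np.ndarray) -> np.ndarray:
    """Unique values in first-appearance order."""
    _, idx = np.unique(arr, return_index=True)
    return arr[np.sort(idx)]


def _knn_sets(affinity: np.ndarray, k: int) -> sp.csr_matrix:
    """Row i -> indicator of its k highest-affinity cells (self excluded)."""
    n = affinity.shape[0]
    A = affinity.copy()
    np.fill_diagonal(A, -np.inf)
    # argsort descending with stable index tie-break
    order = np.argsort(-A, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = order.ravel()
    return sp.csr_matrix(
        (np.ones(n * k, dtype=np.float64), (rows, cols)), shape=(n, n)
    )


def snn_from_affinity(affinity: np.ndarray, k: int) -> SNNGraph:
    """SNN graph from any symmetric affinity (higher = more similar)."""
    n = affinity.shape[0]
    k = min(k, n - 1)
    A = _knn_sets(affinity, k)
    inter = (A @ A.T).toarray()
    union = 2.0 * k - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(jac, 0.0)
    W = sp.csr_matrix(jac)
    return SNNGraph(weights=W, k=k)


def snn_from_coords(Y: np.ndarray, k: int) -> SNNGraph:
    """SNN graph from coordinates (neighbors by Euclidean distance)."""
    Y = np.asarray(Y, dtype=np.float64)
    sq = np.sum(Y**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * Y @ Y.T
    return snn_from_affinity(-d2, k)


def build_snn(
    sim_or_decomp: SimilarityMatrix | SimilarityDecomposition,
    k_fraction: float = 0.01,
) -> SNNGraph:
    """SNN graph with k = max(5, round(k_fraction * n)) nearest neighbors.

    Neighbors are ranked by (reconstructed) similarity — highest similarity
    is nearest.  The floor of 5 keeps tiny inputs usable (1% of 100 cells
    would be a single neighbor).
    """
    if isinstance(sim_or_decomp, SimilarityDecomposition):
        sim = reconstruct(sim_or_decomp)
    else:
        sim = sim_or_decomp
    n = sim.n_cells
    if n < 10:
        raise ValueError("need at least 10 cells to build an SNN graph")
    k = max(5, int(round(k_fraction * n)))
    if k != round(k_fraction * n):
        logger.info("SNN neighbor count floored at %d for n=%d", k, n)
    return snn_from_affinity(sim.values, k)


def snn_to_distance(snn: SNNGraph) -> np.ndarray:
    """Distance matrix max(S_snn) - S_snn, diagonal forced to 0."""
    W = snn.weights.toarray()
    D = W.max() - W
    np.fill_diagonal(D, 0.0)
    return D


def umap_graph(
    D: np.ndarray,
    seed: int = 1,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
):
    """Run UMAP on a precomputed distance matrix.

    Returns (embedding, fuzzy_graph): the 2-D embedding and the symmetrized
    fuzzy simplicial set UMAP builds internally, which is the graph Louvain
    clusters so that embedding and clustering agree.
    """
    import umap  # deferred: heavy numba compilation on first import

    n = D.shape[0]
    reducer = umap.UMAP(
        n_components=2,
        metric="precomputed",
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    emb = reducer.fit_transform(D)
    G = reducer.graph_.tocsr()
    return np.asarray(emb), G


def cluster_graph(
    G: sp.spmatrix,
    resolution: float = 0.8,
    seed: int = 1,
    method: str = "louvain",
) -> ClusterLabels:
    """Community detection on a weighted graph at a given resolution.

    Louvain (igraph multilevel) by default; Leiden available as an
    alternative.  The igraph RNG is seeded through Python's ``random``
    module for run-to-run determinism.
    """
    try:
        import igraph as ig
    except ImportError as exc:  # pragma: no cover
        raise ImportError("python-igraph is required for clustering") from exc

    G = sp.csr_matrix(G)
    Gs = (G + G.T) / 2.0
    coo = sp.triu(Gs, k=1).tocoo()
    edges = list(zip(coo.row.tolist(), coo.col.tolist()))
    g = ig.Graph(n=Gs.shape[0], edges=edges)
    weights = coo.data.tolist()

    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        if method == "louvain":
            part = g.community_multilevel(weights=weights, resolution=resolution)
            membership = part.membership
        elif method == "leiden":
            import leidenalg as la

            part = la.find_partition(
                g,
                la.RBConfigurationVertexPartition,
                weights=weights,
                resolution_parameter=resolution,
                seed=seed,
            )
            membership = part.membership
        else:
            raise ValueError(f"unknown clustering method: {method!r}")
    finally:
        _pyrandom.setstate(state)
    return ClusterLabels(np.asarray(membership), resolution=resolution, method=method)


def embed_and_cluster(
    D: np.ndarray,
    resolution: float = 0.8,
    seed: int = 1,
    method: str = "louvain",
    n_neighbors: int = 15,
) -> tuple[np.ndarray, ClusterLabels]:
    """UMAP embedding plus Louvain clustering of the UMAP fuzzy graph.

    ``D`` should come from :func:`snn_to_distance`.  Resolutions between
    0.2 and 2.0 are the recommended exploration range.
    """
    emb, G = umap_graph(D, seed=seed, n_neighbors=n_neighbors)
    labels = cluster_graph(G, resolution=resolution, seed=seed, method=method)
    return emb, labels
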