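"""Batch correction on eigenvectors of the similarity matrix.

Correction proceeds in four steps for a query batch A against a reference
batch B, all in the r-dimensional eigenvector space of the normalized
similarity over the union of both batches:

1. cross-batch KNN: each query cell finds its k1 nearest reference cells,
   and each reference cell its k2 nearest query cells (Euclidean distance
   in the eigenvalue-weighted space X * sqrt(|lambda|));
2. neighbor filtering: for each reference cell b, the per-dimension mean
   u_b and standard deviation sigma_b of its k2 query neighbors define a
   band u_b +/- 2 sigma_b; a query cell keeps neighbor b only if it lies
   inside the band in EVERY eigenvector (and every RNA PC when multi-omic
   coordinates are supplied);
3. anchors: query cells retaining at least ``min_anchor_neighbors``
   neighbors become anchors, with correction vector the mean displacement
   toward their retained reference neighbors; non-anchor cells inherit the
   SNN-weighted mean of their ``n_prop_anchors`` most similar anchors;
4. the query rows of X are shifted by their correction vectors and the
   similarity is rebuilt from the corrected eigenvectors plus the
   *original* residuals.

Multiple datasets integrate sequentially: project the second reference
onto the first, then each further batch onto the growing corrected
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .decomposition import (
    SimilarityDecomposition,
    eigen_decompose,
    reconstruct,
    scaled_coords,
)
from .graph_cluster import SNNGraph, snn_from_coords
from .matrix_io import BinaryMatrix
from .similarity import (
    SimilarityMatrix,
    cross_similarity,
    normalize_similarity,
    raw_similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "AnchorSet",
    "IntegrationConfig",
    "knn_between_batches",
    "filter_neighbors",
    "compute_correction",
    "apply_correction",
    "integrate_datasets",
]


@dataclass
class NeighborGraph:
    """Bidirectional cross-batch KNN lists in eigenvector space."""

    query_indices: np.ndarray  # global cell indices of the query batch
    ref_indices: np.ndarray  # global cell indices of the reference batch
    neighbors: list[np.ndarray]  # per query cell: ref global indices, nearest first
    distances: list[np.ndarray]
    ref_neighbors: list[np.ndarray]  # per ref cell: query global indices, nearest first
    k1: int
    k2: int


@dataclass
class AnchorSet:
    """Anchor mask and per-query-cell correction vectors."""

    query_indices: np.ndarray
    anchor_mask: np.ndarray  # query-local boolean
    correction: np.ndarray  # n_query x r
    retained_neighbors: list[np.ndarray]

    @property
    def n_anchors(self) -> int:
        return int(self.anchor_mask.sum())


def _default_k(n_other: int) -> int:
    return max(20, int(round(0.01 * n_other)))


def knn_between_batches(
    decomp: SimilarityDecomposition,
    query_cells: np.ndarray,
    ref_cells: np.ndarray,
    k1: int | None = None,
    k2: int | None = None,
) -> NeighborGraph:
    """Cross-batch KNN in the eigenvalue-weighted eigenvector space.

    Returns both directions: query -> reference with k1 neighbors and
    reference -> query with k2.  Defaults: max(20, 1% of the other batch).
    """
    query_cells = np.asarray(query_cells)
    ref_cells = np.asarray(ref_cells)
    if len(query_cells) == 0 or len(ref_cells) == 0:
        raise ValueError("both batches must be non-empty")
    if k1 is None:
        k1 = _default_k(len(ref_cells))
    if k2 is None:
        k2 = _default_k(len(query_cells))
    k1 = min(k1, len(ref_cells))
    k2 = min(k2, len(query_cells))

    Y = scaled_coords(decomp)
    Yq, Yr = Y[query_cells], Y[ref_cells]

    nn_r = NearestNeighbors(n_neighbors=k1).fit(Yr)
    dist_q, idx_q = nn_r.kneighbors(Yq)
    nn_q = NearestNeighbors(n_neighbors=k2).fit(Yq)
    _, idx_r = nn_q.kneighbors(Yr)

    return NeighborGraph(
        query_indices=query_cells,
        ref_indices=ref_cells,
        neighbors=[ref_cells[row] for row in idx_q],
        distances=[row.copy() for row in dist_q],
        ref_neighbors=[query_cells[row] for row in idx_r],
        k1=k1,
        k2=k2,
    )


def filter_neighbors(
    graph: NeighborGraph,
    decomp: SimilarityDecomposition,
    rna_pcs: np.ndarray | None = None,
) -> NeighborGraph:
    """Drop implausible cross-batch neighbors with the 2-sigma band rule.

    For each reference cell b, u_b and sigma_b are the mean and standard
    deviation of b's k2 query-side neighbors in each eigenvector (and each
    RNA PC when ``rna_pcs`` rows, aligned with the query batch, are given).
    A query cell a loses neighbor b iff a lies outside u_b +/- 2 sigma_b in
    ANY dimension.  Never adds neighbors.
    """
    if graph.k2 < 2:
        raise ValueError("k2 must be >= 2 for the sigma filter to be defined")
    coords = decomp.X
    if rna_pcs is not None:
        rna_pcs = np.asarray(rna_pcs, dtype=np.float64)
        if rna_pcs.shape[0] != len(graph.query_indices):
            raise ValueError("rna_pcs rows must align with query cells")
        full = np.zeros((decomp.n_cells, coords.shape[1] + rna_pcs.shape[1]))
        full[:, : coords.shape[1]] = coords
        full[graph.query_indices, coords.shape[1]:] = rna_pcs
        coords = full

    ref_pos = {g: i for i, g in enumerate(graph.ref_indices)}
    u = np.empty((len(graph.ref_indices), coords.shape[1]))
    sig = np.empty_like(u)
    for i, nbrs in enumerate(graph.ref_neighbors):
        pts = coords[nbrs]
        u[i] = pts.mean(axis=0)
        sig[i] = pts.std(axis=0, ddof=1)

    new_neighbors, new_distances = [], []
    n_removed = 0
    for a_local, (nbrs, dists) in enumerate(zip(graph.neighbors, graph.distances)):
        a = graph.query_indices[a_local]
        xa = coords[a]
        keep = np.ones(len(nbrs), dtype=bool)
        for j, b in enumerate(nbrs):
            bi = ref_pos[b]
            if np.any(np.abs(xa - u[bi]) > 2.0 * sig[bi]):
                keep[j] = False
        n_removed += int((~keep).sum())
        new_neighbors.append(nbrs[keep])
        new_distances.append(dists[keep])
    logger.info(
        "sigma filter removed %d of %d cross-batch neighbor links",
        n_removed, sum(len(n) for n in graph.neighbors),
    )
    return NeighborGraph(
        query_indices=graph.query_indices,
        ref_indices=graph.ref_indices,
        neighbors=new_neighbors,
        distances=new_distances,
        ref_neighbors=graph.ref_neighbors,
        k1=graph.k1,
        k2=graph.k2,
    )


def compute_correction(
    graph_filtered: NeighborGraph,
    decomp: SimilarityDecomposition,
    snn: SNNGraph,
    min_anchor_neighbors: int = 5,
    n_prop_anchors: int = 10,
) -> AnchorSet:
    """Correction vectors: anchors average their neighbor displacements.

    Anchors are query cells with >= ``min_anchor_neighbors`` retained
    neighbors; their correction is the mean of (X_b - X_a) over retained
    reference neighbors b.  Every other query cell takes the weighted mean
    of its ``n_prop_anchors`` highest-SNN-weight anchors (weight = SNN edge;
    ties broken by cell index).  Cells with zero SNN weight to every anchor
    fall back to the unweighted mean of all anchor vectors (logged).

    ``snn`` must be built over the query cells only (from their own
    eigenvectors, or from RNA PCs for co-assay data).
    """
    q = graph_filtered.query_indices
    nq = len(q)
    if snn.n_cells != nq:
        raise ValueError("SNN graph must cover exactly the query cells")
    X = decomp.X
    counts = np.array([len(n) for n in graph_filtered.neighbors])
    anchor_mask = counts >= min_anchor_neighbors
    if not anchor_mask.any():
        raise ValueError(
            "no anchors: no query cell retained "
            f">= {min_anchor_neighbors} neighbors after filtering "
            f"(retained-neighbor counts: max={counts.max() if nq else 0}, "
            f"median={np.median(counts) if nq else 0})"
        )

    correction = np.zeros((nq, X.shape[1]))
    anchor_locals = np.flatnonzero(anchor_mask)
    for a_local in anchor_locals:
        nbrs = graph_filtered.neighbors[a_local]
        correction[a_local] = (X[nbrs] - X[q[a_local]]).mean(axis=0)

    W = snn.weights.toarray()
    anchor_vecs = correction[anchor_locals]
    n_fallback = 0
    for a_local in np.flatnonzero(~anchor_mask):
        w = W[a_local, anchor_locals]
        if not np.any(w > 0):
            correction[a_local] = anchor_vecs.mean(axis=0)
            n_fallback += 1
            continue
        # top anchors by SNN weight, stable index tie-break
        order = np.argsort(-w, kind="stable")[:n_prop_anchors]
        order = order[w[order] > 0]
        ww = w[order]
        correction[a_local] = (ww @ anchor_vecs[order]) / ww.sum()
    if n_fallback:
        logger.info(
            "%d non-anchor cells had no SNN link to any anchor; "
            "used the global anchor mean", n_fallback,
        )
    return AnchorSet(
        query_indices=q,
        anchor_mask=anchor_mask,
        correction=correction,
        retained_neighbors=graph_filtered.neighbors,
    )


def apply_correction(
    decomp: SimilarityDecomposition, anchors: AnchorSet
) -> SimilarityDecomposition:
    """Shift query eigenvector rows by their correction vectors.

    Reference rows are untouched and the stored residual is carried over
    unchanged.  Applying a correction to an already-corrected decomposition
    is refused — corrections are estimated against the uncorrected geometry
    and do not compose.
    """
    if decomp.corrected:
        raise ValueError(
            "decomposition already corrected; re-estimate anchors on a fresh "
            "decomposition instead of correcting twice"
        )
    if not np.all(np.isfinite(anchors.correction)):
        raise ValueError("non-finite correction vectors")
    X = decomp.X.copy()
    X[anchors.query_indices] += anchors.correction
    return replace(decomp, X=X, corrected=True)


@dataclass
class IntegrationConfig:
    """Knobs of the sequential integration pipeline."""

    r: int = 30
    k1: int | None = None
    k2: int | None = None
    min_anchor_neighbors: int = 5
    n_prop_anchors: int = 10
    pseudocount: float = 1.0
    log_transform: bool = True
    snn_k_fraction: float = 0.01
    seed: int = 1


def integrate_datasets(
    matrices: list[BinaryMatrix],
    config: IntegrationConfig | None = None,
    batch_names: list[str] | None = None,
    rna_pcs: dict[int, np.ndarray] | None = None,
) -> tuple[SimilarityDecomposition, list[dict]]:
    """Sequentially align batches onto a growing corrected reference.

    Batch 0 is the fixed reference frame.  For each further batch the
    normalized similarity over the union is assembled (the already-
    integrated block keeps its corrected values), decomposed, and the new
    batch is corrected toward the integrated reference via KNN, the
    2-sigma filter, anchors and SNN propagation.  Returns the final
    corrected decomposition over all cells and a per-step provenance log.

    ``rna_pcs`` optionally maps a batch position to an RNA-PC matrix for
    that batch (rows aligned with its cells); the PCs join the sigma filter
    dimensions and replace the ATAC SNN graph for correction propagation.
    """
    if config is None:
        config = IntegrationConfig()
    if len(matrices) < 2:
        raise ValueError("nothing to integrate: need at least 2 batches")
    if batch_names is None:
        batch_names = [f"batch{i}" for i in range(len(matrices))]
    rna_pcs = rna_pcs or {}
    ref_ids = matrices[0].peak_ids
    for m in matrices[1:]:
        if len(m.peak_ids) != len(ref_ids) or not (m.peak_ids == ref_ids).all():
            raise ValueError("peak id mismatch between batches; harmonize peaks first")

    # namespace barcodes once so unions stay unique across batches
    batches = [
        BinaryMatrix(
            m.matrix,
            m.peak_ids,
            np.array([f"{name}:{bc}" for bc in m.cell_barcodes], dtype=object),
            np.repeat(np.array([name], dtype=object), m.n_cells),
        )
        for m, name in zip(matrices, batch_names)
    ]

    log: list[dict] = []
    combined = batches[0]
    S_curr = normalize_similarity(
        raw_similarity(combined), config.pseudocount, config.log_transform
    )
    decomp_c: SimilarityDecomposition | None = None

    for step, (M_new, name) in enumerate(zip(batches[1:], batch_names[1:]), start=1):
        n_ref = combined.n_cells
        n_new = M_new.n_cells
        n = n_ref + n_new
        # assemble the union similarity; the integrated block keeps its
        # corrected values from previous steps
        S_new = normalize_similarity(
            raw_similarity(M_new), config.pseudocount, config.log_transform
        )
        S_cross = cross_similarity(
            combined, M_new, config.pseudocount, config.log_transform
        )
        vals = np.empty((n, n))
        vals[:n_ref, :n_ref] = S_curr.values
        vals[:n_ref, n_ref:] = S_cross
        vals[n_ref:, :n_ref] = S_cross.T
        vals[n_ref:, n_ref:] = S_new.values

        barcodes = np.concatenate([combined.cell_barcodes, M_new.cell_barcodes])
        batch_labels = np.concatenate([combined.batch_labels, M_new.batch_labels])
        lib = np.concatenate([combined.library_sizes, M_new.library_sizes])
        S_union = SimilarityMatrix(vals, barcodes, batch_labels, lib)

        decomp = eigen_decompose(S_union, r=min(config.r, n))
        query = np.arange(n_ref, n)
        ref = np.arange(n_ref)
        graph = knn_between_batches(decomp, query, ref, config.k1, config.k2)
        pcs = rna_pcs.get(step)
        graph_f = filter_neighbors(graph, decomp, pcs)

        k_snn = max(5, int(round(config.snn_k_fraction * n_new)))
        snn_coords = pcs if pcs is not None else scaled_coords(decomp)[query]
        snn = snn_from_coords(snn_coords, k_snn)

        anchors = compute_correction(
            graph_f, decomp, snn,
            config.min_anchor_neighbors, config.n_prop_anchors,
        )
        decomp_c = apply_correction(decomp, anchors)
        S_curr = reconstruct(decomp_c)

        log.append(
            {
                "step": step,
                "query_batch": name,
                "n_ref": int(n_ref),
                "n_query": int(n_new),
                "k1": graph.k1,
                "k2": graph.k2,
                "n_anchors": anchors.n_anchors,
                "neighbor_links_kept": int(sum(len(x) for x in graph_f.neighbors)),
                "neighbor_links_initial": int(sum(len(x) for x in graph.neighbors)),
                "r": decomp.r,
            }
        )
        # merge the new batch into the integrated reference for the next step
        combined = BinaryMatrix(
            sp.hstack([combined.matrix, M_new.matrix], format="csc"),
            combined.peak_ids,
            barcodes,
            batch_labels,
        )
        decomp_c = replace(
            decomp_c, batch_labels=batch_labels, cell_barcodes=barcodes,
            library_sizes=lib,
        )

    assert decomp_c is not None
    return decomp_c, log
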