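"""Cross-batch KNN, the 2-sigma neighbor filter, anchors, and correction."""

import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp

from epiconv.decomposition import SimilarityDecomposition, reconstruct, scaled_coords
from epiconv.graph_cluster import SNNGraph, snn_from_coords
from epiconv.integration import (
    IntegrationConfig,
    apply_correction,
    compute_correction,
    filter_neighbors,
    integrate_datasets,
    knn_between_batches,
)
from epiconv.metrics import lisi
from epiconv.synthetic import SimulationConfig, simulate


def make_decomp(X, eigenvalues=None, R=None):
    n, r = X.shape
    if eigenvalues is None:
        eigenvalues = np.ones(r)
    if R is None:
        R = np.zeros((n, n))
    return SimilarityDecomposition(
        X=np.asarray(X, dtype=np.float64),
        eigenvalues=np.asarray(eigenvalues, dtype=np.float64),
        R=R,
        r=r,
        cell_barcodes=np.array([f"c{i}" for i in range(n)], dtype=object),
    )


class TestKnnBetweenBatches:
    def test_identical_row_is_nearest_at_zero_distance(self, rng):
        X = rng.normal(size=(10, 3))
        X[7] = X[2]  # query cell 7 duplicates reference cell 2
        g = knn_between_batches(make_decomp(X), np.arange(5, 10), np.arange(5), k1=2, k2=2)
        assert g.neighbors[2][0] == 2 and g.distances[2][0] == pytest.approx(0.0)

    def test_k1_equal_ref_size_lists_everyone(self, rng):
        X = rng.normal(size=(8, 2))
        g = knn_between_batches(make_decomp(X), np.arange(4, 8), np.arange(4), k1=4, k2=2)
        assert all(sorted(nb) == [0, 1, 2, 3] for nb in g.neighbors)

    def test_neighbors_respect_planted_clusters(self, rng):
        # two well-separated clusters present in both batches
        centers = np.array([[0.0, 0.0], [50.0, 50.0]])
        labels = np.repeat([0, 1], 20)
        X = centers[np.tile(labels, 2)] + rng.normal(scale=0.5, size=(80, 2))
        g = knn_between_batches(make_decomp(X), np.arange(40, 80), np.arange(40), k1=3, k2=3)
        for a_local, nbrs in enumerate(g.neighbors):
            assert all(labels[b] == labels[a_local] for b in nbrs)

    def test_bruteforce_knn_oracle(self, rng):
        X = rng.normal(size=(30, 4))
        lam = np.array([4.0, -2.0, 1.0, 0.5])
        d = make_decomp(X, lam)
        g = knn_between_batches(d, np.arange(15, 30), np.arange(15), k1=5, k2=5)
        Y = scaled_coords(d)
        for a_local in range(15):
            dist = np.linalg.norm(Y[:15] - Y[15 + a_local], axis=1)
            assert set(g.neighbors[a_local]) == set(np.argsort(dist)[:5])

    def test_empty_batch_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            knn_between_batches(make_decomp(rng.normal(size=(5, 2))),
                                np.arange(0), np.arange(5), 2, 2)


class TestFilterNeighbors:
    def build(self, rng):
        # reference cell 0's query neighborhood has mean ~0, sd ~1 per dim
        Xq = rng.normal(size=(20, 2))
        X = np.vstack([np.zeros((2, 2)), Xq])
        d = make_decomp(X)
        return d, np.arange(2, 22), np.arange(2)

    def test_inside_band_retained_outside_removed(self, rng):
        d, q, ref = self.build(rng)
        d.X[2] = [0.0, 0.0]   # query cell inside every band
        d.X[3] = [9.0, 0.0]   # far outside in dim 0 only -> removed (ANY rule)
        g = knn_between_batches(d, q, ref, k1=2, k2=19)
        g = dataclasses.replace(
            g,
            ref_neighbors=[np.arange(4, 22), np.arange(4, 22)],  # stats from other cells
        )
        f = filter_neighbors(g, d)
        assert len(f.neighbors[0]) == len(g.neighbors[0])  # inside: kept
        assert len(f.neighbors[1]) == 0                     # outside one dim: dropped

    def test_zero_sigma_band_degenerates_to_point(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [0.5, 1.0]])
        d = make_decomp(X)
        g = knn_between_batches(d, np.arange(1, 4), np.arange(1), k1=1, k2=3)
        # ref cell 0's query neighbors: cells 1,2 identical, cell 3 differs in dim 0
        g = dataclasses.replace(g, ref_neighbors=[np.array([1, 2])])
        f = filter_neighbors(g, d)
        assert len(f.neighbors[0]) == 1 and len(f.neighbors[1]) == 1  # at u exactly
        assert len(f.neighbors[2]) == 0  # off the degenerate band

    def test_never_grows_neighbor_lists(self, rng):
        X = rng.normal(size=(40, 3))
        d = make_decomp(X)
        g = knn_between_batches(d, np.arange(20, 40), np.arange(20), k1=6, k2=6)
        f = filter_neighbors(g, d)
        assert all(len(fn) <= len(gn) for fn, gn in zip(f.neighbors, g.neighbors))

    def test_small_k2_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        d = make_decomp(X)
        g = knn_between_batches(d, np.arange(5, 10), np.arange(5), k1=2, k2=1)
        with pytest.raises(ValueError, match="k2"):
            filter_neighbors(g, d)


def snn_of(n, weights=None):
    W = np.zeros((n, n)) if weights is None else np.asarray(weights, dtype=float)
    return SNNGraph(weights=sp.csr_matrix(W), k=2)


class TestComputeCorrection:
    def graph(self, q, neighbors):
        import epiconv.integration as mod

        return mod.NeighborGraph(
            query_indices=np.asarray(q),
            ref_indices=np.arange(np.min(q)),
            neighbors=[np.asarray(nb) for nb in neighbors],
            distances=[np.zeros(len(nb)) for nb in neighbors],
            ref_neighbors=[],
            k1=2,
            k2=2,
        )

    def test_anchor_mean_of_displacements(self):
        # anchor at (0,0), retained neighbors at (0,2) and (2,0) -> correction (1,1)
        X = np.array([[0.0, 2.0], [2.0, 0.0], [0.0, 0.0]])
        d = make_decomp(X)
        g = self.graph([2], [[0, 1]])
        a = compute_correction(g, d, snn_of(1), min_anchor_neighbors=2)
        assert np.allclose(a.correction[0], [1.0, 1.0])

    def test_anchor_at_own_coordinates_gets_zero(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        d = make_decomp(X)
        a = compute_correction(self.graph([2], [[0, 1]]), d, snn_of(1), min_anchor_neighbors=2)
        assert np.allclose(a.correction[0], 0.0)

    def test_non_anchor_inherits_single_snn_anchor(self):
        X = np.array([[0.0, 2.0], [2.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        d = make_decomp(X)
        g = self.graph([2, 3], [[0, 1], []])
        snn = snn_of(2, [[0, 1.0], [1.0, 0]])
        a = compute_correction(g, d, snn, min_anchor_neighbors=2)
        assert a.anchor_mask.tolist() == [True, False]
        assert np.allclose(a.correction[1], a.correction[0])

    def test_isolated_non_anchor_falls_back_to_anchor_mean(self):
        X = np.array([[0.0, 2.0], [2.0, 0.0], [0.0, 0.0], [5.0, 5.0], [1.0, 1.0]])
        d = make_decomp(X)
        g = self.graph([2, 3, 4], [[0, 1], [], [0]])
        a = compute_correction(g, d, snn_of(3), min_anchor_neighbors=2)
        mean_vec = a.correction[a.anchor_mask].mean(axis=0)
        assert np.allclose(a.correction[1], mean_vec)

    def test_no_anchors_errors_with_statistics(self):
        X = np.zeros((4, 2))
        d = make_decomp(X)
        g = self.graph([2, 3], [[], []])
        with pytest.raises(ValueError, match="no anchors"):
            compute_correction(g, d, snn_of(2), min_anchor_neighbors=5)


class TestApplyCorrection:
    def test_zero_correction_preserves_reconstruction(self, rng):
        X = rng.normal(size=(8, 3))
        d = make_decomp(X, np.array([3.0, 2.0, 1.0]), R=rng.normal(size=(8, 8)) * 0)
        S_pre = reconstruct(d).values
        g = TestComputeCorrection().graph([6, 7], [[0, 1], [1, 2]])
        a = compute_correction(g, d, snn_of(2), min_anchor_neighbors=1)
        a = dataclasses.replace(a, correction=np.zeros_like(a.correction))
        assert np.allclose(reconstruct(apply_correction(d, a)).values, S_pre)

    def test_double_correction_forbidden(self, rng):
        d = make_decomp(rng.normal(size=(6, 2)))
        g = TestComputeCorrection().graph([4, 5], [[0], [1]])
        a = compute_correction(g, d, snn_of(2), min_anchor_neighbors=1)
        d2 = apply_correction(d, a)
        with pytest.raises(ValueError, match="already corrected"):
            apply_correction(d2, a)

    def test_reference_rows_untouched(self, rng):
        d = make_decomp(rng.normal(size=(6, 2)))
        ref_before = d.X[:4].copy()
        g = TestComputeCorrection().graph([4, 5], [[0], [1]])
        a = compute_correction(g, d, snn_of(2), min_anchor_neighbors=1)
        d2 = apply_correction(d, a)
        assert np.array_equal(d2.X[:4], ref_before)

    def test_constant_shift_batch_fully_corrected(self, rng):
        # query = exact copy of reference displaced by a constant eigen-space
        # vector; every anchor's displacement is exactly -shift, so all query
        # cells land on their reference twins
        n, r = 40, 4
        Xr = rng.normal(size=(n, r)) * 10  # well-separated cells
        shift = np.array([0.5, -0.3, 0.2, 0.1])  # small vs cell spacing
        X = np.vstack([Xr, Xr + shift])
        lam = np.array([5.0, 4.0, 3.0, 2.0])
        d = make_decomp(X, lam)
        q, ref = np.arange(n, 2 * n), np.arange(n)
        g = knn_between_batches(d, q, ref, k1=1, k2=5)
        f = filter_neighbors(g, d)
        snn = snn_from_coords(scaled_coords(d)[q], 5)
        a = compute_correction(f, d, snn, min_anchor_neighbors=1)
        d2 = apply_correction(d, a)
        S = reconstruct(d2).values
        for i in range(n):
            assert np.allclose(S[n + i, :n], S[i, :n], atol=1e-6)


class TestIntegrateDatasets:
    def test_single_batch_rejected(self):
        cfg = SimulationConfig(n_peaks=200, n_markers=20, cells_per_type=10, n_batches=1)
        mats, _ = simulate(cfg)
        with pytest.raises(ValueError, match="nothing to integrate"):
            integrate_datasets(mats)

    def test_identical_batches_mix_perfectly(self):
        # relabeled copy of one batch: post-integration LISI approaches 2
        cfg = SimulationConfig(n_peaks=1500, n_markers=80, cells_per_type=60, n_batches=1, seed=3)
        mats, _ = simulate(cfg)
        m2 = dataclasses.replace(
            mats[0],
            cell_barcodes=np.array([f"dup_{b}" for b in mats[0].cell_barcodes], dtype=object),
        )
        dec, log = integrate_datasets([mats[0], m2], IntegrationConfig(seed=1))
        from epiconv.graph_cluster import build_snn, snn_to_distance, umap_graph

        emb, _ = umap_graph(snn_to_distance(build_snn(reconstruct(dec))), seed=1)
        li = lisi(emb, dec.batch_labels, perplexity=15)
        assert li.mean() > 1.8
        assert log[0]["n_anchors"] > 0

    def test_reference_eigenvectors_unchanged_and_provenance(self):
        cfg = SimulationConfig(n_peaks=1000, n_markers=60, cells_per_type=40, seed=2)
        mats, _ = simulate(cfg)
        dec, log = integrate_datasets(mats, IntegrationConfig(seed=1))
        assert dec.corrected
        assert len(log) == 1 and log[0]["n_query"] == mats[1].n_cells
        assert dec.n_cells == mats[0].n_cells + mats[1].n_cells

    def test_peak_space_mismatch_rejected(self):
        cfg = SimulationConfig(n_peaks=300, n_markers=30, cells_per_type=10, seed=2)
        mats, _ = simulate(cfg)
        bad = dataclasses.replace(
            mats[1], peak_ids=np.array([f"x{i}" for i in range(300)], dtype=object)
        )
        with pytest.raises(ValueError, match="peak id mismatch"):
            integrate_datasets([mats[0], bad])
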