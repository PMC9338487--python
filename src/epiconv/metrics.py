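"""Batch-mixing and clustering-accuracy metrics: LISI, ARI, over-fit counts.

LISI (local inverse Simpson's index) measures the effective number of
batches in each cell's neighborhood: Gaussian-kernel neighbor weights are
calibrated to a target perplexity by bisection on the bandwidth, batch
probabilities are the weighted neighbor batch frequencies, and
LISI = 1 / sum_b p_b^2.  A value of 1 means the neighborhood is pure
(one batch); B means perfectly even mixing of B batches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .graph_cluster import cluster_graph

logger = logging.getLogger(__name__)

__all__ = [
    "MixingReport",
    "lisi",
    "adjusted_rand_index",
    "count_overfit",
    "best_resolution_ari",
]


@dataclass
class MixingReport:
    """Summary of batch mixing and clustering agreement."""

    lisi_values: np.ndarray
    perplexity: float
    space: str  # "embedding" or "distance"
    ari: float | None = None
    n_overfit: int | None = None
    overfit_fraction: float | None = None
    lisi_threshold: float = 1.1


def _calibrated_weights(d: np.ndarray, perplexity: float,
                        tol: float = 1e-5, max_iter: int = 50) -> np.ndarray:
    """Gaussian weights exp(-beta*d) with entropy calibrated to perplexity."""
    target = np.log(perplexity)
    beta = 1.0
    lo, hi = -np.inf, np.inf
    for _ in range(max_iter):
        w = np.exp(-beta * d)
        sw = w.sum()
        if sw == 0:
            h = 0.0
        else:
            p = w / sw
            nz = p > 0
            h = -np.sum(p[nz] * np.log(p[nz]))
        diff = h - target
        if abs(diff) < tol:
            break
        if diff > 0:  # entropy too high -> sharpen
            lo = beta
            beta = beta * 2 if np.isinf(hi) else (beta + hi) / 2
        else:
            hi = beta
            beta = beta / 2 if np.isinf(lo) else (beta + lo) / 2
    w = np.exp(-beta * d)
    sw = w.sum()
    if sw == 0:  # all weight collapsed; fall back to nearest neighbor
        w = np.zeros_like(d)
        w[np.argmin(d)] = 1.0
        return w
    return w / sw


def lisi(
    data: np.ndarray,
    batch_labels,
    perplexity: float = 30.0,
    precomputed: bool = False,
) -> np.ndarray:
    """Per-cell local inverse Simpson's index over batch labels.

    ``data`` is either an n x d embedding (Euclidean neighbors) or, with
    ``precomputed=True``, an n x n distance matrix.  Neighborhood size is
    3 * perplexity nearest neighbors (self excluded), the standard choice
    for perplexity-calibrated kernels.
    """
    batch_labels = np.asarray(batch_labels)
    n = len(batch_labels)
    codes, _ = _codes(batch_labels)
    B = codes.max() + 1
    if B < 2:
        warnings.warn("single batch: LISI is identically 1", stacklevel=2)
        return np.ones(n)

    k = min(n - 1, max(2, int(round(3 * perplexity))))
    if precomputed:
        D = np.asarray(data, dtype=np.float64)
        if D.shape != (n, n):
            raise ValueError("precomputed distance matrix must be n x n")
        idx = np.argsort(D + np.diag(np.full(n, np.inf)), axis=1, kind="stable")[:, :k]
        dist = np.take_along_axis(D, idx, axis=1)
    else:
        X = np.asarray(data, dtype=np.float64)
        if X.shape[0] != n:
            raise ValueError("embedding rows must match batch labels")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        dist, idx = nn.kneighbors(X)
        dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    out = np.empty(n)
    for i in range(n):
        w = _calibrated_weights(dist[i], perplexity)
        p = np.bincount(codes[idx[i]], weights=w, minlength=B)
        out[i] = 1.0 / np.sum(p**2)
    return out


def _codes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, codes = np.unique(labels, return_inverse=True)
    return codes, uniq


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError(
            f"label vectors differ in length: {labels_a.shape} vs {labels_b.shape}"
        )
    if len(labels_a) < 2:
        raise ValueError("need at least 2 cells")
    return float(adjusted_rand_score(labels_a, labels_b))


def count_overfit(
    lisi_values: np.ndarray,
    eval_mask: np.ndarray | None = None,
    threshold: float = 1.1,
) -> tuple[int, float]:
    """Count evaluated cells whose LISI strictly exceeds the threshold.

    Used with a binary relabeling (type of interest vs rest) as the "batch"
    variable: a cell of a query-unique type whose neighborhood mixes in
    other identities has LISI > 1.1 and counts as over-fitted.
    """
    lisi_values = np.asarray(lisi_values, dtype=np.float64)
    if eval_mask is None:
        eval_mask = np.ones(len(lisi_values), dtype=bool)
    eval_mask = np.asarray(eval_mask, dtype=bool)
    if eval_mask.sum() == 0:
        raise ValueError("empty evaluation mask")
    vals = lisi_values[eval_mask]
    count = int((vals > threshold).sum())
    return count, count / len(vals)


def best_resolution_ari(
    G,
    truth_labels,
    resolutions=None,
    seed: int = 1,
    method: str = "louvain",
) -> tuple[float, float]:
    """Max ARI against truth over a Louvain resolution sweep on a fixed graph.

    ``G`` is the (UMAP fuzzy or SNN) graph the clustering runs on; the
    default sweep is 0.2 to 2.0 in steps of 0.2.
    """
    if resolutions is None:
        resolutions = np.round(np.arange(0.2, 2.01, 0.2), 2)
    resolutions = list(resolutions)
    if not resolutions:
        raise ValueError("resolutions list is empty")
    truth_labels = np.asarray(truth_labels)
    best = (-np.inf, resolutions[0])
    for res in resolutions:
        labels = cluster_graph(G, resolution=float(res), seed=seed, method=method)
        ari = adjusted_rand_index(truth_labels, labels.labels)
        if ari > best[0]:
            best = (ari, float(res))
    return best
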