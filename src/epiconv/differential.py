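"""Hypergeometric differential accessibility, signatures, and peak linking.

For each peak and cluster, accessibility enrichment is a one-tailed
hypergeometric test:

* population size N = total number of cells;
* sample size n = the cluster's total library size divided by the mean
  library size over all cells (rounded half-up, clamped to [1, N]) — a
  sequencing-depth-adjusted effective cluster size;
* successes in the population K = cells with the peak accessible;
* successes in the sample k = cells of the cluster with the peak accessible;
* p = P(X >= k), inclusive upper tail.

Only peaks accessible in at least ``min_frac`` of cells (1% by default) are
tested; peaks significant in several clusters are assigned to the cluster
with the highest normalized count k / n.  No multiple-testing correction is
applied by default (raw p < 0.01 is the calling rule); BH-FDR is available
behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .graph_cluster import ClusterLabels
from .matrix_io import BinaryMatrix, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "DAResult",
    "SignatureVector",
    "da_peaks",
    "signature_scores",
    "normalize_signature",
    "enrichment_fold_change",
    "link_peaks_to_promoters",
    "annotate_cells",
]


@dataclass
class DAResult:
    """Per (peak, cluster) hypergeometric results and marker assignment."""

    table: pd.DataFrame  # peak_id, cluster, K, k, n, p, significant
    assigned: pd.Series  # peak_id -> cluster (only multi/uni-significant peaks)
    tested: np.ndarray  # per-peak bool
    p_cut: float
    min_frac: float

    def markers(self, cluster: int) -> np.ndarray:
        """Peak ids assigned to the given cluster."""
        return self.assigned.index[self.assigned == cluster].to_numpy()


@dataclass
class SignatureVector:
    """Per-cell marker-signature values, raw and percentile-normalized."""

    raw: np.ndarray  # in [0, 1]
    normalized: np.ndarray | None
    cluster: int | None
    x_low: float | None = None
    x_high: float | None = None


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Inclusive upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    The scalar form of the p-value used by :func:`da_peaks` (which applies
    the same survival function vectorized over peaks).
    """
    return float(hypergeom.sf(k - 1, N, K, n))


def da_peaks(
    M: BinaryMatrix,
    labels: ClusterLabels | np.ndarray,
    p_cut: float = 0.01,
    min_frac: float = 0.01,
) -> DAResult:
    """Cluster-specific accessible peaks by the hypergeometric test."""
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    if len(lab) != M.n_cells:
        raise ValueError("labels must cover every cell")
    N = M.n_cells
    lib = M.library_sizes.astype(np.float64)
    mean_lib = lib.mean()
    K = np.asarray(M.matrix.sum(axis=1)).ravel().astype(np.int64)
    tested = K >= min_frac * N

    Mcsr = M.matrix.tocsr()
    rows = []
    for cl in np.unique(lab):
        members = np.flatnonzero(lab == cl)
        if len(members) == 0:
            logger.warning("cluster %s is empty; skipped", cl)
            continue
        n_eff = _round_half_up(lib[members].sum() / mean_lib)
        n_eff = min(max(n_eff, 1), N)
        k = np.asarray(Mcsr[:, members].sum(axis=1)).ravel().astype(np.int64)
        p = hypergeom.sf(k[tested] - 1, N, K[tested], n_eff)
        df = pd.DataFrame(
            {
                "peak_id": M.peak_ids[tested],
                "cluster": cl,
                "K": K[tested],
                "k": k[tested],
                "n": n_eff,
                "p": p,
            }
        )
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    table["significant"] = table["p"] < p_cut
    table["normalized_count"] = table["k"] / table["n"]

    sig = table[table["significant"]]
    assigned = (
        sig.sort_values(
            ["peak_id", "normalized_count", "cluster"],
            ascending=[True, False, True],
        )
        .groupby("peak_id", sort=True)
        .first()["cluster"]
    )
    return DAResult(table=table, assigned=assigned, tested=tested,
                    p_cut=p_cut, min_frac=min_frac)


def signature_scores(M: BinaryMatrix, marker_peaks, cluster: int | None = None) -> SignatureVector:
    """Per cell: accessible markers / accessible peaks."""
    marker_peaks = np.asarray(list(marker_peaks), dtype=object)
    if len(marker_peaks) == 0:
        raise ValueError("empty marker set")
    mask = np.isin(M.peak_ids, marker_peaks)
    if mask.sum() != len(np.unique(marker_peaks)):
        raise ValueError("marker set contains peaks absent from the matrix")
    lib = M.library_sizes.astype(np.float64)
    if (lib == 0).any():
        raise ValueError("cells with zero accessible peaks; run filter_cells first")
    hits = np.asarray(M.matrix[mask].sum(axis=0)).ravel()
    return SignatureVector(raw=hits / lib, normalized=None, cluster=cluster)


def normalize_signature(sig: SignatureVector, clip: bool = False) -> SignatureVector:
    """Percentile normalization (x - x_0.01) / (x_0.99 - x_0.01).

    Percentiles use linear interpolation between order statistics (the
    type-7 convention, numpy's default).  Values outside [0, 1] are kept
    unless ``clip`` is set.
    """
    x = np.asarray(sig.raw, dtype=np.float64)
    if len(np.unique(x)) < 2:
        raise ValueError("signature has < 2 distinct values; nothing to normalize")
    lo, hi = np.percentile(x, [1, 99])
    if hi == lo:
        raise ValueError("degenerate signature spread: 1% and 99% percentiles equal")
    norm = (x - lo) / (hi - lo)
    if clip:
        norm = np.clip(norm, 0.0, 1.0)
    return SignatureVector(raw=sig.raw, normalized=norm, cluster=sig.cluster,
                           x_low=float(lo), x_high=float(hi))


def enrichment_fold_change(N_common: int, N_ATAC: int, N_RNA: int, N_total: int) -> float:
    """Overlap enrichment N_common / (N_ATAC * N_RNA) * N_total.

    Equals 1 when the overlap matches the independence expectation
    N_ATAC * N_RNA / N_total.
    """
    if min(N_ATAC, N_RNA, N_total) <= 0:
        raise ValueError("N_ATAC, N_RNA and N_total must be positive")
    if N_common < 0 or N_common > min(N_ATAC, N_RNA):
        raise ValueError("N_common must lie in [0, min(N_ATAC, N_RNA)]")
    return N_common / (N_ATAC * N_RNA) * N_total


def link_peaks_to_promoters(
    peaks: PeakSet, promoters: PeakSet, midpoint: bool = False
) -> pd.DataFrame:
    """Link each peak to its closest promoter on the same chromosome.

    Distance is measured between closest interval edges (0 when
    overlapping), or between interval midpoints with ``midpoint=True``.
    Ties go to the promoter with the lower start coordinate.  Peaks on
    chromosomes without promoters are returned unlinked (promoter NA).
    """
    if len(promoters) == 0:
        raise ValueError("empty promoter set")
    out = []
    prom_by_chrom: dict[str, np.ndarray] = {}
    pc = promoters.chroms.astype(str)
    for c in np.unique(pc):
        idx = np.flatnonzero(pc == c)
        prom_by_chrom[c] = idx[np.argsort(promoters.starts[idx], kind="stable")]
    for i in range(len(peaks)):
        c = str(peaks.chroms[i])
        if c not in prom_by_chrom:
            out.append((peaks.ids[i], None, np.nan))
            continue
        idx = prom_by_chrom[c]
        ps, pe = promoters.starts[idx], promoters.ends[idx]
        s, e = peaks.starts[i], peaks.ends[i]
        if midpoint:
            d = np.abs((ps + pe) / 2.0 - (s + e) / 2.0)
        else:
            # gap between half-open intervals; 0 if overlapping
            d = np.maximum(0, np.maximum(ps - e + 1, s - pe + 1)).astype(np.float64)
            d[(ps < e) & (s < pe)] = 0.0
        best = np.flatnonzero(d == d.min())
        j = best[np.argmin(ps[best])]  # lower-coordinate tie-break
        out.append((peaks.ids[i], promoters.ids[idx[j]], float(d[j])))
    return pd.DataFrame(out, columns=["peak_id", "promoter_id", "distance"])


def annotate_cells(
    M: BinaryMatrix,
    labels: ClusterLabels | np.ndarray,
    p_cut: float = 0.01,
    min_frac: float = 0.01,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Supervised annotation: markers -> signatures -> argmax label.

    Runs the DA test per cluster, scores every cell on each cluster's
    marker set, percentile-normalizes each signature, and assigns each
    cell the cluster with the highest normalized signature.  Returns the
    per-cell labels and the normalized signature table (cells x clusters).
    """
    da = da_peaks(M, labels, p_cut=p_cut, min_frac=min_frac)
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    cols = {}
    for cl in np.unique(lab):
        markers = da.markers(cl)
        if len(markers) == 0:
            logger.warning("cluster %s has no markers; excluded from annotation", cl)
            continue
        sig = normalize_signature(signature_scores(M, markers, cluster=cl))
        cols[cl] = sig.normalized
    if not cols:
        raise ValueError("no cluster produced any marker; cannot annotate")
    table = pd.DataFrame(cols)
    best = table.to_numpy().argmax(axis=1)
    assigned = np.array(table.columns)[best]
    return assigned, table
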