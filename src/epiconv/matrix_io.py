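"""Fragment counting, binarization, cell filtering and matrix round-trips.

Coordinate convention
---------------------
All intervals are BED: half-open, 0-based ``[start, end)``.  A sequenced
fragment contributes two Tn5 cut sites: its ``start`` coordinate and
``end - 1`` (the last covered base).  Each cut site is tested independently
for peak membership, so a fragment spanning two peaks marks both of them
accessible for that cell.  This mirrors the usual cut-site-centric treatment
of ATAC fragments (peak callers are run on shifted/extended fragment ends,
not on whole fragments).
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "PeakSet",
    "BinaryMatrix",
    "count_fragments_to_matrix",
    "filter_cells",
    "read_matrix",
    "write_matrix",
    "stack_cells",
]


@dataclass(frozen=True)
class FragmentSet:
    """Raw ATAC fragments: (chrom, start, end, barcode) records."""

    records: pd.DataFrame  # columns: chrom, start, end, barcode

    def __post_init__(self) -> None:
        df = self.records
        required = ["chrom", "start", "end", "barcode"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("fragments must satisfy start < end")
        if len(df) and (df["start"] < 0).any():
            raise ValueError("fragment start coordinates must be >= 0")
        if len(df) and (df["barcode"].astype(str).str.len() == 0).any():
            raise ValueError("fragment barcodes must be non-empty")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "FragmentSet":
        """Read a 4+ column BED-like TSV, optionally gzip-compressed.

        Any tabix index is ignored; the file is streamed as plain text.
        """
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "barcode"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "barcode": str},
        )
        return cls(df)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PeakSet:
    """Ordered genomic intervals with unique string identifiers."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.chroms)
        if not (len(self.starts) == len(self.ends) == len(self.ids) == n):
            raise ValueError("peak field lengths disagree")
        if n and not (np.asarray(self.starts) < np.asarray(self.ends)).all():
            raise ValueError("peaks must satisfy start < end")
        if len(set(map(str, self.ids))) != n:
            raise ValueError("peak identifiers must be unique")

    @classmethod
    def from_arrays(cls, chroms, starts, ends, ids=None) -> "PeakSet":
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if ids is None:
            ids = np.array(
                [f"{c}:{s}-{e}" for c, s, e in zip(chroms, starts, ends)],
                dtype=object,
            )
        else:
            ids = np.asarray(ids, dtype=object)
        return cls(chroms, starts, ends, ids)

    @classmethod
    def from_bed(cls, path: str | os.PathLike) -> "PeakSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        ids = df[3].astype(str).to_numpy() if df.shape[1] > 3 else None
        return cls.from_arrays(df[0].astype(str), df[1], df[2], ids)

    def to_bed(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends, "id": self.ids}
        ).to_csv(path, sep="\t", header=False, index=False)

    def merged(self) -> "PeakSet":
        """Union-merge overlapping or duplicate intervals per chromosome.

        Merged peaks get coordinate-derived identifiers.  Overlap is judged on
        the half-open convention: [0,10) and [10,20) do not overlap.
        """
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        out_c, out_s, out_e = [], [], []
        for i in order:
            c, s, e = self.chroms[i], self.starts[i], self.ends[i]
            if out_c and out_c[-1] == c and s < out_e[-1]:
                out_e[-1] = max(out_e[-1], e)
            else:
                out_c.append(c)
                out_s.append(s)
                out_e.append(e)
        if len(out_c) < len(self):
            logger.warning(
                "merged %d overlapping peaks into %d disjoint intervals",
                len(self), len(out_c),
            )
        return PeakSet.from_arrays(out_c, out_s, out_e)

    def __len__(self) -> int:
        return len(self.chroms)


@dataclass
class BinaryMatrix:
    """Sparse binarized peak x cell accessibility matrix with metadata."""

    matrix: sp.csc_matrix  # peaks x cells, entries in {0, 1}
    peak_ids: np.ndarray
    cell_barcodes: np.ndarray
    batch_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = sp.csc_matrix(self.matrix)
        self.peak_ids = np.asarray(self.peak_ids, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if self.matrix.shape != (len(self.peak_ids), len(self.cell_barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.peak_ids)} peaks / {len(self.cell_barcodes)} cells"
            )
        if self.matrix.nnz and not np.isin(self.matrix.data, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1; binarize first")
        if self.batch_labels is not None:
            self.batch_labels = np.asarray(self.batch_labels, dtype=object)
            if len(self.batch_labels) != self.n_cells:
                raise ValueError("batch_labels length must equal cell count")
            key = pd.DataFrame(
                {"b": self.batch_labels, "c": self.cell_barcodes}
            )
            if key.duplicated().any():
                raise ValueError("duplicate barcodes within a batch")
        else:
            if pd.Index(self.cell_barcodes).duplicated().any():
                raise ValueError("duplicate cell barcodes")

    @property
    def n_peaks(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-cell number of accessible peaks (column sums)."""
        return np.asarray(self.matrix.sum(axis=0)).ravel().astype(np.int64)


def count_fragments_to_matrix(fragments: FragmentSet, peaks: PeakSet) -> BinaryMatrix:
    """Count fragment ends against peaks and binarize.

    Entry (p, c) is 1 iff at least one cut site (fragment start, or end - 1)
    of a fragment carrying barcode c lies inside peak p.  Overlapping input
    peaks are union-merged first (a dot-product similarity would otherwise
    double-count shared bases).  Barcodes whose fragments hit no peak at all
    are dropped; fragments on chromosomes absent from the peak set are
    ignored (count logged).
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    peaks = peaks.merged()

    frag = fragments.records
    barcodes = np.unique(frag["barcode"].to_numpy())
    bc_index = {b: i for i, b in enumerate(barcodes)}

    # per-chromosome sorted interval arrays for binary search
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    chrom_arr = peaks.chroms.astype(str)
    for c in np.unique(chrom_arr):
        m = chrom_arr == c
        idx = np.flatnonzero(m)
        order = np.argsort(peaks.starts[idx])
        idx = idx[order]
        by_chrom[c] = (peaks.starts[idx], peaks.ends[idx], idx)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    n_ignored = 0
    for c, grp in frag.groupby("chrom", sort=False):
        if c not in by_chrom:
            n_ignored += len(grp)
            continue
        starts, ends, global_idx = by_chrom[c]
        cell = grp["barcode"].map(bc_index).to_numpy()
        # two cut sites per fragment, tested independently
        sites = np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy() - 1])
        cells2 = np.concatenate([cell, cell])
        pos = np.searchsorted(starts, sites, side="right") - 1
        valid = pos >= 0
        hit = np.zeros(len(sites), dtype=bool)
        hit[valid] = sites[valid] < ends[pos[valid]]
        rows.append(global_idx[pos[hit]])
        cols.append(cells2[hit])
    if n_ignored:
        logger.info("ignored %d fragments on chromosomes absent from peaks", n_ignored)

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = np.empty(0, dtype=np.int64)
        c = np.empty(0, dtype=np.int64)
    mat = sp.coo_matrix(
        (np.ones(len(r), dtype=np.int8), (r, c)),
        shape=(len(peaks), len(barcodes)),
    ).tocsc()
    mat.data[:] = 1  # binarize: duplicate hits collapse
    mat.sum_duplicates()
    mat.data[:] = 1

    keep = np.flatnonzero(np.asarray(mat.sum(axis=0)).ravel() > 0)
    if len(keep) < len(barcodes):
        logger.info("dropped %d barcodes with no peak hits", len(barcodes) - len(keep))
    return BinaryMatrix(mat[:, keep], peaks.ids, barcodes[keep])


def filter_cells(M: BinaryMatrix, min_peaks: int = 1000) -> BinaryMatrix:
    """Drop cells with fewer than ``min_peaks`` accessible peaks (strict).

    A cell with exactly ``min_peaks`` accessible peaks is retained; column
    order of survivors is preserved.
    """
    if min_peaks < 0:
        raise ValueError("min_peaks must be >= 0")
    keep = np.flatnonzero(M.library_sizes >= min_peaks)
    if len(keep) == 0:
        raise ValueError(
            f"all {M.n_cells} cells removed at min_peaks={min_peaks}; "
            "lower the threshold"
        )
    return BinaryMatrix(
        M.matrix[:, keep],
        M.peak_ids,
        M.cell_barcodes[keep],
        None if M.batch_labels is None else M.batch_labels[keep],
    )


def write_matrix(M: BinaryMatrix, out_dir: str | os.PathLike) -> None:
    """Write MTX + sidecar peak BED + barcode list (+ batches if present)."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"), M.matrix.astype(np.int64)
    )
    with open(os.path.join(out_dir, "peaks.bed"), "w") as fh:
        for pid in M.peak_ids:
            pid = str(pid)
            chrom, s, e = pid, "0", "1"  # placeholder for non-coordinate ids
            if ":" in pid and "-" in pid.rsplit(":", 1)[1]:
                c, rest = pid.rsplit(":", 1)
                a, b = rest.split("-", 1)
                if a.isdigit() and b.isdigit():
                    chrom, s, e = c, a, b
            fh.write(f"{chrom}\t{s}\t{e}\t{pid}\n")
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, M.cell_barcodes)) + "\n")
    if M.batch_labels is not None:
        with open(os.path.join(out_dir, "batches.tsv"), "w") as fh:
            fh.write("\n".join(map(str, M.batch_labels)) + "\n")


def read_matrix(
    mtx_path: str | os.PathLike,
    peaks_bed_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    batches_path: str | os.PathLike | None = None,
) -> BinaryMatrix:
    """Read an MTX + peak BED + barcode triple; nonzero entries become 1."""
    mat = sp.csc_matrix(scipy.io.mmread(mtx_path))
    mat.data[:] = 1
    mat = mat.astype(np.int8)

    bed = pd.read_csv(peaks_bed_path, sep="\t", header=None, comment="#")
    peak_ids = (
        bed[3].astype(str).to_numpy()
        if bed.shape[1] > 3
        else np.array([f"{c}:{s}-{e}" for c, s, e in zip(bed[0], bed[1], bed[2])])
    )
    opener = gzip.open if str(barcodes_path).endswith(".gz") else open
    with opener(barcodes_path, "rt") as fh:
        barcodes = np.array([ln.strip() for ln in fh if ln.strip()], dtype=object)

    if len(peak_ids) != mat.shape[0]:
        raise ValueError(
            f"peak BED has {len(peak_ids)} rows but MTX declares {mat.shape[0]}"
        )
    if len(barcodes) != mat.shape[1]:
        raise ValueError(
            f"barcode file has {len(barcodes)} lines but MTX declares {mat.shape[1]}"
        )
    batches = None
    if batches_path is not None:
        with open(batches_path) as fh:
            batches = np.array([ln.strip() for ln in fh if ln.strip()], dtype=object)
    return BinaryMatrix(mat, peak_ids, barcodes, batches)


def stack_cells(matrices: list[BinaryMatrix], batch_names: list[str]) -> BinaryMatrix:
    """Column-stack per-batch matrices over a shared peak space.

    Barcodes are namespaced as ``batch:barcode`` to guarantee uniqueness
    across batches.  Peak id lists must match exactly (harmonize upstream).
    """
    if len(matrices) != len(batch_names):
        raise ValueError("one batch name per matrix required")
    ref_ids = matrices[0].peak_ids
    for m in matrices[1:]:
        if len(m.peak_ids) != len(ref_ids) or not (m.peak_ids == ref_ids).all():
            raise ValueError("peak id mismatch between batches; harmonize peaks first")
    mat = sp.hstack([m.matrix for m in matrices], format="csc")
    barcodes = np.concatenate(
        [
            np.array([f"{b}:{bc}" for bc in m.cell_barcodes], dtype=object)
            for m, b in zip(matrices, batch_names)
        ]
    )
    batches = np.concatenate(
        [np.repeat(np.array([b], dtype=object), m.n_cells) for m, b in zip(matrices, batch_names)]
    )
    return BinaryMatrix(mat, ref_ids, barcodes, batches)
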