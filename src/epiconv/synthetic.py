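"""Synthetic binary scATAC-like data with planted structure.

The generator emulates the statistical skeleton of a multi-batch scATAC
experiment: a handful of cell types, each with a disjoint block of marker
peaks that are far more accessible in that type (probability ``q_in``)
than elsewhere (background ``q_out``); per-cell library-size variation via
a lognormal accessibility scale; and a batch effect that multiplies the
accessibility of a fixed random subset of peaks in affected batches.
Optionally one extra cell type is planted in a single batch only, the
setup used to probe over-fitting of integration methods.

Peaks are sampled independently per cell (Bernoulli), so the data carry no
co-accessibility correlation beyond cell type — which is exactly what the
similarity model assumes, and what makes downstream properties provable.
All randomness flows from a single seed through numpy's SeedSequence
spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix_io import BinaryMatrix

__all__ = [
    "BatchEffect",
    "SimulationConfig",
    "simulate",
    "constant_shift_batch",
]


@dataclass(frozen=True)
class BatchEffect:
    """Multiply accessibility of a random peak fraction in one batch."""

    fraction: float  # fraction of peaks affected, in [0, 1]
    multiplier: float  # accessibility multiplier, >= 0 (1 = no effect)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("batch-effect fraction must be in [0, 1]")
        if self.multiplier < 0:
            raise ValueError("batch-effect multiplier must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator."""

    n_peaks: int = 3000
    n_types: int = 3
    cells_per_type: int = 200
    n_batches: int = 2
    n_markers: int = 150  # marker peaks per type, disjoint blocks
    q_in: float = 0.5  # marker accessibility within the owning type
    q_out: float = 0.1  # background accessibility
    library_sigma: float = 0.35  # lognormal sigma of the per-cell scale
    batch_effects: dict[int, BatchEffect] = field(default_factory=dict)
    unique_type_batch: int | None = None  # batch carrying one extra, private type
    unique_type_cells: int = 0
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_in <= 1.0 and 0.0 <= self.q_out <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_peaks, self.n_types, self.cells_per_type, self.n_batches) <= 0:
            raise ValueError("counts must be positive")
        n_total_types = self.n_types + (1 if self.unique_type_batch is not None else 0)
        if n_total_types * self.n_markers > self.n_peaks:
            raise ValueError("marker blocks exceed the peak space")
        if self.unique_type_batch is not None:
            if not 0 <= self.unique_type_batch < self.n_batches:
                raise ValueError("unique_type_batch out of range")
            if self.unique_type_cells <= 0:
                raise ValueError("unique_type_cells must be positive when planted")
        if self.library_sigma < 0:
            raise ValueError("library_sigma must be >= 0")
        for b, eff in self.batch_effects.items():
            if not 0 <= b < self.n_batches:
                raise ValueError(f"batch effect refers to unknown batch {b}")
            if not isinstance(eff, BatchEffect):
                raise TypeError("batch_effects values must be BatchEffect")


def _type_probs(config: SimulationConfig) -> np.ndarray:
    """(n_total_types, n_peaks) accessibility probabilities before scaling."""
    n_types = config.n_types + (1 if config.unique_type_batch is not None else 0)
    q = np.full((n_types, config.n_peaks), config.q_out)
    for t in range(n_types):
        lo = t * config.n_markers
        q[t, lo: lo + config.n_markers] = config.q_in
    return q


def simulate(config: SimulationConfig) -> tuple[list[BinaryMatrix], pd.DataFrame]:
    """Draw per-batch binary matrices and the ground-truth cell table.

    Each cell's peak p is accessible with probability
    ``clip(s_c * q(type, p) * b(batch, p), 0, 1)`` where s_c is the cell's
    lognormal library scale and b the batch multiplier.  Returns one
    BinaryMatrix per batch plus a truth DataFrame (barcode, batch, type).
    """
    root = np.random.SeedSequence(config.seed)
    ss_effects, ss_cells = root.spawn(2)
    eff_rng = np.random.default_rng(ss_effects)

    # per-batch multiplier vectors over peaks
    batch_mult = {}
    for b in range(config.n_batches):
        mult = np.ones(config.n_peaks)
        eff = config.batch_effects.get(b)
        if eff is not None and eff.fraction > 0:
            n_aff = int(round(eff.fraction * config.n_peaks))
            affected = eff_rng.choice(config.n_peaks, size=n_aff, replace=False)
            mult[affected] = eff.multiplier
        batch_mult[b] = mult

    q_types = _type_probs(config)
    unique_type = config.n_types if config.unique_type_batch is not None else None

    matrices: list[BinaryMatrix] = []
    truth_rows = []
    batch_seeds = ss_cells.spawn(config.n_batches)
    for b in range(config.n_batches):
        rng = np.random.default_rng(batch_seeds[b])
        types = np.repeat(np.arange(config.n_types), config.cells_per_type)
        if unique_type is not None and b == config.unique_type_batch:
            types = np.concatenate(
                [types, np.full(config.unique_type_cells, unique_type)]
            )
        n_cells = len(types)
        scales = rng.lognormal(mean=0.0, sigma=config.library_sigma, size=n_cells)
        probs = np.clip(
            scales[:, None] * q_types[types] * batch_mult[b][None, :], 0.0, 1.0
        )
        vals = (rng.random(probs.shape) < probs).astype(np.int8)
        barcodes = np.array(
            [f"b{b}_c{i:05d}" for i in range(n_cells)], dtype=object
        )
        matrices.append(
            BinaryMatrix(
                sp.csc_matrix(vals.T),  # peaks x cells
                np.array([f"peak_{p:05d}" for p in range(config.n_peaks)], dtype=object),
                barcodes,
                np.repeat(np.array([f"batch{b}"], dtype=object), n_cells),
            )
        )
        for bc, t in zip(barcodes, types):
            truth_rows.append((bc, f"batch{b}", int(t)))
    truth = pd.DataFrame(truth_rows, columns=["barcode", "batch", "type"])
    return matrices, truth


def constant_shift_batch(
    config: SimulationConfig, fraction: float = 0.3, multiplier: float = 0.2
) -> tuple[list[BinaryMatrix], pd.DataFrame]:
    """Paired batches differing only by a planted technical perturbation.

    Batch 0 is drawn from the base configuration; batch 1 additionally has
    the accessibility of a random ``fraction`` of peaks multiplied by
    ``multiplier`` (values below 1 attenuate, above 1 inflate), emulating
    protocol-driven variation shared by every cell of the batch.
    """
    effect = BatchEffect(fraction=fraction, multiplier=multiplier)  # validates
    cfg = replace(config, n_batches=2, batch_effects={1: effect})
    return simulate(cfg)
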