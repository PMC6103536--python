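"""Synthetic peak-by-cell universes for end-to-end, download-free testing.

The generator emulates the statistical shape of a binarized scATAC-seq
matrix: independent Bernoulli accessibility per (cell, peak) with per-peak
open probabilities, per-peak GC fractions, and synthetic BED coordinates on
one pseudo-chromosome.  Feature blocks may carry injected cell-to-cell
heterogeneity of tunable intensity, emulating a population in which two
halves of the cells use disjoint regulatory elements while keeping every
cell's expected total accessibility constant.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import BinaryAccessibilityMatrix, FeaturePeakSet, PeakTable

__all__ = ["BlockSpec", "FixtureSpec", "generate_null_universe",
           "inject_block_heterogeneity", "generate_universe"]

PEAK_WIDTH = 500
PEAK_SPACING = 1000


@dataclass(frozen=True)
class BlockSpec:
    """A named peak block, optionally with heterogeneity intensity h."""

    name: str
    peak_indices: np.ndarray
    h: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "peak_indices",
                           np.asarray(self.peak_indices, dtype=np.int64))
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("heterogeneity h must lie in [0, 1]")


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic universe."""

    n_cells: int
    n_peaks: int
    accessibility_probs: np.ndarray
    gc: np.ndarray
    blocks: tuple[BlockSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.accessibility_probs, dtype=float)
        g = np.asarray(self.gc, dtype=float)
        object.__setattr__(self, "accessibility_probs", p)
        object.__setattr__(self, "gc", g)
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if p.shape != (self.n_peaks,) or g.shape != (self.n_peaks,):
            raise ValueError("probability and gc vectors must match n_peaks")
        if np.any((p < 0) | (p > 1)) or np.any((g < 0) | (g > 1)):
            raise ValueError("probabilities and gc must lie in [0, 1]")
        for b in self.blocks:
            if b.peak_indices.size and (b.peak_indices.min() < 0
                                        or b.peak_indices.max() >= self.n_peaks):
                raise ValueError(f"block {b.name!r} indexes invalid peaks")

    @classmethod
    def default(cls, n_cells: int = 200, n_peaks: int = 2000, seed: int = 0,
                prob_low: float = 0.05, prob_high: float = 0.5,
                blocks: tuple[BlockSpec, ...] = ()) -> "FixtureSpec":
        """Desk-scale stand-in for a real open-chromatin universe.

        Per-peak open probabilities are uniform on [prob_low, prob_high];
        GC fractions follow a Beta(2, 2) bell rescaled onto [0.2, 0.8], so
        GC matching is exercised nontrivially.
        """
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1D0]))
        probs = rng.uniform(prob_low, prob_high, size=n_peaks)
        gc = 0.2 + 0.6 * rng.beta(2.0, 2.0, size=n_peaks)
        return cls(n_cells, n_peaks, probs, gc, blocks, seed)


def _peak_table(spec: FixtureSpec) -> PeakTable:
    starts = np.arange(spec.n_peaks, dtype=np.int64) * PEAK_SPACING
    ids = np.array([f"peak_{j:06d}" for j in range(spec.n_peaks)], dtype=object)
    return PeakTable(np.full(spec.n_peaks, "chrS", dtype=object), starts,
                     starts + PEAK_WIDTH, ids, gc=spec.gc)


def generate_null_universe(spec: FixtureSpec,
                           ) -> tuple[BinaryAccessibilityMatrix, PeakTable]:
    """Independent Bernoulli draws; no feature-linked structure.

    The returned peak table carries the spec's GC values and the realized
    per-peak mean accessibility.
    """
    master = np.random.SeedSequence(spec.seed)
    mat_ss = master.spawn(1)[0]
    rng = np.random.default_rng(mat_ss)
    values = (rng.random((spec.n_cells, spec.n_peaks))
              < spec.accessibility_probs).astype(np.uint8)
    cells = [f"cell_{i:05d}" for i in range(spec.n_cells)]
    table = _peak_table(spec)
    matrix = BinaryAccessibilityMatrix(values, cells, list(table.peak_id))
    table = table.with_mean_accessibility(values.mean(axis=0))
    return matrix, table


def inject_block_heterogeneity(matrix: BinaryAccessibilityMatrix,
                               block: FeaturePeakSet | BlockSpec,
                               h: float,
                               rng: np.random.Generator,
                               probs: np.ndarray | None = None,
                               ) -> BinaryAccessibilityMatrix:
    """Redraw a peak block with two-subpopulation heterogeneity of intensity h.

    Cells are split into two halves (first half / second half of the cell
    order).  The block's peaks are split into two disjoint sub-blocks; with
    intensity h, each half's accessibility mass is shifted onto its own
    sub-block:

        P(open at peak j | half A) = (1 - h) p_j + h * c * [j in sub-block 1]

    with c = sum(p) / |sub-block| so every cell's expected total
    accessibility within the block is unchanged for all h.  At h = 1 the two
    halves open disjoint peak sets, the strongest heterogeneity the design
    can express; at h = 0 the redraw reproduces the null distribution.

    ``probs`` defaults to the block's observed per-peak mean accessibility.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must lie in [0, 1]")
    idx = np.asarray(block.peak_indices, dtype=np.int64)
    if probs is None:
        probs = matrix.values[:, idx].mean(axis=0)
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (idx.size,):
        raise ValueError("probs must align with the block's peaks")
    m = idx.size
    half_peaks = (m + 1) // 2
    in_sub1 = np.zeros(m, dtype=bool)
    in_sub1[:half_peaks] = True
    total = probs.sum()
    c1 = min(total / max(in_sub1.sum(), 1), 1.0)
    c2 = min(total / max((~in_sub1).sum(), 1), 1.0)
    q_a = (1.0 - h) * probs + h * c1 * in_sub1
    q_b = (1.0 - h) * probs + h * c2 * (~in_sub1)

    n = matrix.n_cells
    half_cells = (n + 1) // 2
    new = matrix.values.copy()
    u = rng.random((n, m))
    new[:half_cells, idx] = (u[:half_cells] < q_a).astype(np.uint8)
    new[half_cells:, idx] = (u[half_cells:] < q_b).astype(np.uint8)
    return BinaryAccessibilityMatrix(new, matrix.cell_ids, matrix.peak_ids)


def generate_universe(spec: FixtureSpec,
                      ) -> tuple[BinaryAccessibilityMatrix, PeakTable,
                                 dict[str, FeaturePeakSet]]:
    """Null universe plus heterogeneity injected per the spec's blocks.

    Returns the matrix, the annotated peak table (mean accessibility
    recomputed after injection), and the blocks as feature sets.
    """
    matrix, table = generate_null_universe(spec)
    master = np.random.SeedSequence(spec.seed)
    block_parent = master.spawn(2)[1]
    features: dict[str, FeaturePeakSet] = {}
    children = block_parent.spawn(max(len(spec.blocks), 1))
    for blk, child in zip(spec.blocks, children):
        if blk.h > 0:
            matrix = inject_block_heterogeneity(
                matrix, blk, blk.h, np.random.default_rng(child),
                probs=spec.accessibility_probs[blk.peak_indices])
        features[blk.name] = FeaturePeakSet(blk.name, blk.peak_indices,
                                            universe_size=spec.n_peaks)
    table = table.with_mean_accessibility(matrix.values.mean(axis=0))
    return matrix, table, features
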