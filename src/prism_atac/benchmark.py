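"""Heterogeneity-titration benchmark.

Synthetic cell-to-cell heterogeneity is created by mixing two peak blocks
— an "original" block drawn at random from the universe and a "matched"
block GC-matched to it peak-for-peak — across cells at varying
proportions.  Mixing peaks rather than cells keeps cell identities (and
confounders such as lysis efficiency) fixed.  Under model 1 the matched
block is drawn from the full remaining pool, so both blocks carry
comparable average accessibility; model 2 draws the matched block from
peaks above a percentile cut in mean accessibility, creating a strong
total-accessibility difference between the two cell groups.  Subtype A
runs the titration on the highest-coverage cells, subtype B on the lowest.

A correct variability estimator traces a concave ("inverse-U") curve over
the mixing proportion, minimal at pure mixtures and maximal near 50-50.
Curve quality is summarized by a concavity score (the Spearman correlation
of successive curve differences with a decreasing integer sequence; 1 for
a perfectly concave curve) and by the mean squared residual around a local
polynomial regression (LOESS) fit, which measures the estimator's noise.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats

from .bias_correction import BackgroundConfig, _GcMatchPool, _annotated_pool
from .exceptions import DegenerateBackgroundError, TooFewPointsError
from .matrix_io import BinaryAccessibilityMatrix, FeaturePeakSet, PeakTable
from .variability import raw_variability

__all__ = [
    "SimulationConfig",
    "TitrationCurve",
    "select_cells",
    "draw_peak_blocks",
    "build_mixture",
    "run_titration",
    "u_statistic",
    "loess_fit",
    "loess_mse",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one titration run."""

    model: Literal[1, 2] = 1
    subtype: Literal["A", "B"] = "A"
    n_peaks: int = 500
    n_cells: int = 100
    n_proportion_steps: int = 50
    accessibility_percentile_cut: float = 75.0
    loess_span: float = 0.75
    variability: Literal["raw", "bias_corrected"] = "bias_corrected"
    n_background_iter: int = 30
    gc_tolerance: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if self.subtype not in ("A", "B"):
            raise ValueError("subtype must be 'A' or 'B'")
        if self.n_peaks < 2:
            raise ValueError("n_peaks must be >= 2")
        if self.n_proportion_steps < 3:
            raise ValueError("n_proportion_steps must be >= 3")
        if self.variability not in ("raw", "bias_corrected"):
            raise ValueError("variability must be 'raw' or 'bias_corrected'")


@dataclass(frozen=True)
class TitrationCurve:
    """Variability as a function of the original-peak mixing proportion."""

    proportions: np.ndarray
    variability: np.ndarray
    u_statistic: float | None
    loess_mse: float
    config: SimulationConfig

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        v = np.asarray(self.variability, dtype=float)
        object.__setattr__(self, "proportions", p)
        object.__setattr__(self, "variability", v)
        if p.shape != v.shape:
            raise ValueError("proportions and variability lengths differ")
        if np.any(np.diff(p) <= 0):
            raise ValueError("proportions must be strictly increasing")

    def argmax_proportion(self) -> float:
        return float(self.proportions[int(np.argmax(self.variability))])

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "wt") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("proportion\tvariability\n")
            for p, v in zip(self.proportions, self.variability):
                fh.write(f"{p:.6g}\t{v:.10g}\n")

    def summary_json(self) -> str:
        u = None if self.u_statistic is None else float(self.u_statistic)
        return json.dumps({
            "u_statistic": u,
            "loess_mse": float(self.loess_mse),
            "argmax_proportion": self.argmax_proportion(),
            "config": asdict(self.config),
        })


def select_cells(matrix: BinaryAccessibilityMatrix, subtype: str,
                 n_cells: int) -> np.ndarray:
    """Indices of the n_cells highest- (A) or lowest- (B) coverage cells.

    Coverage is total accessibility (row sum); ties break toward the
    lexicographically smaller cell id.
    """
    if n_cells > matrix.n_cells:
        raise ValueError(f"requested {n_cells} cells of {matrix.n_cells}")
    ids = np.asarray(matrix.cell_ids, dtype=object).astype(str)
    totals = matrix.per_cell_total
    id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
    if subtype == "A":
        order = np.lexsort((id_rank, -totals))
    elif subtype == "B":
        order = np.lexsort((id_rank, totals))
    else:
        raise ValueError("subtype must be 'A' or 'B'")
    return order[:n_cells]


def draw_peak_blocks(matrix: BinaryAccessibilityMatrix, peaks: PeakTable,
                     config: SimulationConfig, rng: np.random.Generator,
                     ) -> tuple[FeaturePeakSet, FeaturePeakSet]:
    """Draw the original block and its GC-matched counterpart.

    The original block is a uniform draw of annotated peaks.  The matched
    block is a peak-for-peak GC-matched draw from the remaining pool —
    restricted, under model 2, to peaks above the configured percentile of
    mean accessibility (percentile computed on the full universe before
    excluding the originals).  The blocks are disjoint.
    """
    annotated = _annotated_pool(peaks, np.array([], dtype=np.int64))
    if annotated.size < 2 * config.n_peaks:
        raise ValueError("universe too small for two disjoint blocks")
    original_idx = rng.choice(annotated, size=config.n_peaks, replace=False)
    original = FeaturePeakSet("original", original_idx, universe_size=len(peaks))

    pool = _annotated_pool(peaks, original_idx)
    if config.model == 2:
        cut = np.nanpercentile(peaks.mean_accessibility,
                               config.accessibility_percentile_cut)
        pool = pool[peaks.mean_accessibility[pool] > cut]
    bg_cfg = BackgroundConfig(n_background_iter=1,
                              gc_tolerance=config.gc_tolerance,
                              accessibility_tolerance=None, seed=0)
    matcher = _GcMatchPool(peaks, original, bg_cfg, pool=pool)
    matched_idx = matcher.draw(rng)
    matched = FeaturePeakSet("matched", matched_idx, universe_size=len(peaks))
    return original, matched


def build_mixture(matrix: BinaryAccessibilityMatrix,
                  original: FeaturePeakSet, matched: FeaturePeakSet,
                  proportion: float) -> BinaryAccessibilityMatrix:
    """Mix the two blocks: a ``proportion`` fraction of cells contribute
    their values at the original peaks, the rest at the matched peaks,
    aligned position-by-position into one cells x n_peaks matrix."""
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if len(original) != len(matched):
        raise ValueError("blocks must have equal cardinality")
    n = matrix.n_cells
    k = int(round(proportion * n))
    values = np.empty((n, len(original)), dtype=np.uint8)
    values[:k] = matrix.values[:k][:, original.peak_indices]
    values[k:] = matrix.values[k:][:, matched.peak_indices]
    peak_ids = [f"mix_{j:05d}" for j in range(len(original))]
    return BinaryAccessibilityMatrix(values, matrix.cell_ids, peak_ids)


def run_titration(matrix: BinaryAccessibilityMatrix, peaks: PeakTable,
                  config: SimulationConfig) -> TitrationCurve:
    """Full titration: one variability value per mixing proportion.

    Proportions are i / n_steps for i = 1..n_steps.  In "bias_corrected"
    mode every point's raw value is divided by the mean raw variability of
    GC-matched background sets (matched to the original block, evaluated
    on the same cells in the untouched universe).  Because the background
    distribution does not depend on the mixing proportion, the
    normalization factor is estimated once per curve and shared across
    steps, rather than re-estimated per point with independent noise.
    """
    master = np.random.SeedSequence(config.seed)
    block_ss, bg_ss = master.spawn(2)
    cells = select_cells(matrix, config.subtype, config.n_cells)
    sub = matrix.restrict_cells(cells)
    original, matched = draw_peak_blocks(sub, peaks, config,
                                         np.random.default_rng(block_ss))
    mean_bg = 1.0
    if config.variability == "bias_corrected":
        pool = _annotated_pool(
            peaks, np.concatenate([original.peak_indices, matched.peak_indices]))
        bg_cfg = BackgroundConfig(n_background_iter=config.n_background_iter,
                                  gc_tolerance=config.gc_tolerance,
                                  accessibility_tolerance=None, seed=0)
        matcher = _GcMatchPool(peaks, original, bg_cfg, pool=pool)
        raws = np.empty(config.n_background_iter)
        for i, child in enumerate(bg_ss.spawn(config.n_background_iter)):
            rng = np.random.default_rng(child)
            bg = FeaturePeakSet(f"bg:{i}", matcher.draw(rng),
                                universe_size=len(peaks))
            raws[i] = raw_variability(sub, bg).value
        mean_bg = float(raws.mean())
        if mean_bg == 0.0:
            raise DegenerateBackgroundError(
                "all background variabilities are zero")

    steps = config.n_proportion_steps
    proportions = np.arange(1, steps + 1) / steps
    values = np.empty(steps)
    mix_peaks = FeaturePeakSet("mixture", np.arange(config.n_peaks),
                               universe_size=config.n_peaks)
    for i, p in enumerate(proportions):
        mix = build_mixture(sub, original, matched, p)
        values[i] = raw_variability(mix, mix_peaks).value / mean_bg
    u = u_statistic(values)
    mse = loess_mse(proportions, values, span=config.loess_span)
    return TitrationCurve(proportions, values, u, mse, config)


def u_statistic(variability) -> float | None:
    """Concavity score of a curve: Spearman correlation of successive
    differences with a decreasing integer sequence.

    For an m-point curve the differences d_i = v_{i+1} - v_i are rank-
    correlated (midranks for ties) with (m-1, m-2, ..., 1); a perfectly
    concave curve scores 1, a convex one -1.  Returns None when all
    differences are tied (e.g. an exactly linear curve).
    """
    v = np.asarray(variability, dtype=float)
    if v.size < 3:
        raise TooFewPointsError("u_statistic needs >= 3 curve points")
    d = np.diff(v)
    # all-tied up to fp round-off (e.g. an exactly linear curve)
    if np.ptp(d) <= 1e-9 * max(np.abs(d).max(), 1e-300):
        return None
    ref = np.arange(d.size, 0, -1)
    return float(stats.spearmanr(d, ref).statistic)


def loess_fit(x, y, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights, evaluated at x.

    For each point, the ``span`` fraction of nearest neighbours is fit by
    weighted least squares of the given degree and the fit is read off at
    that point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    k = int(np.ceil(span * n))
    k = max(min(k, n), degree + 2)
    fitted = np.empty(n)
    for i in range(n):
        dist = np.abs(x - x[i])
        nbr = np.argpartition(dist, k - 1)[:k]
        dmax = dist[nbr].max()
        if dmax > 0:
            w = (1.0 - (dist[nbr] / dmax) ** 3) ** 3
            w = np.clip(w, 0.0, None)
        else:
            w = np.ones(k)
        if w.sum() == 0:
            w = np.ones(k)
        t = x[nbr] - x[i]
        design = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[nbr] * sw, rcond=None)
        fitted[i] = coef[0]
    return fitted


def loess_mse(proportions, variability, span: float = 0.75) -> float:
    """Mean squared residual of the curve around its LOESS fit."""
    x = np.asarray(proportions, dtype=float)
    y = np.asarray(variability, dtype=float)
    if x.size < 5:
        raise TooFewPointsError("loess_mse needs >= 5 curve points")
    fitted = loess_fit(x, y, span=span, degree=2)
    return float(np.mean((y - fitted) ** 2))
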