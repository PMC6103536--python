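"""Two-stage normalization of raw variability.

Stage one cancels technical bias from base composition and coverage: each
raw variability is divided by the mean raw variability of GC-matched
"background" peak sets drawn from the non-feature pool,

    bias_corrected = raw / mean(background raws).

Background sets have the same cardinality as the feature set, are disjoint
from it, and are matched peak-for-peak on GC content; their overall mean
accessibility is additionally constrained to lie within a small tolerance
of the feature set's overall mean accessibility.

Stage two expresses the result in units of background noise: random
non-feature peak sets of equal size ("negative controls") are each
bias-corrected the same way, and

    final = bias_corrected / mean(control bias_corrected values).

A final variation of 1 means the feature is associated with no more
cell-to-cell variation than a random peak set; the controls also yield a
Z-score and an empirical p-value.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateBackgroundError, UnmatchablePeakError
from .matrix_io import BinaryAccessibilityMatrix, FeaturePeakSet, PeakTable
from .variability import raw_variability

__all__ = [
    "BackgroundConfig",
    "VariabilityResult",
    "sample_background_set",
    "bias_corrected_variation",
    "final_variation",
    "empirical_pvalue",
    "write_results_tsv",
]


@dataclass(frozen=True)
class BackgroundConfig:
    """Resampling parameters for the two correction stages.

    gc_tolerance is the half-width of the per-peak GC matching window;
    accessibility_tolerance constrains how far the background set's overall
    mean accessibility may sit from the feature set's (``accessibility_match
    = "per_peak"`` instead constrains every single background peak, and
    ``accessibility_tolerance = None`` disables the constraint).
    """

    n_background_iter: int = 30
    n_negative_control: int = 30
    gc_tolerance: float = 0.02
    accessibility_tolerance: float | None = 0.01
    accessibility_match: Literal["set_mean", "per_peak"] = "set_mean"
    seed: int = 0

    def __post_init__(self):
        if self.n_background_iter < 1 or self.n_negative_control < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.gc_tolerance <= 0:
            raise ValueError("gc_tolerance must be > 0")
        if self.accessibility_tolerance is not None \
                and self.accessibility_tolerance <= 0:
            raise ValueError("accessibility_tolerance must be > 0 or None")
        if self.accessibility_match not in ("set_mean", "per_peak"):
            raise ValueError("accessibility_match must be 'set_mean' or 'per_peak'")


@dataclass(frozen=True)
class VariabilityResult:
    """Raw, bias-corrected, and final variation for one feature set."""

    feature_name: str
    raw: float
    background_mean: float
    bias_corrected: float
    negative_control_mean: float
    final: float
    z_score: float            # NaN when the controls have zero spread
    p_value: float            # empirical upper tail, add-one smoothed
    p_value_normal: float     # normal-theory upper tail from z_score
    background_raws: np.ndarray
    control_bias_corrected: np.ndarray
    n_cells_used: int
    n_cells_dropped_zero: int
    config: BackgroundConfig


def _annotated_pool(peaks: PeakTable, exclude: np.ndarray,
                    require_acc: bool = True) -> np.ndarray:
    """Universe indices usable as background/control candidates."""
    mask = np.ones(len(peaks), dtype=bool)
    mask[exclude] = False
    mask &= ~np.isnan(peaks.gc)
    if require_acc:
        mask &= ~np.isnan(peaks.mean_accessibility)
    return np.flatnonzero(mask)


class _GcMatchPool:
    """Per-peak GC-window candidate lookup over a fixed pool, reusable
    across background iterations for the same feature set."""

    def __init__(self, peaks: PeakTable, feature: FeaturePeakSet,
                 config: BackgroundConfig, pool: np.ndarray | None = None):
        self.peaks = peaks
        self.feature = feature
        self.config = config
        feat_acc = peaks.mean_accessibility[feature.peak_indices]
        self.target_acc = float(np.nanmean(feat_acc))
        if pool is None:
            pool = _annotated_pool(peaks, feature.peak_indices)
        if config.accessibility_tolerance is not None \
                and config.accessibility_match == "per_peak":
            acc = peaks.mean_accessibility[pool]
            pool = pool[np.abs(acc - self.target_acc)
                        <= config.accessibility_tolerance]
        order = np.argsort(peaks.gc[pool], kind="stable")
        self.pool_idx = pool[order]
        self.pool_gc = peaks.gc[self.pool_idx]
        self.pool_acc = peaks.mean_accessibility[self.pool_idx]
        gc_feat = peaks.gc[feature.peak_indices]
        self.lo = np.searchsorted(self.pool_gc, gc_feat - config.gc_tolerance, "left")
        self.hi = np.searchsorted(self.pool_gc, gc_feat + config.gc_tolerance, "right")
        empty = np.flatnonzero(self.hi <= self.lo)
        if empty.size:
            j = int(empty[0])
            pid = peaks.peak_id[feature.peak_indices[j]]
            raise UnmatchablePeakError(
                f"peak {pid!r} (gc={gc_feat[j]:.3f}) has no background "
                f"candidate within +/-{config.gc_tolerance} GC"
                + ("" if config.accessibility_match != "per_peak"
                   else f" and +/-{config.accessibility_tolerance} accessibility"))

    def _assign(self, rng: np.random.Generator) -> np.ndarray:
        """One without-replacement peak-for-peak draw; pool positions per
        feature position, or None if a collision dead-end occurred."""
        n = len(self.feature)
        used = np.zeros(len(self.pool_idx), dtype=bool)
        chosen = np.full(n, -1, dtype=np.int64)
        order = np.argsort(self.hi - self.lo, kind="stable")  # scarcest first
        for j in order:
            window = np.arange(self.lo[j], self.hi[j])
            avail = window[~used[window]]
            if avail.size == 0:
                return None
            pick = int(avail[rng.integers(avail.size)])
            chosen[j] = pick
            used[pick] = True
        return chosen

    def draw(self, rng: np.random.Generator, max_restarts: int = 20) -> np.ndarray:
        chosen = None
        for _ in range(max_restarts):
            chosen = self._assign(rng)
            if chosen is not None:
                break
        if chosen is None:
            raise UnmatchablePeakError(
                f"could not assign {len(self.feature)} distinct GC-matched "
                f"background peaks for feature {self.feature.name!r} "
                f"(pool of {len(self.pool_idx)}); widen gc_tolerance")
        cfg = self.config
        if cfg.accessibility_tolerance is not None \
                and cfg.accessibility_match == "set_mean":
            chosen = self._repair_set_mean(chosen, rng)
        return self.pool_idx[chosen]

    def _repair_set_mean(self, chosen: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
        """Greedy swaps until the set's mean accessibility is within
        tolerance of the feature set's overall mean accessibility."""
        tol = self.config.accessibility_tolerance
        n = chosen.size
        used = np.zeros(len(self.pool_idx), dtype=bool)
        used[chosen] = True
        cur_sum = float(self.pool_acc[chosen].sum())
        for _ in range(5 * n):
            gap = cur_sum / n - self.target_acc
            if abs(gap) <= tol:
                return chosen
            improved = False
            for j in rng.permutation(n):
                window = np.arange(self.lo[j], self.hi[j])
                avail = window[~used[window]]
                if avail.size == 0:
                    continue
                new_means = (cur_sum - self.pool_acc[chosen[j]]
                             + self.pool_acc[avail]) / n
                k = int(np.argmin(np.abs(new_means - self.target_acc)))
                if abs(new_means[k] - self.target_acc) < abs(gap):
                    used[chosen[j]] = False
                    cur_sum += float(self.pool_acc[avail[k]]
                                     - self.pool_acc[chosen[j]])
                    chosen[j] = int(avail[k])
                    used[chosen[j]] = True
                    improved = True
                    break
            if not improved:
                break
        raise UnmatchablePeakError(
            f"cannot bring background mean accessibility within "
            f"+/-{tol} of {self.target_acc:.4f} for feature "
            f"{self.feature.name!r}; widen accessibility_tolerance")


def sample_background_set(peaks: PeakTable, feature: FeaturePeakSet,
                          config: BackgroundConfig,
                          rng: np.random.Generator,
                          pool: np.ndarray | None = None,
                          name: str | None = None) -> FeaturePeakSet:
    """Draw one background peak set matched to ``feature``.

    One background peak per original peak (position-aligned), sampled
    uniformly without replacement among non-feature peaks whose GC lies
    within ``gc_tolerance`` of that original peak's GC, under the configured
    accessibility constraint.  Deterministic given ``rng``'s state.
    """
    matcher = _GcMatchPool(peaks, feature, config, pool=pool)
    idx = matcher.draw(rng)
    return FeaturePeakSet(name or f"background:{feature.name}", idx,
                          universe_size=len(peaks))


def _background_raws(matrix: BinaryAccessibilityMatrix,
                     matcher: _GcMatchPool, peaks: PeakTable,
                     seed_seq: np.random.SeedSequence,
                     n_iter: int) -> np.ndarray:
    raws = np.empty(n_iter)
    for i, child in enumerate(seed_seq.spawn(n_iter)):
        rng = np.random.default_rng(child)
        bg_idx = matcher.draw(rng)
        bg = FeaturePeakSet(f"background:{matcher.feature.name}:{i}", bg_idx,
                            universe_size=len(peaks))
        raws[i] = raw_variability(matrix, bg).value
    return raws


def bias_corrected_variation(matrix: BinaryAccessibilityMatrix,
                             feature: FeaturePeakSet, peaks: PeakTable,
                             config: BackgroundConfig,
                             seed_seq: np.random.SeedSequence | None = None,
                             ) -> tuple[float, np.ndarray]:
    """Raw variability divided by the mean over matched background draws.

    Returns (bias_corrected, background raw values).  The master seed (or
    the supplied SeedSequence) spawns one stream per iteration, so changing
    the iteration count does not shift earlier draws.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    matcher = _GcMatchPool(peaks, feature, config)
    raw = raw_variability(matrix, feature).value
    raws = _background_raws(matrix, matcher, peaks, seed_seq,
                            config.n_background_iter)
    mean_bg = float(raws.mean())
    if mean_bg == 0.0:
        raise DegenerateBackgroundError(
            f"all background variabilities are zero for {feature.name!r}")
    return raw / mean_bg, raws


def empirical_pvalue(observed: float, controls: Sequence[float]) -> float:
    """Add-one-smoothed upper-tail fraction of controls >= observed."""
    controls = np.asarray(controls, dtype=float)
    return float((1 + (controls >= observed).sum()) / (controls.size + 1))


def final_variation(matrix: BinaryAccessibilityMatrix,
                    feature: FeaturePeakSet, peaks: PeakTable,
                    config: BackgroundConfig) -> VariabilityResult:
    """Full two-stage pipeline for one feature set.

    Negative-control sets are uniform draws of non-feature peaks with the
    feature's cardinality; each is bias-corrected with its own GC-matched
    backgrounds before entering the final ratio.  Distinct controls may
    overlap one another but never the feature set.
    """
    master = np.random.SeedSequence(config.seed)
    feat_ss, ctrl_master = master.spawn(2)

    raw_res = raw_variability(matrix, feature)
    matcher = _GcMatchPool(peaks, feature, config)
    bg_raws = _background_raws(matrix, matcher, peaks, feat_ss,
                               config.n_background_iter)
    background_mean = float(bg_raws.mean())
    if background_mean == 0.0:
        raise DegenerateBackgroundError(
            f"all background variabilities are zero for {feature.name!r}")
    bias_corrected = raw_res.value / background_mean

    ctrl_pool = _annotated_pool(peaks, feature.peak_indices)
    if ctrl_pool.size < len(feature):
        raise UnmatchablePeakError(
            f"non-feature pool ({ctrl_pool.size}) smaller than feature "
            f"({len(feature)}); cannot draw negative controls")
    ctrl_bc = np.empty(config.n_negative_control)
    for i, child in enumerate(ctrl_master.spawn(config.n_negative_control)):
        draw_ss, bg_ss = child.spawn(2)
        rng = np.random.default_rng(draw_ss)
        idx = rng.choice(ctrl_pool, size=len(feature), replace=False)
        ctrl = FeaturePeakSet(f"control:{feature.name}:{i}", idx,
                              universe_size=len(peaks))
        ctrl_matcher = _GcMatchPool(peaks, ctrl, config)
        ctrl_raw = raw_variability(matrix, ctrl).value
        ctrl_raws = _background_raws(matrix, ctrl_matcher, peaks, bg_ss,
                                     config.n_background_iter)
        mean_bg = float(ctrl_raws.mean())
        if mean_bg == 0.0:
            raise DegenerateBackgroundError(
                f"all background variabilities are zero for control {i}")
        ctrl_bc[i] = ctrl_raw / mean_bg

    ctrl_mean = float(ctrl_bc.mean())
    final = bias_corrected / ctrl_mean
    sd = float(ctrl_bc.std(ddof=1)) if ctrl_bc.size > 1 else 0.0
    z = (bias_corrected - ctrl_mean) / sd if sd > 0 else float("nan")
    p_emp = empirical_pvalue(bias_corrected, ctrl_bc)
    p_norm = float(stats.norm.sf(z)) if np.isfinite(z) else float("nan")
    return VariabilityResult(
        feature_name=feature.name, raw=raw_res.value,
        background_mean=background_mean, bias_corrected=bias_corrected,
        negative_control_mean=ctrl_mean, final=final, z_score=z,
        p_value=p_emp, p_value_normal=p_norm, background_raws=bg_raws,
        control_bias_corrected=ctrl_bc, n_cells_used=raw_res.n_cells_used,
        n_cells_dropped_zero=raw_res.n_cells_dropped_zero, config=config)


_RESULT_COLUMNS = ["feature_name", "raw", "background_mean", "bias_corrected",
                   "negative_control_mean", "final", "z_score", "p_value",
                   "p_value_normal", "n_cells_used", "n_cells_dropped_zero"]


def write_results_tsv(results: Sequence[VariabilityResult], path,
                      header_lines: Sequence[str] = (),
                      iterations_path=None) -> None:
    """One row per feature set; optional per-iteration sidecar TSV."""
    path = Path(path)
    with open(path, "wt") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        if results:
            cfg = results[0].config
            fh.write(f"# n_background_iter={cfg.n_background_iter} "
                     f"n_negative_control={cfg.n_negative_control} "
                     f"gc_tolerance={cfg.gc_tolerance} "
                     f"accessibility_tolerance={cfg.accessibility_tolerance} "
                     f"accessibility_match={cfg.accessibility_match} "
                     f"seed={cfg.seed}\n")
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write("\t".join(
                f"{getattr(r, c):.10g}" if isinstance(getattr(r, c), float)
                else str(getattr(r, c)) for c in _RESULT_COLUMNS) + "\n")
    if iterations_path is not None:
        with open(iterations_path, "wt") as fh:
            fh.write("feature_name\tkind\titeration\tvalue\n")
            for r in results:
                for i, v in enumerate(r.background_raws):
                    fh.write(f"{r.feature_name}\tbackground_raw\t{i}\t{v:.10g}\n")
                for i, v in enumerate(r.control_bias_corrected):
                    fh.write(f"{r.feature_name}\tcontrol_bias_corrected\t{i}\t{v:.10g}\n")
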