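"""Titration benchmark: cell selection, block mixing, curve statistics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prism_atac import (BinaryAccessibilityMatrix, FeaturePeakSet,
                        SimulationConfig, build_mixture, draw_peak_blocks,
                        loess_fit, loess_mse, raw_variability, run_titration,
                        select_cells, u_statistic)
from prism_atac.exceptions import TooFewPointsError


def _matrix(values, cell_ids=None):
    values = np.asarray(values, dtype=np.uint8)
    cells = cell_ids or [f"c{i}" for i in range(values.shape[0])]
    return BinaryAccessibilityMatrix(values, cells,
                                     [f"p{j}" for j in range(values.shape[1])])


class TestSelectCells:
    @pytest.fixture()
    def matrix(self):
        # totals: c1 -> 10, c2 -> 5, c3 -> 1
        v = np.zeros((3, 10), dtype=np.uint8)
        v[0, :10] = 1
        v[1, :5] = 1
        v[2, :1] = 1
        return _matrix(v, cell_ids=["c1", "c2", "c3"])

    def test_subtype_a_takes_highest(self, matrix):
        idx = select_cells(matrix, "A", 2)
        assert [matrix.cell_ids[i] for i in idx] == ["c1", "c2"]

    def test_subtype_b_takes_lowest(self, matrix):
        idx = select_cells(matrix, "B", 2)
        assert [matrix.cell_ids[i] for i in idx] == ["c3", "c2"]

    def test_tie_broken_lexicographically(self):
        v = np.ones((3, 4), dtype=np.uint8)
        m = _matrix(v, cell_ids=["zz", "aa", "mm"])
        idx = select_cells(m, "A", 1)
        assert m.cell_ids[idx[0]] == "aa"

    def test_too_many_cells_requested(self, matrix):
        with pytest.raises(ValueError):
            select_cells(matrix, "A", 5)


class TestDrawPeakBlocks:
    def test_model1_contract(self, small_universe):
        matrix, peaks = small_universe
        cfg = SimulationConfig(model=1, n_peaks=100, seed=4)
        orig, match = draw_peak_blocks(matrix, peaks, cfg,
                                       np.random.default_rng(4))
        assert len(orig) == len(match) == 100
        assert not set(orig.peak_indices) & set(match.peak_indices)
        assert np.abs(peaks.gc[match.peak_indices]
                      - peaks.gc[orig.peak_indices]).max() <= cfg.gc_tolerance

    def test_model2_matched_above_percentile(self, small_universe):
        matrix, peaks = small_universe
        cfg = SimulationConfig(model=2, n_peaks=60, gc_tolerance=0.05, seed=4)
        _, match = draw_peak_blocks(matrix, peaks, cfg,
                                    np.random.default_rng(4))
        cut = np.nanpercentile(peaks.mean_accessibility, 75)
        assert (peaks.mean_accessibility[match.peak_indices] > cut).all()

    def test_fixed_seed_reproducible(self, small_universe):
        matrix, peaks = small_universe
        cfg = SimulationConfig(n_peaks=50, seed=8)
        a = draw_peak_blocks(matrix, peaks, cfg, np.random.default_rng(8))
        b = draw_peak_blocks(matrix, peaks, cfg, np.random.default_rng(8))
        assert np.array_equal(a[0].peak_indices, b[0].peak_indices)
        assert np.array_equal(a[1].peak_indices, b[1].peak_indices)


class TestBuildMixture:
    @pytest.fixture()
    def setup(self, rng):
        values = (rng.random((10, 20)) < 0.5).astype(np.uint8)
        m = _matrix(values)
        orig = FeaturePeakSet("o", np.arange(0, 8), universe_size=20)
        match = FeaturePeakSet("m", np.arange(10, 18), universe_size=20)
        return m, orig, match

    def test_endpoints(self, setup):
        m, orig, match = setup
        assert np.array_equal(build_mixture(m, orig, match, 0.0).values,
                              m.values[:, match.peak_indices])
        assert np.array_equal(build_mixture(m, orig, match, 1.0).values,
                              m.values[:, orig.peak_indices])

    def test_half_split(self, setup):
        m, orig, match = setup
        mix = build_mixture(m, orig, match, 0.5)
        assert np.array_equal(mix.values[:5], m.values[:5, orig.peak_indices])
        assert np.array_equal(mix.values[5:], m.values[5:, match.peak_indices])

    def test_shape_constant_in_proportion(self, setup):
        m, orig, match = setup
        for p in (0.0, 0.13, 0.5, 0.77, 1.0):
            mix = build_mixture(m, orig, match, p)
            assert mix.values.shape == (10, 8)
            assert mix.cell_ids == m.cell_ids


class TestUStatistic:
    def test_concave_parabola_is_one(self):
        i = np.arange(50.0)
        assert u_statistic(-(i - 25) ** 2) == pytest.approx(1.0)

    def test_convex_parabola_is_minus_one(self):
        i = np.arange(50.0)
        assert u_statistic((i - 25) ** 2) == pytest.approx(-1.0)

    def test_linear_curve_missing(self):
        assert u_statistic(np.linspace(0, 1, 20)) is None

    def test_too_short(self):
        with pytest.raises(TooFewPointsError):
            u_statistic([1.0, 2.0])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=30),
           st.floats(-100, 100), st.floats(0.01, 50))
    def test_invariant_to_shift_and_positive_scale(self, v, shift, scale):
        base = u_statistic(v)
        moved = u_statistic(np.asarray(v) * scale + shift)
        if base is None:
            assert moved is None
        else:
            assert moved == pytest.approx(base, abs=1e-9)


class TestLoess:
    def test_exact_quadratic_reproduced(self):
        x = np.linspace(0, 1, 30)
        y = 2.0 - 3.0 * x + 1.7 * x ** 2
        assert loess_mse(x, y, span=1.0) <= 1e-12

    def test_constant_curve_zero_mse(self):
        assert loess_mse(np.linspace(0, 1, 20), np.full(20, 0.4)) == pytest.approx(
            0.0, abs=1e-20)

    def test_too_few_points(self):
        with pytest.raises(TooFewPointsError):
            loess_mse([0, 1, 2, 3], [0, 1, 2, 3])

    def test_matches_r_loess_oracle(self):
        """Frozen fitted values from R: loess(y ~ x, span, degree = 2,
        surface = "direct") on the same 20-point dataset."""
        rng = np.random.default_rng(42)
        x = np.arange(1, 21) / 20
        y = -(x - 0.5) ** 2 + 0.05 * rng.standard_normal(20)
        expected = {
            0.50: [-0.19555638, -0.16104536, -0.13380236, -0.11067258,
                   -0.09182055, -0.07850831, -0.05820516, -0.02952366,
                   -0.00801843, 0.00124427, 0.00879405, 0.01863907,
                   0.01411533, -0.01331329, -0.05176733, -0.09357002,
                   -0.13046224, -0.16683073, -0.20250911, -0.23663368],
            0.75: [-0.19115298, -0.16233884, -0.13568305, -0.11086920,
                   -0.08786524, -0.06726166, -0.04995678, -0.03517127,
                   -0.01329118, 0.00636133, 0.01503668, 0.01366646,
                   0.00392657, -0.02104846, -0.04759528, -0.07843614,
                   -0.11465677, -0.15612153, -0.20242927, -0.25306700],
            1.00: [-0.20338193, -0.16705699, -0.13391098, -0.10399482,
                   -0.07744403, -0.05449255, -0.03532547, -0.01995477,
                   -0.00803988, 0.00194083, 0.00760359, 0.00238483,
                   -0.00876099, -0.02562603, -0.04847110, -0.07753629,
                   -0.11294186, -0.15467463, -0.20265827, -0.25675353],
        }
        for span, vals in expected.items():
            assert loess_fit(x, y, span=span) == pytest.approx(vals, abs=1e-7)

    def test_noise_recovered_within_factor_two(self):
        """MSE around the fit tracks the injected noise variance."""
        sigma = 0.05
        mses = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.linspace(0, 1, 50)
            y = -(x - 0.5) ** 2 + sigma * rng.standard_normal(50)
            mses.append(loess_mse(x, y, span=0.75))
        mean_mse = np.mean(mses)
        assert sigma ** 2 / 2 < mean_mse < sigma ** 2 * 2


class TestRunTitration:
    def test_duplicate_blocks_give_flat_curve(self, rng):
        """If matched columns literally duplicate the original columns,
        no heterogeneity is injected at any proportion."""
        block = (rng.random((12, 10)) < 0.5).astype(np.uint8)
        block[block.sum(1) == 0, 0] = 1
        m = _matrix(np.hstack([block, block]))
        orig = FeaturePeakSet("o", np.arange(10), universe_size=20)
        match = FeaturePeakSet("m", np.arange(10, 20), universe_size=20)
        all_peaks = FeaturePeakSet("all", np.arange(10), universe_size=10)
        values = [raw_variability(build_mixture(m, orig, match, p), all_peaks).value
                  for p in np.arange(1, 21) / 20]
        assert np.ptp(values) <= 1e-12
        assert loess_mse(np.arange(1, 21) / 20, values) <= 1e-12

    def test_inverse_u_on_fixture(self, small_universe):
        matrix, peaks = small_universe
        cfg = SimulationConfig(model=1, subtype="A", n_peaks=100, n_cells=80,
                               n_proportion_steps=20, seed=2)
        curve = run_titration(matrix, peaks, cfg)
        assert curve.proportions.shape == (20,)
        assert np.all(np.diff(curve.proportions) > 0)
        # endpoints below the midpoint: necessary condition for inverse-U
        mid = curve.variability[len(curve.variability) // 2 - 1]
        assert curve.variability[0] < mid and curve.variability[-1] < mid
        assert curve.u_statistic is not None and curve.u_statistic > 0.5

    def test_swapped_blocks_reverse_the_curve(self, small_universe):
        """Mixing is symmetric: exchanging the original and matched blocks
        mirrors the titration curve around the 50% point."""
        matrix, peaks = small_universe
        cfg = SimulationConfig(n_peaks=150, n_cells=80, seed=6,
                               variability="raw")
        orig, match = draw_peak_blocks(matrix, peaks, cfg,
                                       np.random.default_rng(6))
        sub = matrix.restrict_cells(select_cells(matrix, "A", 80))
        grid = np.arange(1, 20) / 20
        all_peaks = FeaturePeakSet("all", np.arange(150), universe_size=150)
        sub_rev = sub.restrict_cells(np.arange(79, -1, -1))
        fwd = np.array([raw_variability(build_mixture(sub, orig, match, p),
                                        all_peaks).value for p in grid])
        rev = np.array([raw_variability(build_mixture(sub_rev, match, orig,
                                                      1 - p),
                                        all_peaks).value for p in grid])
        # each cell carries the same block in both runs (dispersion is
        # invariant to cell order), so the curves agree exactly
        assert fwd == pytest.approx(rev, abs=1e-10)

    def test_raw_flavor_equals_scaled_default(self, small_universe):
        """The shared background normalization is a positive constant, so
        the default curve is the raw curve rescaled and U is unchanged."""
        matrix, peaks = small_universe
        kwargs = dict(n_peaks=100, n_cells=60, n_proportion_steps=10, seed=3,
                      n_background_iter=5)
        bc = run_titration(matrix, peaks,
                           SimulationConfig(variability="bias_corrected",
                                            **kwargs))
        raw = run_titration(matrix, peaks,
                            SimulationConfig(variability="raw", **kwargs))
        ratio = raw.variability / bc.variability
        assert np.ptp(ratio) < 1e-9
        assert bc.u_statistic == pytest.approx(raw.u_statistic, abs=1e-12)
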