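import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_grid
from d3map.delay_density import (
    DelayPairs,
    DensityConfig,
    compute_density_map,
    compute_histogram2d,
    default_range,
    histogram1d,
    load_grid_txt,
    make_delay_pairs,
    normalize_to_unit_max,
    save_grid_txt,
    shuffle_intervals,
    smooth_density_2d,
)
from d3map.rr_io import InsufficientDataError, RRSeries
from d3map.synthetic import BistableSpec, gen_bistable


def dense_dscatter_smooth(values: np.ndarray, lambda_user: float) -> np.ndarray:
    """Independent dense-linear-algebra oracle for the penalized smoother."""
    n = values.shape[0]
    lam = n / lambda_user
    eye = np.eye(n)
    d1 = np.diff(eye, 1, axis=0)
    d2 = np.diff(eye, 2, axis=0)
    a = eye + 2.0 * lam * d1.T @ d1 + lam**2 * d2.T @ d2
    z = np.linalg.solve(a, values)
    return np.linalg.solve(a, z.T).T


class TestDelayPairs:
    def test_lag1_construction(self):
        s = RRSeries.from_intervals([0.5, 0.7, 0.9])
        p = make_delay_pairs(s, lag=1)
        np.testing.assert_array_equal(p.x, [0.5, 0.7])
        np.testing.assert_array_equal(p.y, [0.7, 0.9])

    def test_lag_consistency_invariant(self):
        s = RRSeries.from_intervals(np.linspace(0.4, 1.2, 10))
        for lag in (1, 2, 3):
            p = make_delay_pairs(s, lag=lag)
            assert len(p) == 10 - lag
            np.testing.assert_array_equal(p.x[lag:], p.y[:-lag])

    def test_series_not_longer_than_lag_rejected(self):
        s = RRSeries.from_intervals([0.5, 0.7])
        with pytest.raises(InsufficientDataError):
            make_delay_pairs(s, lag=2)

    def test_constant_series_lies_on_identity_line(self):
        s = RRSeries.from_intervals([0.8] * 10)
        p = make_delay_pairs(s)
        np.testing.assert_array_equal(p.x, p.y)


class TestHistogram2d:
    def test_single_point_mass(self):
        p = DelayPairs(np.full(7, 0.55), np.full(7, 0.55))
        g = compute_histogram2d(p, nbins=4, range=(0.0, 1.0))
        assert g.values.sum() == 7
        assert g.values.max() == 7
        assert g.max_count_m == 7

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_mass_conservation_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-0.2, 1.2, 300)
        y = rng.uniform(-0.2, 1.2, 300)
        g = compute_histogram2d(DelayPairs(x, y), nbins=13, range=(0.0, 1.0))
        in_range = np.sum((x >= 0) & (x <= 1) & (y >= 0) & (y <= 1))
        assert g.values.sum() == in_range == g.total_count
        assert g.n_out_of_range == 300 - in_range

    def test_half_open_binning_convention(self):
        # interior edge -> upper bin; the top of the range -> last bin
        p = DelayPairs(np.array([0.5, 1.0]), np.array([0.5, 1.0]))
        g = compute_histogram2d(p, nbins=2, range=(0.0, 1.0))
        assert g.values[1, 1] == 2
        assert g.values[0, 0] == 0

    def test_empty_grid_flagged_not_raised(self):
        p = DelayPairs(np.array([5.0]), np.array([5.0]))
        g = compute_histogram2d(p, nbins=4, range=(0.0, 1.0))
        assert g.is_empty
        assert g.n_out_of_range == 1


class TestNormalize:
    def test_direct_division_by_max(self):
        g = make_grid([[2.0, 4.0], [0.0, 4.0]])
        out = normalize_to_unit_max(g)
        np.testing.assert_allclose(out.values, [[0.5, 1.0], [0.0, 1.0]])
        assert out.normalized

    def test_all_zero_grid_passes_through(self):
        g = make_grid(np.zeros((3, 3)))
        out = normalize_to_unit_max(g)
        assert out.normalized
        assert np.all(out.values == 0)

    def test_double_normalization_rejected(self):
        g = normalize_to_unit_max(make_grid([[1.0, 2.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="already normalized"):
            normalize_to_unit_max(g)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_argmax_preserved(self, seed):
        rng = np.random.default_rng(seed)
        g = make_grid(rng.uniform(0, 10, (6, 6)))
        assert normalize_to_unit_max(g).argmax() == g.argmax()


class TestSmoother:
    def test_matches_dense_oracle(self, rng):
        vals = rng.uniform(0, 20, (15, 15))
        g = make_grid(vals)
        out = smooth_density_2d(g, lambda_user=20.0)
        np.testing.assert_allclose(out.values, dense_dscatter_smooth(vals, 20.0), atol=1e-8)

    def test_constant_grid_unchanged(self):
        g = make_grid(np.full((12, 12), 3.7))
        out = smooth_density_2d(g)
        np.testing.assert_allclose(out.values, 3.7, atol=1e-10)

    def test_mass_and_column_sums_conserved(self, rng):
        vals = rng.uniform(0, 50, (10, 10))
        g = make_grid(vals)
        out = smooth_density_2d(g, lambda_user=5.0)
        # column pass conserves column sums; the row pass redistributes
        # within rows, so total mass survives both
        np.testing.assert_allclose(out.values.sum(), vals.sum(), rtol=1e-8)

    def test_impulse_response_spreads_and_lowers_peak(self):
        vals = np.zeros((11, 11))
        vals[5, 5] = 1.0
        strong = smooth_density_2d(make_grid(vals), lambda_user=1.0)
        assert strong.values[5, 5] < 1.0
        assert strong.values[5, 4] > 0 and strong.values[4, 5] > 0
        # weak smoothing approaches the identity
        weak = smooth_density_2d(make_grid(vals), lambda_user=1e6)
        assert abs(weak.values[5, 5] - 1.0) < 1e-3
        assert strong.values[5, 5] < weak.values[5, 5]

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="nbins >= 3"):
            smooth_density_2d(make_grid(np.ones((2, 2))))


class TestComposition:
    def test_max_is_exactly_one(self):
        s = gen_bistable(BistableSpec(n_beats=2000, seed=21))
        g = compute_density_map(s, DensityConfig(nbins=50))
        assert g.values.max() == 1.0
        assert g.normalized

    def test_unsmoothed_map_equals_manual_composition(self, small_series):
        cfg = DensityConfig(nbins=30, range=(0.3, 1.5), smooth=False)
        auto = compute_density_map(small_series, cfg)
        manual = normalize_to_unit_max(
            compute_histogram2d(make_delay_pairs(small_series, 1), 30, (0.3, 1.5))
        )
        np.testing.assert_array_equal(auto.values, manual.values)

    def test_determinism(self, small_series):
        a = compute_density_map(small_series, DensityConfig(nbins=40))
        b = compute_density_map(small_series, DensityConfig(nbins=40))
        np.testing.assert_array_equal(a.values, b.values)

    def test_transpose_matches_time_reversed_series(self):
        # away from bin edges, the map of the reversed series is the transpose
        rng = np.random.default_rng(5)
        rr = rng.choice([0.435, 0.705, 1.065], size=400)  # values at bin centers
        fwd = compute_density_map(
            RRSeries.from_intervals(rr), DensityConfig(nbins=10, range=(0.3, 1.2), smooth=False)
        )
        rev = compute_density_map(
            RRSeries.from_intervals(rr[::-1]), DensityConfig(nbins=10, range=(0.3, 1.2), smooth=False)
        )
        np.testing.assert_array_equal(fwd.values.T, rev.values)


class TestShuffle:
    def test_interval_multiset_preserved_exactly(self, small_series):
        out = shuffle_intervals(small_series, seed=3)
        np.testing.assert_array_equal(np.sort(out.intervals), np.sort(small_series.intervals))

    def test_1d_histogram_invariant_under_shuffle(self, small_series):
        out = shuffle_intervals(small_series, seed=4)
        h_orig = histogram1d(small_series, 25, (0.3, 1.5))
        h_shuf = histogram1d(out, 25, (0.3, 1.5))
        np.testing.assert_array_equal(h_orig, h_shuf)

    def test_fixed_seed_reproducible(self, small_series):
        a = shuffle_intervals(small_series, seed=7)
        b = shuffle_intervals(small_series, seed=7)
        np.testing.assert_array_equal(a.intervals, b.intervals)

    def test_two_beat_permutations_equidistributed(self):
        s = RRSeries.from_intervals([0.5, 0.9])
        hits = sum(shuffle_intervals(s, seed=k).intervals[0] == 0.9 for k in range(1000))
        assert abs(hits / 1000 - 0.5) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            shuffle_intervals(RRSeries.from_intervals([0.5]), seed=0)


class TestHistogram1d:
    def test_conservation(self, small_series):
        lo, hi = default_range(small_series)
        h = histogram1d(small_series, 20, (lo, hi))
        assert h.sum() == len(small_series)

    def test_all_out_of_range_gives_zero_vector(self, small_series):
        h = histogram1d(small_series, 10, (10.0, 20.0))
        assert np.all(h == 0)


class TestGridText:
    def test_round_trip(self, small_series, tmp_path):
        g = compute_density_map(small_series, DensityConfig(nbins=20))
        path = save_grid_txt(g, tmp_path / "grid.txt")
        back = load_grid_txt(path)
        np.testing.assert_allclose(back.values, g.values, rtol=1e-6)
        np.testing.assert_allclose(back.x_edges, g.x_edges, rtol=1e-6)
        assert back.normalized
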