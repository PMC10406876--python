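import numpy as np
import pytest

from iccs_coloc.errors import DegenerateInputError, ValidationError
from iccs_coloc.iccs import (
    CorrelationMap2D,
    GaussianFitResult,
    ICCSConfig,
    RadialCorrelation,
    coloc_fraction,
    correlate_2d,
    correlate_2d_direct,
    fit_gaussian,
    radial_average,
    run_iccs,
)
from iccs_coloc.io_masks import NuclearMask

from conftest import make_foci_image


def _map_from_values(values, n_pairs=None):
    values = np.asarray(values, dtype=float)
    L = values.shape[0] // 2
    if n_pairs is None:
        n_pairs = np.where(np.isfinite(values), 1, 0)
    return CorrelationMap2D(
        values=values, pair=(0, 1), n_pairs=np.asarray(n_pairs), max_lag_px=L
    )


def _converged_fit(g0, w=3.0, g_inf=0.0):
    return GaussianFitResult(
        g0=g0, w_px=w, g_inf=g_inf, converged=True, rss=0.0, n_points=10
    )


class TestCorrelate2D:
    def test_constant_image_zero_everywhere(self):
        img = np.full((32, 32), 5.0)
        mask = NuclearMask(mask=np.ones((32, 32), dtype=bool))
        cmap = correlate_2d(img, img, mask, max_lag_px=8)
        assert np.nanmax(np.abs(cmap.values)) < 1e-9

    def test_zero_lag_hand_example(self):
        # [[4,0],[0,0]]: <I^2>/<I>^2 - 1 = (16/4)/1 - 1 = 3 at zero lag
        img = np.array([[4.0, 0.0], [0.0, 0.0]])
        mask = NuclearMask(mask=np.ones((2, 2), dtype=bool))
        g = correlate_2d_direct(img, img, mask, max_lag_px=0)
        assert g[0, 0] == pytest.approx(3.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_fft_matches_direct_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.1, 1.0, (16, 16))
        b = rng.uniform(0.1, 1.0, (16, 16))
        m = rng.uniform(size=(16, 16)) > 0.35
        m[8, 8] = True  # guarantee non-empty
        mask = NuclearMask(mask=m)
        fast = correlate_2d(a, b, mask, max_lag_px=6, pair=(0, 1))
        slow = correlate_2d_direct(a, b, mask, max_lag_px=6)
        defined = fast.defined
        np.testing.assert_allclose(
            fast.values[defined], slow[defined], atol=1e-10, rtol=0
        )
        # undefined lags agree too
        assert np.all(np.isnan(slow[~defined]))

    def test_autocorrelation_point_symmetric_exactly(self, rng):
        a = rng.uniform(0.1, 1.0, (32, 32))
        m = rng.uniform(size=(32, 32)) > 0.2
        cmap = correlate_2d(a, a, NuclearMask(mask=m), max_lag_px=8, pair=(0, 0))
        v = cmap.values
        flipped = v[::-1, ::-1]
        both = np.isfinite(v) & np.isfinite(flipped)
        np.testing.assert_array_equal(v[both], flipped[both])

    def test_n_pairs_counts(self):
        mask = NuclearMask(mask=np.ones((8, 8), dtype=bool))
        img = np.ones((8, 8))
        cmap = correlate_2d(img, img, mask, max_lag_px=2)
        assert cmap.n_pairs[2, 2] == 64  # zero lag: all pixels pair with themselves
        assert cmap.n_pairs[2, 3] == 56  # lag (0,1): 8 rows x 7 columns

    def test_zero_mean_degenerate(self):
        mask = NuclearMask(mask=np.ones((8, 8), dtype=bool))
        with pytest.raises(DegenerateInputError):
            correlate_2d(np.zeros((8, 8)), np.ones((8, 8)), mask, max_lag_px=2)

    def test_lag_too_large_rejected(self):
        mask = NuclearMask(mask=np.ones((8, 8), dtype=bool))
        with pytest.raises(ValidationError):
            correlate_2d(np.ones((8, 8)), np.ones((8, 8)), mask, max_lag_px=4)

    def test_shape_mismatch_rejected(self):
        mask = NuclearMask(mask=np.ones((8, 8), dtype=bool))
        with pytest.raises(ValidationError):
            correlate_2d(np.ones((8, 8)), np.ones((8, 9)), mask, max_lag_px=2)


class TestRadialAverage:
    def test_single_zero_lag(self):
        values = np.full((5, 5), np.nan)
        values[2, 2] = 3.0
        n_pairs = np.zeros((5, 5), int)
        n_pairs[2, 2] = 10
        radial = radial_average(_map_from_values(values, n_pairs), bin_width_px=1.0)
        assert len(radial.radii_px) == 1
        assert radial.radii_px[0] == 0.0
        assert radial.g[0] == 3.0

    def test_unit_radius_mean(self):
        values = np.full((3, 3), np.nan)
        values[1, 0] = 1.0  # (dy=0, dx=-1)
        values[1, 2] = 1.0
        values[0, 1] = 3.0
        values[2, 1] = 3.0
        radial = radial_average(_map_from_values(values), bin_width_px=1.0)
        assert len(radial.radii_px) == 1
        assert radial.radii_px[0] == pytest.approx(1.0)
        assert radial.g[0] == pytest.approx(2.0)
        assert radial.counts[0] == 4

    def test_analytic_gaussian_profile_within_2pct(self):
        L = 8
        dy, dx = np.mgrid[-L : L + 1, -L : L + 1]
        values = np.exp(-(dy**2 + dx**2) / 9.0)
        radial = radial_average(
            _map_from_values(values, np.ones_like(values, int)), bin_width_px=1.0
        )
        expected = np.exp(-radial.radii_px**2 / 9.0)
        # 2% relative agreement where the profile is non-negligible; in the
        # far tail the angular mean of a convex profile deviates relative to
        # its tiny value (discretization of the lag grid), so check absolute
        core = expected >= 0.05
        np.testing.assert_allclose(radial.g[core], expected[core], rtol=0.02)
        np.testing.assert_allclose(radial.g, expected, atol=0.01)

    def test_min_pairs_filter_drops_lags(self):
        values = np.ones((3, 3))
        n_pairs = np.full((3, 3), 200)
        n_pairs[0, 0] = 5  # corner lag poorly supported
        full = radial_average(_map_from_values(values, n_pairs), bin_width_px=1.0)
        filtered = radial_average(
            _map_from_values(values, n_pairs), bin_width_px=1.0, min_pairs_per_lag=100
        )
        assert filtered.counts.sum() == full.counts.sum() - 1

    def test_bad_bin_width(self):
        values = np.ones((3, 3))
        with pytest.raises(ValidationError):
            radial_average(_map_from_values(values), bin_width_px=0)

    def test_radii_strictly_increasing_invariant(self, rng):
        a = rng.uniform(0.1, 1.0, (32, 32))
        mask = NuclearMask(mask=np.ones((32, 32), dtype=bool))
        cmap = correlate_2d(a, a, mask, max_lag_px=10)
        radial = radial_average(cmap, bin_width_px=1.0)
        assert np.all(np.diff(radial.radii_px) > 0)
        assert np.all(radial.counts > 0)


class TestFitGaussian:
    def test_noiseless_recovery(self):
        r = np.arange(1, 13, dtype=float)
        g = 0.5 * np.exp(-(r**2) / 16.0) + 0.1
        radial = RadialCorrelation(radii_px=r, g=g, counts=np.ones(len(r), int))
        fit = fit_gaussian(radial, exclude_zero_lag=True, fit_range_px=12.0)
        assert fit.converged
        assert fit.g0 == pytest.approx(0.5, abs=1e-6)
        assert fit.w_px == pytest.approx(4.0, abs=1e-6)
        assert fit.g_inf == pytest.approx(0.1, abs=1e-6)
        assert fit.rss < 1e-12

    def test_all_zero_profile(self):
        r = np.arange(1, 10, dtype=float)
        radial = RadialCorrelation(
            radii_px=r, g=np.zeros(len(r)), counts=np.ones(len(r), int)
        )
        fit = fit_gaussian(radial, exclude_zero_lag=True, fit_range_px=10.0)
        assert fit.converged
        assert abs(fit.g0) <= 1e-8
        assert abs(fit.g_inf) <= 1e-8

    def test_noisy_width_recovery_monte_carlo(self):
        r = np.arange(1, 13, dtype=float)
        clean = 0.5 * np.exp(-(r**2) / 16.0) + 0.1
        widths = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, 0.01, size=len(r))
            radial = RadialCorrelation(
                radii_px=r, g=noisy, counts=np.ones(len(r), int)
            )
            fit = fit_gaussian(radial, exclude_zero_lag=True, fit_range_px=12.0)
            assert fit.converged
            widths.append(fit.w_px)
        assert abs(np.median(widths) - 4.0) / 4.0 <= 0.05

    def test_too_few_bins(self):
        radial = RadialCorrelation(
            radii_px=np.array([1.0, 2.0, 3.0]),
            g=np.zeros(3),
            counts=np.ones(3, int),
        )
        with pytest.raises(ValidationError):
            fit_gaussian(radial, exclude_zero_lag=False, fit_range_px=5.0)


class TestColocFraction:
    def test_perfect_colocalization(self):
        res = coloc_fraction(
            _converged_fit(0.5), _converged_fit(0.5), _converged_fit(0.5)
        )
        assert res.f_raw == pytest.approx(1.0)
        assert res.f == pytest.approx(1.0)

    def test_independence(self):
        res = coloc_fraction(
            _converged_fit(0.4), _converged_fit(0.3), _converged_fit(0.0)
        )
        assert res.f == 0.0

    def test_printed_formula_arithmetic(self):
        res = coloc_fraction(
            _converged_fit(0.4), _converged_fit(0.2), _converged_fit(0.1)
        )
        assert res.f_raw == pytest.approx(0.375, abs=1e-12)

    def test_clamping_flagged(self):
        res = coloc_fraction(
            _converged_fit(0.2), _converged_fit(0.2), _converged_fit(0.5)
        )
        assert res.f == 1.0
        assert res.f_raw > 1.0
        assert "clamped" in res.qc_flags

    def test_negative_cross_amplitude(self):
        res = coloc_fraction(
            _converged_fit(0.4), _converged_fit(0.4), _converged_fit(-0.1)
        )
        assert res.f == 0.0
        assert "anticorrelated_cross_amplitude" in res.qc_flags

    def test_nonpositive_auto_amplitude_flag_not_exception(self):
        res = coloc_fraction(
            _converged_fit(-0.1), _converged_fit(0.4), _converged_fit(0.1)
        )
        assert np.isnan(res.f)
        assert "nonpositive_autocorrelation_amplitude" in res.qc_flags

    def test_nonconverged_fit_rejected(self):
        bad = GaussianFitResult(
            g0=np.nan, w_px=np.nan, g_inf=np.nan, converged=False, rss=np.nan, n_points=9
        )
        with pytest.raises(ValidationError):
            coloc_fraction(bad, _converged_fit(0.4), _converged_fit(0.1))


class TestRunIccs:
    def test_identical_channels_f_near_one(self):
        image, _, mask = make_foci_image(f_true=0.0, seed=5)
        image.channels[1] = image.channels[0].copy()
        res = run_iccs(image, 0, 1, mask, ICCSConfig())
        assert res.f >= 0.99

    def test_independent_channels_small_f(self):
        fs = []
        for seed in range(10):
            image, _, mask = make_foci_image(f_true=0.0, seed=seed)
            fs.append(run_iccs(image, 0, 1, mask, ICCSConfig()).f)
        assert np.mean(fs) <= 0.07

    def test_half_colocalized_recovery(self):
        fs = []
        for seed in range(10):
            image, _, mask = make_foci_image(f_true=0.5, seed=seed)
            fs.append(run_iccs(image, 0, 1, mask, ICCSConfig()).f)
        assert abs(np.mean(fs) - 0.5) <= 0.10

    def test_scale_invariance(self):
        image, _, mask = make_foci_image(f_true=0.5, seed=9)
        res1 = run_iccs(image, 0, 1, mask, ICCSConfig())
        image.channels[0] = image.channels[0] * 3.7
        image.channels[1] = image.channels[1] * 0.25
        res2 = run_iccs(image, 0, 1, mask, ICCSConfig())
        assert abs(res1.f - res2.f) <= 1e-9
        assert abs(res1.fit11.g0 - res2.fit11.g0) <= 1e-9
        assert abs(res1.fit12.g0 - res2.fit12.g0) <= 1e-9

    def test_amplitude_decreases_with_density(self):
        g0s = []
        for n in (20, 50, 100):
            image, _, mask = make_foci_image(f_true=0.5, n_foci=n, seed=3, noise="none")
            g0s.append(run_iccs(image, 0, 1, mask, ICCSConfig()).fit11.g0)
        assert g0s[0] > g0s[1] > g0s[2]

    def test_deterministic(self):
        image, _, mask = make_foci_image(f_true=0.5, seed=2)
        r1 = run_iccs(image, 0, 1, mask, ICCSConfig())
        r2 = run_iccs(image, 0, 1, mask, ICCSConfig())
        assert r1.f == r2.f
        assert r1.fit12.g0 == r2.fit12.g0

    def test_bad_channel_index(self):
        image, _, mask = make_foci_image(f_true=0.5, seed=2)
        with pytest.raises(ValidationError):
            run_iccs(image, 0, 5, mask, ICCSConfig())
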