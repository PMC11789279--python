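"""Unit and oracle tests for the spatial-period pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spinecyto as sc
from spinecyto.periodicity import _exact_mwu_two_tailed, analyse_roi


def make_profile(values, spacing=1.0):
    return sc.Profile1D(np.asarray(values, float), spacing)


# --------------------------------------------------------------------------
# ROI extraction and row means


class TestExtractRoi:
    def test_full_image_is_identity(self):
        img = sc.ImageGrid(np.arange(200.0).reshape(20, 10), 1.0)
        roi = sc.RoiBox(0, 20, width_um=10)
        sub = sc.extract_roi(img, roi)
        np.testing.assert_array_equal(sub.values, img.values)
        assert sub.pixel_um == img.pixel_um

    @pytest.mark.parametrize(
        "pixel_um,dv0,dv1,width,shape",
        [(1.0, 0, 20, 15, (20, 15)), (0.5, 10, 50, 7.5, (80, 15))],
    )
    def test_calibration_arithmetic(self, pixel_um, dv0, dv1, width, shape):
        img = sc.ImageGrid(np.zeros((200, 40)), pixel_um)
        sub = sc.extract_roi(img, sc.RoiBox(dv0, dv1, width_um=width))
        assert sub.values.shape == shape

    def test_out_of_bounds_raises(self):
        img = sc.ImageGrid(np.zeros((20, 10)), 1.0)
        with pytest.raises(IndexError):
            sc.extract_roi(img, sc.RoiBox(0, 25, width_um=10))

    def test_invalid_roi_raises(self):
        with pytest.raises(ValueError):
            sc.RoiBox(10, 10)
        with pytest.raises(ValueError):
            sc.RoiBox(0, 10, width_um=0)


class TestRowMeanProfile:
    def test_single_column_equals_column(self):
        col = np.arange(12.0)
        prof = sc.row_mean_profile(sc.ImageGrid(col[:, None], 1.0))
        np.testing.assert_array_equal(prof.values, col)

    def test_mean_is_columnwise(self):
        img = sc.ImageGrid(np.array([[1.0, 3.0], [2.0, 2.0]] * 4), 1.0)
        np.testing.assert_array_equal(sc.row_mean_profile(img).values,
                                      [2.0] * 8)

    def test_row_sinusoid_period_preserved(self):
        n = 64
        x = np.sin(2 * np.pi * np.arange(n) / 16)
        img = sc.ImageGrid(np.tile(x[:, None], (1, 5)), 1.0)
        prof = sc.row_mean_profile(img)
        np.testing.assert_allclose(prof.values, x, atol=1e-12)


# --------------------------------------------------------------------------
# blur


class TestBlur:
    def test_constant_image_unchanged(self):
        img = sc.ImageGrid(np.full((30, 10), 3.7), 1.0)
        np.testing.assert_allclose(sc.blur(img, 3.0).values, 3.7, rtol=1e-12)

    @pytest.mark.parametrize("period_um", [10.0, 20.0, 40.0])
    def test_gaussian_transfer_function(self, period_um):
        """Sinusoid attenuation matches exp(-2 pi^2 sigma^2 / T^2) to 2%."""
        n, sigma = 240, 3.0
        x = np.cos(2 * np.pi * np.arange(n) / period_um)
        img = sc.ImageGrid(np.tile(x[:, None], (1, 15)), 1.0)
        blurred = sc.blur(img, sigma)
        k = int(n / period_um)
        amp = 2 * np.abs(np.fft.rfft(blurred.values[:, 7])[k]) / n
        expected = np.exp(-2 * np.pi**2 * sigma**2 / period_um**2)
        assert amp == pytest.approx(expected, rel=0.02)

    def test_zero_sigma_is_identity(self):
        img = sc.ImageGrid(np.random.default_rng(0).normal(size=(20, 8)), 1.0)
        np.testing.assert_array_equal(sc.blur(img, 0.0).values, img.values)

    def test_negative_sigma_raises(self):
        img = sc.ImageGrid(np.zeros((10, 4)), 1.0)
        with pytest.raises(ValueError):
            sc.blur(img, -1.0)


# --------------------------------------------------------------------------
# detrend


class TestDetrend:
    def test_quartic_removed_exactly(self):
        n = 100
        x = np.linspace(-1, 1, n)
        quartic = 3 - 2 * x + x**2 + 0.5 * x**3 - 4 * x**4
        out = sc.detrend(make_profile(quartic)).values
        assert np.max(np.abs(out)) < 1e-8 * np.max(np.abs(quartic))

    def test_sinusoid_survives_detrending(self):
        n = 200
        x = np.linspace(-1, 1, n)
        sine = np.sin(2 * np.pi * np.arange(n) / 20)
        out = sc.detrend(make_profile(5 * x**4 - x**2 + sine)).values
        r = np.corrcoef(out, sine)[0, 1]
        assert r > 0.99

    def test_constant_gives_zero_and_zero_mean(self):
        out = sc.detrend(make_profile(np.full(50, 2.5))).values
        np.testing.assert_allclose(out, 0, atol=1e-10)
        rng = np.random.default_rng(1)
        out2 = sc.detrend(make_profile(rng.normal(size=64))).values
        assert abs(out2.mean()) < 1e-10

    def test_too_short_profile_raises(self):
        with pytest.raises(ValueError):
            sc.detrend(make_profile(np.arange(8)), order=8)


# --------------------------------------------------------------------------
# periodogram + Fisher g-test


def brute_force_dft_power(values):
    n = len(values)
    power = []
    for k in range(1, n // 2 + 1):
        c = sum(
            values[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n)
        )
        power.append(abs(c) ** 2 / n)
    return np.array(power)


class TestPeriodogram:
    def test_pure_sinusoid_single_ordinate(self):
        n = 64
        x = np.sin(2 * np.pi * 4 * np.arange(n) / n)
        pg = sc.periodogram(make_profile(x))
        assert np.argmax(pg.power) == 3  # k = 4
        others = np.delete(pg.power, 3)
        assert others.max() < 1e-20 * pg.power[3]

    @pytest.mark.parametrize("n", [17, 32, 64])
    def test_matches_brute_force_dft(self, n, rng):
        x = rng.normal(size=n)
        pg = sc.periodogram(make_profile(x))
        np.testing.assert_allclose(pg.power, brute_force_dft_power(x),
                                   rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("n", [31, 64])
    def test_parseval(self, n, rng):
        x = rng.normal(size=n)
        x = x - x.mean()
        pg = sc.periodogram(make_profile(x))
        # sum over all DFT ordinates equals n * variance; positive
        # frequencies carry double weight except DC (0 here) and Nyquist
        w = np.full(pg.m, 2.0)
        if pg.has_nyquist:
            w[-1] = 1.0
        total = (w * pg.power).sum()
        np.testing.assert_allclose(total, n * x.var(), rtol=1e-6)

    def test_periods_strictly_decreasing_and_no_dc(self):
        pg = sc.periodogram(make_profile(np.arange(20.0)))
        assert np.all(np.diff(pg.periods_um) < 0)
        assert pg.periods_um[0] == 20.0  # k=1, not the zero frequency


class TestFisherGTest:
    def test_single_nonzero_ordinate_gives_p_zero(self):
        n = 32
        x = np.sin(2 * np.pi * 4 * np.arange(n) / n)
        assert sc.fisher_g_test(sc.periodogram(make_profile(x))) == 0.0

    def test_all_zero_spectrum_signalled(self):
        with pytest.raises(ZeroDivisionError):
            sc.fisher_g_test(sc.periodogram(make_profile(np.zeros(16))))

    def test_monte_carlo_calibration(self):
        """Type-I error at alpha=0.05 on white noise within [3.5%, 6.5%]."""
        rejections = 0
        n_rep = 2000
        for seed in range(n_rep):
            prof = sc.gen_white_noise_profile(128, 1.0, 1.0, seed=seed)
            if sc.fisher_g_test(sc.periodogram(prof)) <= 0.05 - 1e-12:
                rejections += 1
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_matches_simulation_oracle_small_m(self, rng):
        """p for a fixed m=8 spectrum matches a Monte-Carlo null of
        exponential ordinates within 0.01."""
        power = np.array([0.5, 1.2, 0.3, 3.8, 0.9, 0.2, 1.1, 0.6])
        pg = sc.PeriodogramResult(
            periods_um=16.0 / np.arange(1, 9), power=power,
            n_samples=17, spacing_um=1.0, has_nyquist=False,
        )
        p = sc.fisher_g_test(pg)
        sims = rng.exponential(size=(200_000, 8))
        g_null = sims.max(axis=1) / sims.sum(axis=1)
        g_obs = power.max() / power.sum()
        p_mc = np.mean(g_null >= g_obs)
        assert p == pytest.approx(p_mc, abs=0.01)


class TestFftDominantPeriod:
    def test_exact_bin_recovery(self):
        n = 240
        x = np.sin(2 * np.pi * np.arange(n) / 40)
        est = sc.fft_dominant_period(make_profile(x))
        assert est.period_um == pytest.approx(40.0)
        assert est.significant

    def test_power_ordering_picks_stronger_component(self):
        n = 240
        t = np.arange(n)
        x = 2 * np.sin(2 * np.pi * t / 40) + np.sin(2 * np.pi * t / 24)
        est = sc.fft_dominant_period(make_profile(x))
        assert est.period_um == pytest.approx(40.0)

    def test_tie_break_prefers_largest_period(self):
        from spinecyto.periodicity import dominant_period_index

        power = np.array([0.1, 0.2, 5.0, 0.3, 5.0, 0.1])
        pg = sc.PeriodogramResult(
            periods_um=12.0 / np.arange(1, 7), power=power,
            n_samples=12, spacing_um=1.0, has_nyquist=True,
        )
        # exact tie between k=3 (4 µm) and k=5 (2.4 µm): smaller k wins
        assert dominant_period_index(pg) == 2

    def test_trend_scale_periods_suppressed(self):
        # a half-cycle trend should not be reported as the period
        n = 240
        x = np.sin(np.pi * np.arange(n) / n) + 0.3 * np.sin(
            2 * np.pi * np.arange(n) / 40
        )
        est = sc.fft_dominant_period(make_profile(x))
        assert est.period_um <= n / 3


# --------------------------------------------------------------------------
# ACF


def brute_force_acf(x, max_lag):
    x = x - x.mean()
    n = len(x)
    c = [sum(x[t] * x[t + lag] for t in range(n - lag)) / n
         for lag in range(max_lag + 1)]
    return np.array(c) / c[0]


class TestAutocorrelation:
    @pytest.mark.parametrize("n", [16, 33, 64])
    def test_matches_brute_force(self, n, rng):
        x = rng.normal(size=n)
        acf = sc.autocorrelation(make_profile(x))
        np.testing.assert_allclose(acf.r, brute_force_acf(x, n // 2),
                                   rtol=1e-9, atol=1e-9)

    def test_lag_zero_is_one_and_bounded(self, rng):
        acf = sc.autocorrelation(make_profile(rng.normal(size=50)))
        assert acf.r[0] == pytest.approx(1.0)
        assert np.all(np.abs(acf.r) <= 1 + 1e-12)

    def test_cosine_peaks_at_multiples_of_period(self):
        n, period = 240, 40
        x = np.cos(2 * np.pi * np.arange(n) / period)
        acf = sc.autocorrelation(make_profile(x))
        for mult in (1, 2):
            lo, hi = mult * period - 3, mult * period + 3
            window = acf.r[lo : hi + 1]
            assert np.argmax(window) + lo == pytest.approx(mult * period,
                                                           abs=1)

    def test_zero_variance_signalled(self):
        with pytest.raises(ZeroDivisionError):
            sc.autocorrelation(make_profile(np.full(20, 4.0)))


class TestBootstrapThreshold:
    def test_seed_determinism(self, rng):
        prof = make_profile(rng.normal(size=60))
        t1 = sc.bootstrap_acf_threshold(prof, n_boot=200, seed=9)
        t2 = sc.bootstrap_acf_threshold(prof, n_boot=200, seed=9)
        np.testing.assert_array_equal(t1, t2)

    def test_threshold_decreases_with_alpha(self, rng):
        prof = make_profile(rng.normal(size=60))
        t_strict = sc.bootstrap_acf_threshold(prof, n_boot=400, alpha=0.01,
                                              seed=3)
        t_loose = sc.bootstrap_acf_threshold(prof, n_boot=400, alpha=0.20,
                                             seed=3)
        assert np.all(t_loose[1:] <= t_strict[1:])

    def test_small_n_boot_warns(self, rng):
        prof = make_profile(rng.normal(size=30))
        with pytest.warns(UserWarning):
            sc.bootstrap_acf_threshold(prof, n_boot=50, seed=1)

    def test_white_noise_exceedance_calibration(self):
        """Per-lag exceedance of the alpha=0.05 envelope within [3%, 7%]."""
        exceed = total = 0
        for seed in range(100):
            prof = sc.gen_white_noise_profile(100, 1.0, 1.0, seed=5000 + seed)
            acf = sc.autocorrelation(prof)
            thr = sc.bootstrap_acf_threshold(prof, n_boot=200, alpha=0.05,
                                             seed=seed)
            exceed += int((acf.r[1:] > thr[1:]).sum())
            total += acf.r.size - 1
        assert 0.03 <= exceed / total <= 0.07


class TestAcfPeriod:
    def _acf_with_peaks(self, peak_lags, n=130):
        r = np.zeros(n)
        r[0] = 1.0
        for lag in peak_lags:
            r[lag] = 0.5
        return sc.AcfResult(
            lags_um=np.arange(n, dtype=float), r=r, spacing_um=1.0,
            threshold=np.full(n, 0.2),
        )

    def test_equally_spaced_peaks(self):
        est = sc.acf_period(self._acf_with_peaks([40, 80, 120]))
        assert est.period_um == pytest.approx(40.0)
        np.testing.assert_array_equal(est.significant_peak_lags_um,
                                      [40, 80, 120])

    def test_no_peak_above_threshold_gives_no_period(self, rng):
        acf = self._acf_with_peaks([40])
        acf.threshold = np.full(acf.r.size, 0.9)
        est = sc.acf_period(acf)
        assert est.period_um is None

    def test_threshold_required(self, rng):
        acf = sc.autocorrelation(make_profile(rng.normal(size=40)))
        with pytest.raises(ValueError):
            sc.acf_period(acf)


# --------------------------------------------------------------------------
# end-to-end pipeline


class TestPipeline:
    def test_synthetic_recovery_fft_and_acf(self, default_tissue, full_roi):
        image, truth = default_tissue
        cfg = sc.RunConfig(seed=42, n_boot=500)
        fft_est, acf_est = analyse_roi(image, full_roi(image), cfg)
        assert fft_est.period_um == pytest.approx(truth, rel=0.10)
        assert fft_est.significant
        assert acf_est.period_um == pytest.approx(truth, rel=0.15)

    def test_blur_flips_dominant_period_from_10_to_40(self):
        """Internuclear (10 µm) periodicity dominates the raw spectrum;
        the 3 µm blur suppresses it so the microcluster period wins."""
        img, truth = sc.gen_tissue_image(sc.TissueImageParams(seed=11))
        roi = sc.RoiBox(0, img.dv_extent_um, width_um=img.ab_extent_um)
        no_blur, _ = analyse_roi(img, roi, sc.RunConfig(sigma_um=0.0,
                                                        seed=11, n_boot=100))
        with_blur, _ = analyse_roi(img, roi, sc.RunConfig(seed=11,
                                                          n_boot=100))
        assert no_blur.period_um == pytest.approx(10.0, abs=1.0)
        assert with_blur.period_um == pytest.approx(truth, rel=0.10)

    def test_identical_rois_identical_estimates(self, default_tissue):
        image, _ = default_tissue
        roi = sc.RoiBox(0, image.dv_extent_um, width_um=image.ab_extent_um)
        table = sc.run_pipeline(image, [roi, roi],
                                sc.RunConfig(seed=1, n_boot=200))
        a = table[table.roi_id == 0].drop(columns="roi_id").reset_index(drop=True)
        b = table[table.roi_id == 1].drop(columns="roi_id").reset_index(drop=True)
        assert a.equals(b)

    def test_trend_invariance(self, full_roi):
        """Adding an order-<=4 polynomial trend moves the FFT estimate by
        less than one frequency bin."""
        params = sc.TissueImageParams(seed=3, trend_coeffs=(0,))
        img, truth = sc.gen_tissue_image(params)
        x = np.linspace(-1, 1, img.values.shape[0])
        trend = 2.0 * x**4 - 1.0 * x**3 + 0.5 * x**2 + x
        img2 = sc.ImageGrid(img.values + trend[:, None], img.pixel_um)
        cfg = sc.RunConfig(seed=3, n_boot=100)
        e1, _ = analyse_roi(img, full_roi(img), cfg)
        e2, _ = analyse_roi(img2, full_roi(img2), cfg)
        span = img.dv_extent_um
        k1, k2 = span / e1.period_um, span / e2.period_um
        assert abs(k1 - k2) <= 1.0

    def test_per_roi_failure_recorded_not_raised(self, default_tissue):
        image, _ = default_tissue
        good = sc.RoiBox(0, image.dv_extent_um, width_um=image.ab_extent_um)
        bad = sc.RoiBox(0, 2 * image.dv_extent_um)
        table = sc.run_pipeline(image, [bad, good],
                                sc.RunConfig(seed=1, n_boot=100))
        assert (table[table.roi_id == 0].error != "").all()
        assert (table[table.roi_id == 1].error == "").all()
        assert np.isfinite(table[table.roi_id == 1].period_um).all()


# --------------------------------------------------------------------------
# group comparison


class TestCompareGroups:
    def test_exact_enumeration_small_groups(self):
        assert sc.compare_groups([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        assert sc.compare_groups([5.0, 5.0], [5.0, 5.0]) == pytest.approx(1.0)

    def test_exact_matches_permutation_oracle(self, rng):
        a, b = rng.normal(size=5), rng.normal(0.8, 1.0, size=5)
        p_exact = _exact_mwu_two_tailed(a, b)
        # oracle: random permutation resampling of group labels
        pooled = np.concatenate([a, b])
        mu = len(a) * len(b) / 2
        obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        count = 0
        n_perm = 20000
        prng = np.random.default_rng(123)
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            u = sum(
                (x > y) + 0.5 * (x == y)
                for x in perm[:5] for y in perm[5:]
            )
            count += abs(u - mu) >= abs(obs - mu) - 1e-12
        assert p_exact == pytest.approx(count / n_perm, abs=0.01)

    def test_asymptotic_branch_used_for_large_groups(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(1.5, 1.0, size=15)
        p = sc.compare_groups(a, b)
        assert 0 <= p <= 1
        import scipy.stats

        expected = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert p == pytest.approx(expected)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            sc.compare_groups([], [1.0])


# --------------------------------------------------------------------------
# properties


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(min_value=16, max_value=80),
       st.integers(min_value=0, max_value=1000))
def test_acf_bounds_property(n, seed):
    """ACF normalisation holds for arbitrary noise profiles."""
    x = np.random.default_rng(seed).normal(size=max(n, 16))
    acf = sc.autocorrelation(sc.Profile1D(x, 1.0))
    assert acf.r[0] == pytest.approx(1.0)
    assert np.all(np.abs(acf.r) <= 1 + 1e-9)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=1000))
def test_periodogram_nonnegative_and_parseval(seed):
    x = np.random.default_rng(seed).normal(size=48)
    x -= x.mean()
    pg = sc.periodogram(sc.Profile1D(x, 1.0))
    assert np.all(pg.power >= 0)
    w = np.full(pg.m, 2.0)
    w[-1] = 1.0  # n even
    np.testing.assert_allclose((w * pg.power).sum(), 48 * x.var(), rtol=1e-6)
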