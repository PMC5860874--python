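"""Spectral analysis, two-peak model, shuffling, and correlations."""
import numpy as np
import pytest

from flygroom.rhythm import (ConstantSeriesError, PeakModelParams,
                             ShuffleRetryError, bootstrap_correlation_p,
                             dominant_period, fit_two_peak_model,
                             lomb_scargle, pearson_r, shuffle_experiment,
                             threshold_power, two_peak_template)
from flygroom.synthetic import generate_rhythmic_series


def series_values(period_h=24.0, days=4, amplitude=0.2, noise_sd=0.03, seed=0):
    s = generate_rhythmic_series(period_h, days, amplitude=amplitude,
                                 noise_sd=noise_sd, seed=seed)
    return s.fractions["activity"].to_numpy()


class TestThresholdPower:
    @pytest.mark.parametrize("p, n, expected", [
        (0.05, 1, 2.9957),
        (0.05, 100, 7.5756),
    ])
    def test_direct_evaluation(self, p, n, expected):
        assert threshold_power(p, n) == pytest.approx(expected, abs=1e-3)

    def test_stricter_p_gives_higher_threshold(self):
        for n in (1, 10, 500):
            assert threshold_power(0.01, n) > threshold_power(0.05, n)

    def test_rejects_p_outside_unit_interval(self):
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                threshold_power(bad, 10)


class TestLombScargle:
    def test_sinusoid_peak_at_true_period(self):
        pg = lomb_scargle(series_values(), 30.0)
        period, power, sig = dominant_period(pg)
        assert abs(period - 24.0) <= 0.5
        assert sig == 0.01

    def test_amplitude_scaling_leaves_normalized_power_unchanged(self):
        y = series_values(noise_sd=0.0)
        a = lomb_scargle(y, 30.0)
        b = lomb_scargle(2.0 * y, 30.0)
        assert np.allclose(a.power, b.power)

    def test_constant_series_flagged(self):
        with pytest.raises(ConstantSeriesError):
            lomb_scargle(np.full(192, 0.3), 30.0)

    def test_white_noise_rarely_beats_threshold(self):
        """Peak power stays below the p=0.05 threshold in >= 90% of seeds."""
        below = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = rng.normal(0.3, 0.05, size=192)
            pg = lomb_scargle(y, 30.0)
            if pg.power.max() <= pg.thresholds[0.05]:
                below += 1
        assert below >= 0.9 * n_seeds

    def test_mutant_period_ordering_recovered(self):
        """Short/wild-type/long rhythm periods are each recovered within
        half a bin-width, preserving their ordering."""
        recovered = []
        for period in (19.2, 24.0, 28.8):
            pg = lomb_scargle(series_values(period_h=period, seed=7), 30.0)
            est, _, sig = dominant_period(pg)
            assert abs(est - period) <= 0.5
            assert sig == 0.01
            recovered.append(est)
        assert recovered == sorted(recovered)

    def test_finer_bins_raise_peak_power_relative_to_threshold(self):
        """Peak power grows with the number of bins much faster than the
        (logarithmic) significance threshold."""
        margins = []
        for bin_min in (30.0, 5.0, 1.0):
            y = generate_rhythmic_series(24.0, days=2, bin_min=bin_min,
                                         amplitude=0.2, noise_sd=0.05,
                                         seed=11).fractions["activity"]
            pg = lomb_scargle(y.to_numpy(), bin_min)
            margins.append(pg.power.max() - pg.thresholds[0.05])
        assert margins[0] < margins[1] < margins[2]

    def test_tie_goes_to_lower_period(self):
        pg = lomb_scargle(series_values(), 30.0)
        pg.power[:] = 1.0  # force an all-way tie
        period, _, _ = dominant_period(pg, band_h=(16.0, 32.0))
        in_band = pg.period_h[(pg.period_h >= 16) & (pg.period_h <= 32)]
        assert period == pytest.approx(in_band.min())


class TestTwoPeakModel:
    TRUE = PeakModelParams(b_MD=0.6, b_MR=0.5, b_ER=0.7, b_ED=0.6,
                           T_0=24.0, T_M=5.0, T_E=4.0, H_M=1.0, H_E=0.7)

    def test_parameter_recovery_with_noise(self):
        t = np.arange(8 * 48) * 0.5  # 8 days of 30-min bins
        rng = np.random.default_rng(0)
        y = two_peak_template(t, self.TRUE)
        y = y + rng.normal(0.0, 0.05 * y.max(), size=y.shape)
        fit = fit_two_peak_model(y, 30.0)
        for name in ("b_MD", "b_MR", "b_ER", "b_ED", "H_M", "H_E"):
            true = getattr(self.TRUE, name)
            assert abs(getattr(fit, name) - true) <= 0.1 * abs(true) + 1e-9
        for name in ("T_0", "T_M", "T_E"):
            assert abs(getattr(fit, name) - getattr(self.TRUE, name)) <= 0.5

    def test_flat_series_flagged_degenerate(self):
        fit = fit_two_peak_model(np.zeros(192), 30.0)
        assert fit.degenerate

    def test_refit_of_fitted_curve_is_a_fixed_point(self):
        t = np.arange(8 * 48) * 0.5
        y = two_peak_template(t, self.TRUE)
        fit = fit_two_peak_model(y, 30.0, init=self.TRUE)
        refit = fit_two_peak_model(two_peak_template(t, fit), 30.0, init=fit)
        assert np.allclose(refit.as_array(), fit.as_array(), atol=1e-6)


class TestShuffle:
    def setup_method(self):
        self.g = series_values(amplitude=0.1, seed=1) * 0.2
        self.l = series_values(amplitude=0.15, seed=2) * 0.5
        self.w = np.clip(self.g + self.l + 0.2, 0, 1)

    def test_conservation_identity_exact(self):
        rand_g, mod_l, wake, _ = shuffle_experiment(
            self.g, self.l, self.w, mode="locomotion", seed=0)
        assert np.allclose(mod_l + rand_g, self.l + self.g,
                           rtol=0.0, atol=1e-12)
        assert wake is self.w or np.array_equal(wake, self.w)

    def test_modified_wake_stays_in_unit_interval(self):
        rand_g, loco, mod_w, _ = shuffle_experiment(
            self.g, self.l, self.w, mode="wake", seed=0)
        assert np.all((mod_w >= 0) & (mod_w <= 1))
        assert np.array_equal(loco, self.l)

    def test_identity_permutation_changes_nothing(self):
        ident = np.arange(len(self.g))
        rand_g, mod_l, _, _ = shuffle_experiment(
            self.g, self.l, self.w, mode="locomotion", permutation=ident)
        assert np.array_equal(rand_g, self.g)
        assert np.array_equal(mod_l, self.l)

    def test_invalid_fixed_permutation_reports_retry_failure(self):
        g = np.array([0.9, 0.0, 0.0, 0.0])
        w = np.array([0.95, 0.05, 0.05, 0.05])
        # swapping the large grooming bin drives modified wake below 0
        with pytest.raises(ShuffleRetryError):
            shuffle_experiment(g, w.copy(), w, mode="wake",
                               permutation=np.array([1, 0, 2, 3]))

    def test_randomized_grooming_loses_rhythm_companion_keeps_it(self):
        g = series_values(amplitude=0.2, seed=3) * 0.2
        l = series_values(amplitude=0.2, seed=4) * 0.5 + 0.2
        w = np.clip(g + l + 0.1, 0, 1)
        rand_g, mod_l, _, _ = shuffle_experiment(g, l, w,
                                                 mode="locomotion", seed=5)
        pg_rand = lomb_scargle(rand_g, 30.0)
        _, power_rand, sig_rand = dominant_period(pg_rand)
        pg_mod = lomb_scargle(mod_l, 30.0)
        _, _, sig_mod = dominant_period(pg_mod)
        assert sig_rand is None
        assert sig_mod is not None


class TestCorrelations:
    def test_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_four_point_longhand_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        # longhand: cov = E[(x-2.5)(y-2.5)] = 0.75, sd_x = sd_y = sqrt(1.25)
        assert pearson_r(x, y) == pytest.approx(0.75 / 1.25)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_perfect_correlation_hits_resolution_floor(self):
        x = np.arange(60.0)
        res = bootstrap_correlation_p(x, x, n_resamples=999, seed=0)
        assert res.p_boot == pytest.approx(1.0 / 1000.0)

    def test_fixed_seed_reproduces_p(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 40))
        a = bootstrap_correlation_p(x, y, n_resamples=2000, seed=9)
        b = bootstrap_correlation_p(x, y, n_resamples=2000, seed=9)
        assert a.p_boot == b.p_boot

    def test_null_p_values_roughly_uniform(self):
        """Independent x, y: p < 0.05 in about 5% of replicates."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            x, y = rng.normal(size=(2, 30))
            res = bootstrap_correlation_p(x, y, n_resamples=400, seed=i)
            if res.p_boot < 0.05:
                hits += 1
        assert hits / n_rep < 0.12
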