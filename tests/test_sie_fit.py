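import math
import warnings

import numpy as np
import pytest

from islesar import (
    MODEL_SPECS,
    InfeasibleThresholdError,
    ModelForm,
    SARDataset,
    SARParams,
    SearchSettings,
    fit_given_thresholds,
    log_likelihood,
    run_sie_analysis,
    search_thresholds,
    select_model,
    simulate_sar,
    SARSimConfig,
)
from islesar.sie_fit import (
    continuous_grid,
    search_one_threshold_continuous,
    search_one_threshold_discontinuous,
    search_two_thresholds,
    two_slope_candidates,
)

from conftest import REPTILE_LIKE_TRUTH, noisy_sar
import oracles


class TestFitGivenThresholds:
    def test_perfect_line_recovered(self):
        x = np.linspace(-1, 3, 25)
        ds = SARDataset.from_log_values(x, 0.4 + 0.25 * x)
        fit = fit_given_thresholds(MODEL_SPECS[ModelForm.POWER], ds)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.params.intercepts[0] == pytest.approx(0.4)
        assert fit.params.slopes[0] == pytest.approx(0.25)

    def test_two_slope_rss_matches_per_segment_oracle(self, rng):
        x = np.sort(rng.uniform(-1, 2, 8))
        y = rng.normal(0, 1, 8)
        ds = SARDataset.from_log_values(x, y)
        t1 = float(x[3])
        fit = fit_given_thresholds(MODEL_SPECS[ModelForm.TWO_SLOPE], ds, [t1])
        assert fit.rss == pytest.approx(oracles.segment_rss(x, y, [t1]), rel=1e-10)

    def test_left_horizontal_2_generative_identity(self):
        truth = SARParams((0.3, -0.5), (0.2, 0.6), (0.0, 1.5))
        ds = noisy_sar(ModelForm.LEFT_HORIZONTAL_2, truth, n=60, noise=0.0, seed=4)
        fit = fit_given_thresholds(
            MODEL_SPECS[ModelForm.LEFT_HORIZONTAL_2], ds, truth.thresholds
        )
        assert fit.rss < 1e-20

    @pytest.mark.parametrize("form", list(ModelForm))
    def test_segment_fits_beat_nothing_worse_than_oracle(self, form, rng):
        """Per-segment / hinge least squares equal the normal-equations
        oracle RSS for every form at fixed feasible thresholds."""
        x = np.sort(rng.uniform(-2, 3, 30))
        y = rng.normal(0.5, 0.4, 30)
        ds = SARDataset.from_log_values(x, y)
        t1, t2 = float(x[9]), float(x[19])
        spec = MODEL_SPECS[form]
        thr = [t1, t2][: spec.n_thresholds]
        fit = fit_given_thresholds(spec, ds, thr)
        if form in (ModelForm.POWER, ModelForm.TWO_SLOPE, ModelForm.THREE_SLOPE):
            expected = oracles.segment_rss(x, y, thr)
        elif form is ModelForm.LEFT_HORIZONTAL_1:
            expected = oracles.hinge_rss(x, y, t1)
        else:
            sel = x <= t2
            expected = oracles.hinge_rss(x[sel], y[sel], t1) + oracles.line_rss(
                x[~sel], y[~sel]
            )
        assert fit.rss == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_undersized_segment_raises(self):
        x = np.linspace(0, 1, 10)
        ds = SARDataset.from_log_values(x, x)
        with pytest.raises(InfeasibleThresholdError):
            fit_given_thresholds(MODEL_SPECS[ModelForm.TWO_SLOPE], ds, [float(x[0])])


class TestOneThresholdSearches:
    def test_grid_candidate_count(self):
        """20 points spanning exactly [0, 1] at step 0.001 -> 1001 candidates."""
        x = np.linspace(0.0, 1.0, 20)
        ds = SARDataset.from_log_values(x, x)
        fit = search_one_threshold_continuous(ds, SearchSettings())
        assert fit.n_candidates == 1001
        assert len(continuous_grid(0.0, 1.0, 0.001)) == 1001

    def test_continuous_recovery_within_one_step(self):
        truth = SARParams((0.2,), (0.35,), (1.0,))
        ds = noisy_sar(ModelForm.LEFT_HORIZONTAL_1, truth, n=80, noise=0.0, seed=7,
                       log_range=(-1.0, 3.0))
        fit = search_one_threshold_continuous(ds, SearchSettings())
        assert abs(fit.params.thresholds[0] - 1.0) <= 0.001 + 1e-9
        # the hinge cannot land exactly on the truth between grid points,
        # so only near-zero lack of fit remains
        assert fit.rss < 1e-5

    def test_continuous_search_equals_bruteforce(self, rng):
        x = np.sort(rng.uniform(0, 2, 50))
        y = 0.1 + 0.3 * np.maximum(0, x - 0.9) + rng.normal(0, 0.05, 50)
        ds = SARDataset.from_log_values(x, y)
        s = SearchSettings(grid_step=0.01)
        fit = search_one_threshold_continuous(ds, s)
        t_or, rss_or = oracles.brute_lh1(x, y, 0.01, s.min_segment_points)
        assert fit.params.thresholds[0] == pytest.approx(t_or, abs=1e-12)
        assert fit.rss == pytest.approx(rss_or, rel=1e-9)

    def test_discontinuous_candidates_are_distinct_areas(self):
        """10 islands over 4 distinct areas -> 3 candidate break points."""
        areas = [1.0, 1.0, 1.0, 10.0, 10.0, 100.0, 100.0, 100.0, 1000.0, 1000.0]
        ds = SARDataset.from_areas_richness(areas, [1] * 10)
        assert len(two_slope_candidates(ds)) == 3

    def test_discontinuous_recovery_noise_free(self, rng):
        x = np.sort(rng.uniform(-1, 2, 30))
        t_true = float(x[9])  # break between the 10th and 11th sorted points
        spec = MODEL_SPECS[ModelForm.TWO_SLOPE]
        truth = SARParams((0.1, -0.4), (0.05, 0.5), (t_true,))
        from islesar import evaluate_model

        ds = SARDataset.from_log_values(x, evaluate_model(spec, truth, x))
        fit = search_one_threshold_discontinuous(ds, SearchSettings())
        assert fit.params.thresholds[0] == pytest.approx(t_true)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_discontinuous_search_equals_bruteforce(self, rng):
        x = np.sort(rng.uniform(-1, 2, 35))
        y = rng.normal(0, 0.5, 35)
        ds = SARDataset.from_log_values(x, y)
        s = SearchSettings()
        fit = search_one_threshold_discontinuous(ds, s)
        t_or, rss_or = oracles.brute_two_slope(x, y, s.min_segment_points)
        assert fit.params.thresholds[0] == pytest.approx(t_or, abs=1e-12)
        assert fit.rss == pytest.approx(rss_or, rel=1e-9)


class TestTwoThresholdSearches:
    def test_three_slope_noise_free_recovery(self, rng):
        ds = noisy_sar(ModelForm.THREE_SLOPE, REPTILE_LIKE_TRUTH, n=200, noise=0.0,
                       seed=11, log_range=(-4.4, 5.0))
        fit = search_two_thresholds(ModelForm.THREE_SLOPE, ds, SearchSettings())
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        # recovered thresholds sit at the sampled islands bracketing truth
        t1, t2 = fit.params.thresholds
        assert abs(t1 - REPTILE_LIKE_TRUTH.thresholds[0]) < 0.2
        assert abs(t2 - REPTILE_LIKE_TRUTH.thresholds[1]) < 0.2

    def test_three_slope_equals_bruteforce(self, rng):
        x = np.sort(rng.uniform(-2, 3, 30))
        y = rng.normal(0, 0.4, 30)
        ds = SARDataset.from_log_values(x, y)
        s = SearchSettings()
        fit = search_two_thresholds(ModelForm.THREE_SLOPE, ds, s)
        (t1, t2), rss_or = oracles.brute_three_slope(x, y, s.min_segment_points)
        assert fit.params.thresholds == pytest.approx((t1, t2), abs=1e-12)
        assert fit.rss == pytest.approx(rss_or, rel=1e-9)

    def test_left_horizontal_2_equals_bruteforce(self, rng):
        x = np.sort(rng.uniform(0, 3, 30))
        y = 0.2 + 0.3 * np.maximum(0, x - 1.0) + rng.normal(0, 0.1, 30)
        ds = SARDataset.from_log_values(x, y)
        s = SearchSettings(grid_step=0.01)
        fit = search_two_thresholds(ModelForm.LEFT_HORIZONTAL_2, ds, s)
        (t1, t2), rss_or = oracles.brute_lh2(x, y, 0.01, s.min_segment_points)
        assert fit.params.thresholds == pytest.approx((t1, t2), abs=1e-12)
        assert fit.rss == pytest.approx(rss_or, rel=1e-9)

    def test_three_slope_never_worse_than_two_slope_when_splittable(self):
        """Adding a feasible third segment cannot increase the RSS."""
        mp = SearchSettings().min_segment_points
        for seed in range(20):
            ds = noisy_sar(
                ModelForm.TWO_SLOPE,
                SARParams((0.1, -0.3), (0.05, 0.4), (0.5,)),
                n=40,
                noise=0.1,
                seed=seed,
            )
            two = search_thresholds(ModelForm.TWO_SLOPE, ds)
            three = search_thresholds(ModelForm.THREE_SLOPE, ds)
            x = ds.log_area
            t = two.params.thresholds[0]
            sizes = (int((x <= t).sum()), int((x > t).sum()))
            if max(sizes) >= 2 * mp:
                assert three.rss <= two.rss + 1e-12

    def test_two_slope_never_worse_than_power(self):
        for seed in range(10):
            ds = noisy_sar(
                ModelForm.POWER, SARParams((0.3,), (0.25,)), n=40, noise=0.1, seed=seed
            )
            power = search_thresholds(ModelForm.POWER, ds)
            two = search_thresholds(ModelForm.TWO_SLOPE, ds)
            assert two.rss <= power.rss + 1e-12


class TestLikelihoodAndSelection:
    def test_closed_form_unit_variance(self):
        """rss = n gives logL = -(n/2)(ln 2pi + 1)."""
        n = 37
        assert log_likelihood(float(n), n) == pytest.approx(
            -(n / 2) * (math.log(2 * math.pi) + 1)
        )

    def test_direct_arithmetic(self):
        n, rss = 100, 1.0
        expected = -(n / 2) * (math.log(2 * math.pi) + math.log(rss / n) + 1)
        assert log_likelihood(rss, n) == pytest.approx(expected)

    def test_monotone_in_rss(self):
        assert log_likelihood(2.0, 50) < log_likelihood(1.0, 50)

    def test_zero_rss_floored_with_warning(self):
        with pytest.warns(RuntimeWarning):
            val = log_likelihood(0.0, 10)
        assert math.isfinite(val)

    def _fit(self, form, aic):
        spec = MODEL_SPECS[form]
        k = spec.n_coefficients + spec.n_thresholds + 1
        n_lines = spec.n_coefficients // 2
        params = SARParams(
            (0.0,) * n_lines,
            (0.0,) * n_lines,
            tuple(float(i) for i in range(spec.n_thresholds)),
        )
        from islesar.sie_fit import SARFit

        return SARFit(spec=spec, params=params, rss=1.0, n=10,
                      logL=(2 * k - aic) / 2, K=k, aic=aic)

    def test_equal_aic_gives_half_half(self):
        t = select_model([self._fit(ModelForm.POWER, 100.0),
                          self._fit(ModelForm.TWO_SLOPE, 100.0)])
        assert t.weight[ModelForm.POWER] == pytest.approx(0.5)
        assert t.weight[ModelForm.TWO_SLOPE] == pytest.approx(0.5)

    def test_delta_two_gives_documented_weights(self):
        t = select_model([self._fit(ModelForm.POWER, 100.0),
                          self._fit(ModelForm.TWO_SLOPE, 102.0)])
        assert t.weight[ModelForm.POWER] == pytest.approx(0.7311, abs=5e-5)
        assert t.weight[ModelForm.TWO_SLOPE] == pytest.approx(0.2689, abs=5e-5)

    def test_weights_sum_to_one_and_shift_invariant(self):
        fits = [self._fit(f, a) for f, a in
                [(ModelForm.POWER, 10.0), (ModelForm.TWO_SLOPE, 13.0),
                 (ModelForm.THREE_SLOPE, 20.0)]]
        t1 = select_model(fits)
        shifted = [self._fit(f.form, f.aic + 57.0) for f in fits]
        t2 = select_model(shifted)
        assert sum(t1.weight.values()) == pytest.approx(1.0, abs=1e-12)
        for form in t1.weight:
            assert t1.weight[form] == pytest.approx(t2.weight[form], abs=1e-10)
        assert t1.delta_aic[t1.best] == 0.0


class TestRunSIEAnalysis:
    def test_noise_free_power_data_selects_power(self):
        ds = noisy_sar(ModelForm.POWER, SARParams((0.357,), (0.151,)),
                       n=120, noise=0.0, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = run_sie_analysis(ds)
        assert table.best is ModelForm.POWER

    def test_noisy_three_slope_data_selects_three_slope(self):
        ds = simulate_sar(SARSimConfig(
            n_islands=500, true_form=ModelForm.THREE_SLOPE,
            true_params=REPTILE_LIKE_TRUTH, noise_sd=0.05, seed=5))
        table = run_sie_analysis(ds)
        assert table.best is ModelForm.THREE_SLOPE
        assert table.delta_aic[ModelForm.THREE_SLOPE] == 0.0

    def test_constant_response_prefers_lowest_k(self):
        """All forms fit a flat response perfectly; AIC then ranks by K."""
        x = np.linspace(0, 4, 40)
        ds = SARDataset.from_log_values(x, np.full(40, 0.5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = run_sie_analysis(ds)
        assert table.best is ModelForm.POWER
        for fit in table.fits.values():
            assert fit.rss == pytest.approx(0.0, abs=1e-12)
            assert all(abs(z) < 1e-9 for z in fit.params.slopes)

    def test_selection_table_shape(self):
        ds = noisy_sar(ModelForm.POWER, SARParams((0.3,), (0.2,)), n=60,
                       noise=0.1, seed=9)
        table = run_sie_analysis(ds)
        frame = table.to_frame()
        assert len(frame) == 5
        assert frame["delta_AIC"].min() == 0.0
        assert frame["weight"].sum() == pytest.approx(1.0, abs=1e-12)
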