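import numpy as np
import pytest

import thermokin as tk
from thermokin.errors import DegenerateFitError, FitWarning, InvalidArgumentError
from thermokin.fitting import (
    evaluate_fit,
    fit_arrhenius,
    fit_decay_rate,
    fit_rcem,
    fit_time_delay,
    fit_two_state,
    predict_survival_pct,
)


class TestFitDecayRate:
    def test_pure_exponential_recovered_exactly(self):
        t = np.array([0.0, 600.0, 1800.0, 3600.0])
        s = np.exp(-0.001 * t)
        est = fit_decay_rate(t, s, "free_intercept")
        assert est.rate_k == pytest.approx(0.001, rel=1e-6)
        assert est.shoulder_td == 0.0

    def test_shoulder_recovered_from_post_plateau_points(self):
        t = np.array([1000.0, 1500.0, 2500.0, 4000.0])
        s = np.exp(-0.001 * (t - 1000.0))
        est = fit_decay_rate(t, s, "free_intercept")
        assert est.rate_k == pytest.approx(0.001, rel=1e-9)
        assert est.shoulder_td == pytest.approx(1000.0, rel=1e-6)

    def test_hinge_uses_plateau_points_too(self):
        t = np.array([300.0, 600.0, 900.0, 1200.0, 1800.0, 2700.0])
        s = np.where(t <= 1200, 1.0, np.exp(-2e-4 * (t - 1200.0)))
        est = fit_decay_rate(t, s, "free_intercept")
        assert est.rate_k == pytest.approx(2e-4, rel=1e-6)
        assert est.shoulder_td == pytest.approx(1200.0, rel=1e-6)

    def test_through_origin_mode_forces_unit_start(self):
        t = np.array([600.0, 1800.0, 3600.0])
        s = np.exp(-0.001 * t)
        est = fit_decay_rate(t, s, "through_origin")
        assert est.rate_k == pytest.approx(0.001, rel=1e-9)
        assert est.shoulder_td == 0.0

    def test_constant_survival_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_decay_rate([0.0, 600.0, 1200.0], [0.8, 0.8, 0.8])

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_decay_rate([0.0, 600.0], [1.0, 0.5])

    def test_rising_survival_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_decay_rate([0.0, 600.0, 1200.0], [0.3, 0.6, 0.9])

    def test_detection_floor_points_are_censored(self):
        # late-time survivals below the clip floor must not flatten the slope
        t = np.array([180.0, 300.0, 600.0, 1200.0, 1800.0, 3600.0])
        s = np.exp(-0.007 * t)  # underflows the 1e-4 floor from ~1300 s on
        est = fit_decay_rate(t, s, "free_intercept")
        assert est.rate_k == pytest.approx(0.007, rel=1e-6)


class TestFitArrhenius:
    def test_noiseless_round_trip_from_published_rates(self, kpc_arrhenius):
        temps = [315.65, 317.15, 319.15, 323.15]
        ests = [tk.DecayRateEstimate(T, tk.rate_constant(kpc_arrhenius, T), 0.0, 1.0, 5)
                for T in temps]
        fitted, r2 = fit_arrhenius(ests)
        assert fitted.activation_energy == pytest.approx(383112.0, rel=1e-6)
        assert fitted.ln_frequency_factor == pytest.approx(137.63, rel=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_points_give_perfect_r_squared(self, kpc_arrhenius):
        ests = [tk.DecayRateEstimate(T, tk.rate_constant(kpc_arrhenius, T), 0.0, 1.0, 5)
                for T in (317.15, 321.15)]
        _, r2 = fit_arrhenius(ests)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_single_temperature_rejected(self, kpc_arrhenius):
        ests = [tk.DecayRateEstimate(317.15, 1e-3, 0.0, 1.0, 5)]
        with pytest.raises(InvalidArgumentError):
            fit_arrhenius(ests)

    def test_ols_slope_unbiased_under_lnk_noise(self, kpc_arrhenius):
        # Monte Carlo property of OLS: i.i.d. noise on ln k leaves the
        # expected slope (hence Ea) unbiased.
        rng = np.random.default_rng(42)
        temps = np.array([315.65, 317.15, 319.15, 323.15])
        true_lnk = np.log([tk.rate_constant(kpc_arrhenius, T) for T in temps])
        eas = []
        for _ in range(200):
            lnk = true_lnk + rng.normal(0, 0.1, temps.size)
            ests = [tk.DecayRateEstimate(T, float(np.exp(v)), 0.0, 1.0, 5)
                    for T, v in zip(temps, lnk)]
            eas.append(fit_arrhenius(ests)[0].activation_energy)
        assert np.mean(eas) == pytest.approx(383112.0, rel=0.01)


class TestFitTimeDelay:
    def test_exact_line_recovery_with_clamped_point_excluded(self):
        # two observed shoulders on the line t_d = 254920 - 800 T plus one
        # clamped-at-zero temperature that must be treated as censored
        ests = [tk.DecayRateEstimate(316.15, 1e-3, 2000.0, 1.0, 5),
                tk.DecayRateEstimate(317.15, 2e-3, 1200.0, 1.0, 5),
                tk.DecayRateEstimate(318.65, 4e-3, 0.0, 1.0, 5)]
        d = fit_time_delay(ests)
        assert d.slope_m == pytest.approx(800.0, rel=1e-9)
        assert d.intercept_b == pytest.approx(254920.0, rel=1e-9)

    def test_all_zero_delays_warn_and_return_no_delay(self):
        ests = [tk.DecayRateEstimate(T, 1e-3, 0.0, 1.0, 5) for T in (317.15, 319.15)]
        with pytest.warns(FitWarning):
            d = fit_time_delay(ests)
        assert (d.slope_m, d.intercept_b) == (0.0, 0.0)

    def test_censored_temperatures_bound_the_line(self):
        # noisy shoulders at two mild temperatures must not extrapolate a
        # long delay into a hotter temperature whose decay showed none
        ests = [tk.DecayRateEstimate(315.65, 2.4e-4, 2645.0, 0.9, 2),
                tk.DecayRateEstimate(317.15, 1.1e-3, 2264.0, 0.9, 2),
                tk.DecayRateEstimate(319.15, 1.2e-3, 0.0, 0.99, 8),
                tk.DecayRateEstimate(323.15, 7.0e-3, 0.0, 0.99, 5)]
        d = fit_time_delay(ests, censor_bound_s=180.0)
        assert d.intercept_b - d.slope_m * 319.15 <= 180.0 + 1e-9
        assert d.intercept_b - d.slope_m * 315.65 > 2000.0

    def test_satisfied_censoring_bound_leaves_ols_fit_untouched(self):
        ests = [tk.DecayRateEstimate(316.15, 1e-3, 2000.0, 1.0, 5),
                tk.DecayRateEstimate(317.15, 2e-3, 1200.0, 1.0, 5),
                tk.DecayRateEstimate(319.15, 4e-3, 0.0, 1.0, 8)]
        # exact line predicts t_d = -1600 < 0 at the censored temperature
        d = fit_time_delay(ests, censor_bound_s=180.0)
        assert d.slope_m == pytest.approx(800.0, rel=1e-9)
        assert d.intercept_b == pytest.approx(254920.0, rel=1e-9)

    def test_single_nonzero_delay_rejected(self):
        ests = [tk.DecayRateEstimate(316.15, 1e-3, 1500.0, 1.0, 5),
                tk.DecayRateEstimate(319.15, 2e-3, 0.0, 1.0, 5)]
        with pytest.raises(InvalidArgumentError):
            fit_time_delay(ests)


class TestFitTwoState:
    TRUTH = tk.TwoStateParams(alpha=0.005, beta=300.0, gamma=0.94)
    TEMPS = [315.65, 317.15, 319.15, 323.15]
    # durations keeping survival inside the logit clip range for TRUTH
    DURS = [60.0, 120.0, 300.0, 600.0, 900.0, 1080.0]

    def conditions(self):
        return [(T, t, tk.two_state_survival(t, T, self.TRUTH))
                for T in self.TEMPS for t in self.DURS]

    def test_noiseless_exact_recovery(self):
        params, report = fit_two_state(self.conditions())
        assert params.alpha == pytest.approx(self.TRUTH.alpha, rel=1e-9)
        assert params.beta == pytest.approx(self.TRUTH.beta, rel=1e-9)
        assert params.gamma == pytest.approx(self.TRUTH.gamma, rel=1e-9)
        assert report.rmse_pct == pytest.approx(0.0, abs=1e-6)

    def test_matches_explicit_normal_equations(self):
        conds = self.conditions()
        params, _ = fit_two_state(conds)
        arr = np.array(conds)
        X = np.column_stack([arr[:, 0], arr[:, 1], np.ones(len(arr))])
        c = np.clip(arr[:, 2], 1e-4, 1 - 1e-4)
        y = np.log(c / (1 - c))
        gamma, neg_alpha, neg_beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert params.gamma == pytest.approx(gamma, rel=1e-9)
        assert params.alpha == pytest.approx(-neg_alpha, rel=1e-9)
        assert params.beta == pytest.approx(-neg_beta, rel=1e-9)

    def test_half_survival_everywhere_gives_zero_coefficients(self):
        conds = [(T, t, 0.5) for T in (316.0, 320.0) for t in (100.0, 500.0)]
        params, _ = fit_two_state(conds)
        assert params.alpha == pytest.approx(0.0, abs=1e-12)
        assert params.beta == pytest.approx(0.0, abs=1e-9)
        assert params.gamma == pytest.approx(0.0, abs=1e-12)

    def test_saturated_observations_are_clipped_not_dropped(self):
        conds = self.conditions() + [(315.65, 10.0, 1.0)]
        _, report = fit_two_state(conds)
        assert len(report.residuals) == len(conds)

    def test_rank_deficient_design_rejected(self):
        conds = [(316.0, 100.0, 0.9), (316.0, 100.0, 0.8),
                 (316.0, 100.0, 0.7), (316.0, 100.0, 0.6)]
        with pytest.raises((DegenerateFitError, InvalidArgumentError)):
            fit_two_state(conds)


class TestFitRcem:
    def test_consistent_with_arrhenius_closed_form(self, kpc_arrhenius):
        temps = [317.15, 319.15, 321.15, 323.15]  # 44-50 degC
        ests = [tk.DecayRateEstimate(T, tk.rate_constant(kpc_arrhenius, T), 0.0, 1.0, 5)
                for T in temps]
        r = fit_rcem(ests)
        t_mid = 320.15
        closed = np.exp(-kpc_arrhenius.activation_energy
                        / (kpc_arrhenius.gas_constant * t_mid * (t_mid + 1)))
        assert r == pytest.approx(closed, rel=0.05)

    def test_two_temperatures_one_kelvin_apart_exact(self, kpc_arrhenius):
        k1 = tk.rate_constant(kpc_arrhenius, 320.15)
        k2 = tk.rate_constant(kpc_arrhenius, 321.15)
        ests = [tk.DecayRateEstimate(320.15, k1, 0.0, 1.0, 5),
                tk.DecayRateEstimate(321.15, k2, 0.0, 1.0, 5)]
        assert fit_rcem(ests) == pytest.approx(k1 / k2, rel=1e-9)

    def test_temperature_independent_rates_give_unity(self):
        ests = [tk.DecayRateEstimate(T, 1e-3, 0.0, 1.0, 5)
                for T in (317.15, 319.15, 323.15)]
        assert fit_rcem(ests) == pytest.approx(1.0, rel=1e-12)

    def test_below_break_temperatures_excluded(self, kpc_arrhenius):
        ests = [tk.DecayRateEstimate(T, tk.rate_constant(kpc_arrhenius, T), 0.0, 1.0, 5)
                for T in (313.15, 315.15)]
        with pytest.raises(InvalidArgumentError):
            fit_rcem(ests, above_break_only=True)


class TestEvaluateFit:
    def _dataset_from_predictions(self, params, offset_pct=0.0):
        rows = []
        # mild conditions keep predictions well above the offsets used below
        for T in (315.65, 317.15):
            for t in (300.0, 900.0, 1800.0):
                pred = predict_survival_pct("arrhenius", T, t, params)
                s = (pred - offset_pct) / 100.0
                rows.append({"cell_line": "KPC", "setpoint_K": T, "duration_s": t,
                             "recovery_h": 24.0, "well_1": s, "mean_survival": s})
        import pandas as pd
        return tk.ViabilityDataset(pd.DataFrame(rows))

    def test_perfect_predictions_give_zero_rmse(self, kpc_arrhenius):
        ds = self._dataset_from_predictions(kpc_arrhenius)
        fr = evaluate_fit(ds, "arrhenius", kpc_arrhenius)
        assert fr.rmse_pct == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_gives_that_rmse(self, kpc_arrhenius):
        ds = self._dataset_from_predictions(kpc_arrhenius, offset_pct=10.0)
        fr = evaluate_fit(ds, "arrhenius", kpc_arrhenius)
        assert fr.rmse_pct == pytest.approx(10.0, rel=1e-9)

    def test_invariant_to_condition_ordering(self, kpc_arrhenius):
        ds = self._dataset_from_predictions(kpc_arrhenius, offset_pct=5.0)
        shuffled = tk.ViabilityDataset(ds.df.sample(frac=1.0, random_state=1))
        a = evaluate_fit(ds, "arrhenius", kpc_arrhenius).rmse_pct
        b = evaluate_fit(shuffled, "arrhenius", kpc_arrhenius).rmse_pct
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_dataset_rejected(self, kpc_arrhenius):
        import pandas as pd
        with pytest.raises(InvalidArgumentError):
            evaluate_fit(pd.DataFrame(), "arrhenius", kpc_arrhenius)
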