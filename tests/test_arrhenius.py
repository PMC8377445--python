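"""Arrhenius regression, BIC selection, ANCOVA, traces, allometry."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from thermodev import (
    ArrheniusLinearRegression,
    ArrheniusQuadraticRegression,
    allometric_time_ratio,
    bic_compare,
    compare_slopes_ancova,
    duration_ratio,
    fit_linear,
    fit_quadratic,
    from_arrhenius_coords,
    generate_absorbance_trace,
    rate_from_absorbance,
    to_arrhenius_coords,
)
from thermodev.constants import R_J_PER_MOL_K


def arrhenius_rates(T_celsius, Ea_kJ, lnA, noise_sd=0.0, rng=None):
    T = np.asarray(T_celsius, dtype=float)
    lnk = lnA - Ea_kJ * 1000.0 / (R_J_PER_MOL_K * (T + 273.15))
    if noise_sd:
        lnk = lnk + rng.normal(0.0, noise_sd, size=T.shape)
    return np.exp(lnk)


class TestCoordinates:
    def test_reference_points(self):
        x, y = to_arrhenius_coords(25.0, 1.0)
        assert x == pytest.approx(1 / 298.15)
        assert y == 0.0
        x, y = to_arrhenius_coords(0.0, math.e)
        assert x == pytest.approx(1 / 273.15)
        assert y == pytest.approx(1.0)

    def test_round_trip(self):
        T = np.array([5.0, 20.0, 37.5])
        r = np.array([0.01, 1.3, 250.0])
        T2, r2 = from_arrhenius_coords(*to_arrhenius_coords(T, r))
        assert np.allclose(T2, T, atol=1e-12)
        assert np.allclose(r2, r, rtol=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            to_arrhenius_coords(20.0, 0.0)


class TestLinearRegression:
    def test_exact_recovery(self, arrhenius_points):
        T, rate = arrhenius_points
        fit = fit_linear(T, rate)
        assert fit.Ea_kJ_per_mol == pytest.approx(64.0, abs=1e-9)
        assert fit.intercept == pytest.approx(5.0, abs=1e-9)
        assert fit.ci68_Ea_kJ_per_mol == pytest.approx(0.0, abs=1e-9)

    def test_core_range_restriction(self, arrhenius_points):
        T, rate = arrhenius_points
        fit = fit_linear(T, rate, core_range_C=(14.3, 27.0))
        assert fit.n == int(((T >= 14.3) & (T <= 27.0)).sum())
        assert fit.Ea_kJ_per_mol == pytest.approx(64.0, abs=1e-9)

    def test_two_points_define_line_without_ci(self):
        fit = fit_linear([15.0, 25.0], arrhenius_rates([15.0, 25.0], 70.0, 8.0))
        assert fit.Ea_kJ_per_mol == pytest.approx(70.0, abs=1e-9)
        assert fit.ci68_Ea_kJ_per_mol is None

    def test_single_point_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_linear([20.0], [1.0])

    def test_zero_x_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            fit_linear([20.0, 20.0, 20.0], [1.0, 1.1, 0.9])

    def test_se_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        T = np.linspace(12, 30, 40)
        rate = arrhenius_rates(T, 64.0, 5.0, noise_sd=0.1, rng=rng)
        est = ArrheniusLinearRegression().fit(T, rate)
        x, y = to_arrhenius_coords(T, rate)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert est.slope_ == pytest.approx(ref.params[1], rel=1e-9)
        se_Ea_ref = ref.bse[1] * R_J_PER_MOL_K / 1000.0
        assert est.se_Ea_ == pytest.approx(se_Ea_ref, rel=1e-9)

    def test_ea_invariant_under_rate_rescaling(self, arrhenius_points):
        T, rate = arrhenius_points
        f1 = fit_linear(T, rate)
        f2 = fit_linear(T, 17.3 * rate)
        assert f2.Ea_kJ_per_mol == pytest.approx(f1.Ea_kJ_per_mol, abs=1e-9)
        assert f2.intercept - f1.intercept == pytest.approx(math.log(17.3))

    def test_sklearn_params_round_trip(self):
        est = ArrheniusLinearRegression(core_range_C=(14.3, 27.0))
        assert est.get_params() == {"core_range_C": (14.3, 27.0)}
        est.set_params(core_range_C=None)
        assert est.core_range_C is None

    def test_predict_inverts_fit(self, arrhenius_points):
        T, rate = arrhenius_points
        est = ArrheniusLinearRegression().fit(T, rate)
        assert np.allclose(est.predict(T), rate, rtol=1e-9)


class TestQuadraticRegression:
    def test_exact_parabola_recovered(self):
        T = np.linspace(5, 45, 12)
        x = 1 / (T + 273.15)
        c2, c1, c0 = -2.0e7, 1.35e5, -227.808
        rate = np.exp(c2 * x**2 + c1 * x + c0)
        q = fit_quadratic(T, rate)
        assert q.c2 == pytest.approx(c2, rel=1e-9)
        assert q.c1 == pytest.approx(c1, rel=1e-9)
        assert q.c0 == pytest.approx(c0, rel=1e-9)
        assert q.concavity == "downward"

    def test_linear_data_gives_zero_curvature_term(self, arrhenius_points):
        T, rate = arrhenius_points
        q = fit_quadratic(T, rate)
        # c2 ~ 0 relative to the scale c2*x^2 contributes to ln k
        x = 1 / (T + 273.15)
        assert abs(q.c2) * x.max() ** 2 < 1e-6

    def test_concave_down_generator_truth(self):
        rng = np.random.default_rng(11)
        T = np.linspace(8, 40, 30)
        x = 1 / (T + 273.15)
        lnk = -3.0e7 * x**2 + 2.0e5 * x - 333.312 + rng.normal(0, 0.02, T.size)
        q = fit_quadratic(T, np.exp(lnk))
        assert q.concavity == "downward"

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_quadratic([10.0, 20.0, 30.0], [1.0, 2.0, 3.0])

    def test_rank_deficiency(self):
        with pytest.raises(ValueError, match="deficient"):
            fit_quadratic([10.0, 10.0, 20.0, 20.0], [1.0, 1.0, 2.0, 2.0])


class TestBicCompare:
    def test_exactly_linear_penalty_rule(self, arrhenius_points):
        T, rate = arrhenius_points
        T20 = np.concatenate([T, T + 0.5, T[:4] + 0.25])
        rate20 = arrhenius_rates(T20, 64.0, 5.0)
        assert T20.size == 20
        m = bic_compare(T20, rate20)
        assert m.log_ratio == pytest.approx(-math.log(20) / 2)
        assert m.preferred == "linear"

    def test_strong_curvature_prefers_quadratic(self):
        T = np.linspace(5, 45, 24)
        x = 1 / (T + 273.15)
        rate = np.exp(-3.0e7 * x**2 + 2.0e5 * x - 333.312)
        m = bic_compare(T, rate)
        assert m.preferred == "quadratic"
        assert m.log_ratio > 10

    def test_simulated_concave_data_selection_rate(self):
        """Quadratic preferred in >= 95% of noisy concave-truth replicates."""
        rng = np.random.default_rng(2024)
        T = np.linspace(8, 40, 40)
        x = 1 / (T + 273.15)
        lnk_true = -2.0e7 * x**2 + 1.35e5 * x - 227.808
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            lnk = lnk_true + rng.normal(0.0, 0.05, T.size)
            if bic_compare(T, np.exp(lnk)).preferred == "quadratic":
                wins += 1
        assert wins / n_rep >= 0.95

    def test_matches_direct_bic_formula(self):
        rng = np.random.default_rng(5)
        T = np.linspace(10, 35, 15)
        rate = arrhenius_rates(T, 64.0, 5.0, noise_sd=0.05, rng=rng)
        m = bic_compare(T, rate)
        x, y = to_arrhenius_coords(T, rate)
        n = T.size
        rss1 = np.sum((y - np.polyval(np.polyfit(x, y, 1), x)) ** 2)
        rss2 = np.sum((y - np.polyval(np.polyfit(x, y, 2), x)) ** 2)
        bic1 = n * math.log(rss1 / n) + 2 * math.log(n)
        bic2 = n * math.log(rss2 / n) + 3 * math.log(n)
        assert m.log_ratio == pytest.approx((bic1 - bic2) / 2, rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 5"):
            bic_compare([10, 15, 20, 25], [1, 2, 3, 4])


class TestAncova:
    def test_identical_groups_null(self):
        T = np.linspace(14, 27, 10)
        rate = arrhenius_rates(T, 60.0, 5.0)
        rng = np.random.default_rng(0)
        noisy = rate * np.exp(rng.normal(0, 0.05, T.size))
        res = compare_slopes_ancova(T, noisy, T, noisy)
        assert res.F == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_matches_statsmodels_interaction_test(self):
        rng = np.random.default_rng(9)
        T = np.linspace(14, 27, 25)
        ra = arrhenius_rates(T, 56.0, 4.0, noise_sd=0.08, rng=rng)
        rb = arrhenius_rates(T, 84.0, 15.0, noise_sd=0.08, rng=rng)
        res = compare_slopes_ancova(T, ra, T, rb)
        xa, ya = to_arrhenius_coords(T, ra)
        xb, yb = to_arrhenius_coords(T, rb)
        x = np.concatenate([xa, xb])
        y = np.concatenate([ya, yb])
        g = np.repeat([0.0, 1.0], T.size)
        X = sm.add_constant(np.column_stack([x, g, x * g]))
        full = sm.OLS(y, X).fit()
        t_int = full.tvalues[3]
        assert res.F == pytest.approx(t_int**2, rel=1e-8)
        assert res.p == pytest.approx(full.pvalues[3], rel=1e-8)

    def test_distinct_slopes_detected_with_power(self):
        rng = np.random.default_rng(12)
        T = np.repeat(np.linspace(14.5, 26.5, 11), 6)
        ra = arrhenius_rates(T, 56.0, 18.0, noise_sd=0.06, rng=rng)
        rb = arrhenius_rates(T, 84.0, 29.0, noise_sd=0.06, rng=rng)
        res = compare_slopes_ancova(T, ra, T, rb, core_range_C=(14.3, 27.0))
        assert res.p < 1e-6
        assert res.power > 0.95

    def test_power_is_noncentral_f_tail(self):
        rng = np.random.default_rng(4)
        T = np.linspace(14, 27, 12)
        ra = arrhenius_rates(T, 60.0, 5.0, noise_sd=0.1, rng=rng)
        rb = arrhenius_rates(T, 75.0, 10.0, noise_sd=0.1, rng=rng)
        res = compare_slopes_ancova(T, ra, T, rb)
        crit = stats.f.ppf(0.95, 1, res.df_den)
        assert res.power == pytest.approx(stats.ncf.sf(crit, 1, res.df_den, res.F))

    def test_type_one_error_calibration(self):
        """Equal-slope simulations reject at ~alpha (2000 replicates)."""
        rng = np.random.default_rng(77)
        T = np.linspace(14, 27, 12)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            ra = arrhenius_rates(T, 64.0, 5.0, noise_sd=0.08, rng=rng)
            rb = arrhenius_rates(T, 64.0, 5.5, noise_sd=0.08, rng=rng)
            if compare_slopes_ancova(T, ra, T, rb).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_slopes_ancova([14, 27], [1, 2], [14, 20, 27], [1, 2, 3])


class TestAbsorbanceRate:
    def test_exact_line(self):
        t = np.arange(0, 6, 1 / 60)
        a = 0.02 * t + 0.1
        assert rate_from_absorbance(t, a, (1.5, 4.5)) == pytest.approx(0.02)

    def test_constant_trace(self):
        t = np.arange(0, 6, 1 / 60)
        assert rate_from_absorbance(t, np.full_like(t, 0.3), (1.5, 4.5)) == \
            pytest.approx(0.0, abs=1e-15)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="window"):
            rate_from_absorbance([0.0, 1.0], [0.0, 1.0], (5.0, 6.0))

    def test_noisy_trace_recovery_within_3se(self):
        trace = generate_absorbance_trace(
            0.015, intercept_AU=0.1, duration_min=5.0, sampling_s=1.0,
            noise_sd=1e-3, seed=8,
        )
        slope = rate_from_absorbance(trace["time_min"], trace["absorbance"],
                                     (1.5, 4.5))
        mask = (trace["time_min"] >= 1.5) & (trace["time_min"] <= 4.5)
        t = trace["time_min"][mask].to_numpy()
        se = 1e-3 / math.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(slope - 0.015) < 3 * se


class TestAllometry:
    def test_frog_fly_mass_ratio_prediction(self):
        assert allometric_time_ratio(25.0, 0.67) == pytest.approx(2.47, abs=0.01)

    def test_equal_masses(self):
        assert allometric_time_ratio(3.0, 3.0) == 1.0

    def test_fourth_root(self):
        assert allometric_time_ratio(16.0, 1.0) == pytest.approx(2.0)

    def test_nonpositive_mass(self):
        with pytest.raises(ValueError):
            allometric_time_ratio(0.0, 1.0)

    def test_duration_ratio(self):
        assert duration_ratio(26.0, 17.0) == pytest.approx(1.5, abs=0.05)
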