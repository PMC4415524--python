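"""Thermal screen: Pearson, nested-model F-tests, Arrhenius, limit detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from thermoembryo import (C_BRIGGSAE, C_ELEGANS, FeatureResponseSpec,
                          arrhenius_fit, arrhenius_r2, classify_feature,
                          detect_limits, fit_within_range, ftest_beyond_limit,
                          gen_feature_table, gen_respiration, gen_viability,
                          pearson_screen, respiration_departure)
from thermoembryo.thermal import _nested_f

RANGE = (12.0, 25.0)
ELEGANS_TEMPS = [7.5] + list(np.arange(8.0, 28.0))


def _tidy(T, y, feature="f"):
    return pd.DataFrame({"feature": feature, "temperature": T, "value": y})


class TestPearsonScreen:
    def test_bonferroni_threshold_exact(self):
        res = pearson_screen(_tidy([12, 16, 20, 24], [1, 2, 3, 4]), RANGE,
                             M=35, family_alpha=0.05)
        assert res[0].bonferroni_threshold == 0.05 / 35

    def test_perfect_linear_r(self):
        res = pearson_screen(_tidy([12, 16, 20, 24], [1, 2, 3, 4]), RANGE, M=1)
        assert res[0].pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_r(self):
        # r = 14 / sqrt(80 * 2.75) from the covariance/variance sums
        res = pearson_screen(_tidy([12, 16, 20, 24], [1, 2, 3, 3]), RANGE, M=1)
        assert res[0].pearson_r == pytest.approx(14.0 / np.sqrt(80 * 2.75), abs=1e-9)

    def test_constant_feature_independent(self):
        res = pearson_screen(_tidy([12, 16, 20, 24], [5, 5, 5, 5]), RANGE, M=35)
        assert res[0].pearson_r == 0.0
        assert not res[0].temperature_dependent

    def test_too_few_observations_untestable(self):
        res = pearson_screen(_tidy([14, 20], [1, 2]), RANGE, M=35)
        assert res[0].untestable


class TestWithinRangeModel:
    def test_independent_constant(self):
        kind, (y0, alpha), rss = fit_within_range([12, 16, 20], [5, 5, 5],
                                                  dependent=False)
        assert (kind, y0, alpha) == ("constant", 5.0, 0.0)
        assert rss == 0.0

    def test_exact_exponential_selected(self):
        T = np.arange(12.0, 26.0)
        y = 3.0 * np.exp(-0.08 * T)
        kind, (y0, alpha), rss = fit_within_range(T, y, dependent=True)
        assert kind == "exponential"
        assert alpha == pytest.approx(-0.08, abs=1e-9)
        assert rss < 1e-12

    def test_exact_linear_selected(self):
        T = np.arange(12.0, 26.0)
        kind, (y0, alpha), rss = fit_within_range(T, 2.0 + 0.5 * T, dependent=True)
        assert kind == "linear"
        assert rss < 1e-18


class TestNestedF:
    def test_formula_arithmetic(self):
        F, p = _nested_f(rss1=10.0, rss2=5.0, p1=2, p2=3, n=13)
        assert F == pytest.approx(10.0, abs=1e-12)

    def test_p_matches_squared_t_relation(self):
        # F(1, m) is the square of a central t with m df
        _, p = _nested_f(rss1=10.0, rss2=5.0, p1=2, p2=3, n=13)
        assert p == pytest.approx(2 * stats.t.sf(np.sqrt(10.0), 10), rel=1e-9)
        assert p == pytest.approx(0.0102, abs=2e-4)

    def test_constant_case_equals_squared_two_sample_t(self):
        # all beyond observations at one temperature -> the hinge model is the
        # two-group means model, so F equals the pooled two-sample t squared
        rng = np.random.default_rng(8)
        T = np.array([13.0, 16, 19, 22, 24, 27, 27, 27, 27])
        y = rng.normal(0, 1, T.size)
        y[T >= 27] += 1.0
        fit = ftest_beyond_limit(T, y, RANGE, "upper", dependent=False)
        t_stat, t_p = stats.ttest_ind(y[T < 27], y[T >= 27])
        assert fit.F == pytest.approx(t_stat**2, rel=1e-9)
        assert fit.p_value == pytest.approx(t_p, rel=1e-9)

    def test_linear_case_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(12)
        T = np.concatenate([np.arange(12.0, 26.0), [26, 27, 28]])
        y = 1.0 + 0.3 * T + rng.normal(0, 0.5, T.size)
        fit = ftest_beyond_limit(T, y, RANGE, "upper", dependent=True,
                                 within_kind="linear")
        hinge = (T - 25.0) * (T >= 25.0)
        m1 = sm.OLS(y, sm.add_constant(T)).fit()
        m2 = sm.OLS(y, sm.add_constant(np.column_stack([T, hinge]))).fit()
        F_sm, p_sm, _ = m2.compare_f_test(m1)
        assert fit.F == pytest.approx(F_sm, rel=1e-9)
        assert fit.p_value == pytest.approx(p_sm, rel=1e-9)

    def test_beta_recovered_exactly_without_noise(self):
        spec = FeatureResponseSpec(kind="constant", y0=10.0, beta_upper=-1.0,
                                   limits=RANGE)
        table = gen_feature_table({"f": spec}, list(np.arange(12.0, 26.0))
                                  + [26.0, 27.0, 28.0], 1, seed=0)
        fit = ftest_beyond_limit(table["temperature"], table["value"], RANGE,
                                 "upper", dependent=False)
        assert fit.beta == pytest.approx(-1.0, abs=1e-9)
        assert fit.changed

    def test_lower_side_sign_convention(self):
        spec = FeatureResponseSpec(kind="constant", y0=10.0, beta_lower=2.0,
                                   limits=RANGE)
        table = gen_feature_table({"f": spec}, [9.0, 10.0, 11.0]
                                  + list(np.arange(12.0, 26.0)), 1, seed=0)
        fit = ftest_beyond_limit(table["temperature"], table["value"], RANGE,
                                 "lower", dependent=False)
        assert fit.beta == pytest.approx(2.0, abs=1e-9)

    def test_nesting_invariants_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            T = np.concatenate([np.arange(12.0, 26.0), [26, 27, 28]])
            y = rng.normal(0, 1, T.size)
            fit = ftest_beyond_limit(T, y, RANGE, "upper", dependent=False)
            assert fit.rss2 <= fit.rss1 + 1e-12
            assert fit.F >= 0
            assert 0 < fit.p_value <= 1

    def test_power_monotone_in_beta(self):
        T = np.concatenate([np.arange(12.0, 26.0), [26, 27, 28]])
        rates = []
        for beta in (0.5, 1.0, 2.0):
            rng = np.random.default_rng(77)
            hits = 0
            for _ in range(500):
                y = rng.normal(0, 1, T.size) - beta * (T - 25.0) * (T >= 25.0)
                if ftest_beyond_limit(T, y, RANGE, "upper",
                                      dependent=False).p_value < 0.05:
                    hits += 1
            rates.append(hits / 500)
        assert rates == sorted(rates)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ftest_beyond_limit([20.0, 22.0], [1.0, 2.0], RANGE, "upper",
                               dependent=False)


class TestClassifyFeature:
    def test_constant_with_upper_break(self):
        spec = FeatureResponseSpec(kind="constant", y0=57.4, beta_upper=-2.0,
                                   sigma=0.05, limits=RANGE)
        table = gen_feature_table({"f": spec}, list(np.arange(12.0, 26.0))
                                  + [26, 27, 28] + [9, 10, 11], 3, seed=4)
        rep = classify_feature(table["temperature"], table["value"], RANGE, M=35)
        assert not rep.screen.temperature_dependent
        assert rep.upper.changed
        assert not rep.lower.changed

    def test_exponential_no_break(self):
        spec = FeatureResponseSpec(kind="exponential", y0=3.0, alpha=-0.06,
                                   sigma=0.001, limits=RANGE)
        table = gen_feature_table({"f": spec}, [9, 10, 11]
                                  + list(np.arange(12.0, 26.0)) + [26, 27, 28],
                                  3, seed=9)
        rep = classify_feature(table["temperature"], table["value"], RANGE, M=35)
        assert rep.screen.temperature_dependent
        assert rep.within_kind == "exponential"
        assert not rep.upper.changed
        assert not rep.lower.changed

    def test_all_missing_untestable(self):
        rep = classify_feature([14.0, 20.0], [np.nan, np.nan], RANGE, M=35)
        assert rep.untestable


class TestArrhenius:
    def test_constant_durations_zero_energy(self):
        fit = arrhenius_fit(np.arange(12.0, 26.0), np.full(14, 100.0))
        assert fit.E == pytest.approx(0.0, abs=1e-12)

    def test_plateau_lowers_explained_variance(self):
        T_in = np.arange(12.0, 26.0)
        kB = 8.617333e-5
        d_in = 2.0 * np.exp(0.65 / (kB * (T_in + 273.15)))
        fit = arrhenius_fit(T_in, d_in, range_=RANGE)
        assert fit.r2_percent == pytest.approx(100.0, abs=1e-6)
        T_all = np.concatenate([T_in, [26.0, 27.0, 28.0]])
        d_all = np.concatenate([d_in, np.full(3, d_in[-1])])  # plateau beyond
        assert arrhenius_r2(fit, T_all, d_all) < fit.r2_percent

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_fit([15.0, 20.0], [10.0, -1.0])


class TestDetectLimits:
    def test_elegans_preset(self):
        via = gen_viability(C_ELEGANS, ELEGANS_TEMPS, noise=False)
        limits = detect_limits(via)
        assert (limits.lower, limits.upper) == (12.0, 25.0)

    def test_briggsae_preset(self):
        via = gen_viability(C_BRIGGSAE, np.arange(9.0, 31.0), noise=False)
        limits = detect_limits(via)
        assert (limits.lower, limits.upper) == (14.0, 27.0)

    def test_all_viable_warns_unbounded(self):
        df = pd.DataFrame({"temperature": [15.0, 20.0, 25.0],
                           "fraction": [0.95, 0.96, 0.95]})
        with pytest.warns(UserWarning, match="unbounded"):
            limits = detect_limits(df)
        assert (limits.lower, limits.upper) == (15.0, 25.0)

    def test_single_viable_degenerate(self):
        df = pd.DataFrame({"temperature": [15.0, 20.0, 25.0],
                           "fraction": [0.5, 0.95, 0.5]})
        with pytest.warns(UserWarning, match="degenerate"):
            limits = detect_limits(df)
        assert (limits.lower, limits.upper) == (20.0, 20.0)

    def test_no_viable_range_raises(self):
        df = pd.DataFrame({"temperature": [15.0, 20.0], "fraction": [0.1, 0.2]})
        with pytest.raises(ValueError, match="no viable range"):
            detect_limits(df)

    def test_tie_broken_toward_20(self):
        df = pd.DataFrame({"temperature": [10, 11, 12, 15, 19, 20, 21],
                           "fraction": [0.95, 0.95, 0.95, 0.1, 0.95, 0.95, 0.95]})
        limits = detect_limits(df)
        assert (limits.lower, limits.upper) == (19.0, 21.0)

    @given(st.lists(st.booleans(), min_size=2, max_size=20))
    def test_returned_limits_are_tested_temperatures(self, pattern):
        T = np.arange(len(pattern), dtype=float) + 5.0
        frac = np.where(pattern, 0.95, 0.5)
        df = pd.DataFrame({"temperature": T, "fraction": frac})
        if not any(pattern):
            with pytest.raises(ValueError):
                detect_limits(df)
            return
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            limits = detect_limits(df)
        assert limits.lower in T and limits.upper in T
        assert limits.lower <= limits.upper
        covered = (T >= limits.lower) & (T <= limits.upper)
        assert np.all(frac[covered] > 0.9)


class TestRespirationDeparture:
    def test_upper_departure_detected(self):
        resp = gen_respiration(E=0.65, prefactor=2.0, temps=np.arange(9.0, 29.0),
                               range_=(12.0, 24.0), dev_lower=0.0, dev_upper=-0.2,
                               sigma=0.005, seed=2)
        out = respiration_departure(resp, (12.0, 24.0))
        assert out["upper"].changed
        assert out["upper"].beta < 0
        assert not out["lower"].changed

    def test_exact_data_no_departure(self):
        resp = gen_respiration(E=0.65, prefactor=2.0, temps=np.arange(9.0, 29.0),
                               range_=(12.0, 24.0))
        out = respiration_departure(resp, (12.0, 24.0))
        for side in ("lower", "upper"):
            assert out[side].F == pytest.approx(0.0, abs=1e-6)
            assert not out[side].changed

    def test_single_beyond_point_algebra(self):
        # 5-point toy: 3 exact Arrhenius points within range, one deviating
        # point on each side; the hinge model absorbs the deviation exactly
        resp = gen_respiration(E=0.65, prefactor=2.0,
                               temps=[10.0, 14.0, 18.0, 22.0, 26.0],
                               range_=(12.0, 24.0), dev_lower=0.3, dev_upper=-0.3)
        out = respiration_departure(resp, (12.0, 24.0))
        for side in ("lower", "upper"):
            assert out[side].rss1 > 1e-6
            assert out[side].rss2 < 1e-18
            assert out[side].p_value < 0.0014
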