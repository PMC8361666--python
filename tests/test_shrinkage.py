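"""Shrinkage estimates, the three variance formulae, and their identities."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metablup import (
    StudySet,
    blup_decomposition_terms,
    blup_estimates,
    fit_random_effects,
    shrinkage_factors,
    study_prediction_intervals,
    variance_crude,
    variance_quan,
    variance_raudenbush,
)
from metablup.shrinkage import ZeroTau2Warning

from conftest import study_sets

Z975 = 1.959964


class TestShrinkageFactors:
    @pytest.mark.parametrize(
        "v, tau2, expected",
        [(0.5, 0.0, 1.0), (0.5, 0.5, 0.5), (0.25, 0.75, 0.25)],
    )
    def test_direct_ratios(self, v, tau2, expected):
        data = StudySet(y=[0.0], v=[v])
        assert shrinkage_factors(data, tau2)[0] == pytest.approx(expected)

    @given(study_sets(), st.floats(0.0, 50.0))
    def test_bounded_in_unit_interval(self, data, tau2):
        b = shrinkage_factors(data, tau2)
        assert np.all((b >= 0.0) & (b <= 1.0))


class TestBlupEstimates:
    def test_full_shrinkage_at_zero_tau2(self, toy_five):
        fit = fit_random_effects(toy_five, 0.0)
        theta_i, gamma_i = blup_estimates(toy_five, fit)
        np.testing.assert_allclose(theta_i, fit.theta_hat)
        np.testing.assert_allclose(gamma_i, 0.0)

    def test_hand_worked_convex_combination(self):
        data = StudySet(y=[0.0, 1.0], v=[0.5, 0.5])
        fit = fit_random_effects(data, 0.5)
        theta_i, gamma_i = blup_estimates(data, fit)
        np.testing.assert_allclose(theta_i, [0.25, 0.75])
        np.testing.assert_allclose(gamma_i, [-0.25, 0.25])

    @given(study_sets(), st.floats(0.0, 20.0))
    def test_lies_between_study_and_pooled_estimate(self, data, tau2):
        fit = fit_random_effects(data, tau2)
        theta_i, _ = blup_estimates(data, fit)
        lo = np.minimum(data.y, fit.theta_hat) - 1e-12
        hi = np.maximum(data.y, fit.theta_hat) + 1e-12
        assert np.all((theta_i >= lo) & (theta_i <= hi))

    def test_larger_variances_shrink_more(self):
        # equal |Y_i - theta_hat|: shrinkage grows with v_i
        data = StudySet(y=[-1.0, 1.0, -1.0, 1.0], v=[0.1, 0.1, 0.8, 0.8])
        fit = fit_random_effects(data, 0.5)
        theta_i, _ = blup_estimates(data, fit)
        moves = np.abs(theta_i - data.y)
        assert moves[2] > moves[0] and moves[3] > moves[1]


class TestVarianceFormulae:
    def test_crude_hand_values_and_precision_identity(self):
        assert variance_crude(0.5, 0.5) == pytest.approx(0.25)
        assert 1.0 / variance_crude(0.5, 0.5) == pytest.approx(
            1.0 / 0.5 + 1.0 / 0.5
        )

    def test_crude_warns_at_zero_tau2(self):
        with pytest.warns(ZeroTau2Warning):
            out = variance_crude(np.array([0.3, 0.7]), 0.0)
        np.testing.assert_allclose(out, 0.0)

    def test_raudenbush_hand_value(self):
        # v = tau2 = 0.5, w = 2: 0.25 + 0.5 * 0.25 / 1
        assert variance_raudenbush(0.5, 0.5, 2.0) == pytest.approx(0.375)

    def test_raudenbush_single_study_equals_within_variance(self):
        # n = 1: 1/w = v + tau2 makes the ratio to v exactly one
        v, tau2 = 0.37, 0.81
        w = 1.0 / (v + tau2)
        assert variance_raudenbush(v, tau2, w) == pytest.approx(v, rel=1e-12)

    def test_raudenbush_zero_tau2_is_pooled_variance(self):
        assert variance_raudenbush(0.4, 0.0, 5.0) == pytest.approx(0.2)

    def test_quan_hand_values(self):
        assert variance_quan(0.5, 0.0, 5.0) == pytest.approx(0.2)
        # v = tau2 = 0.5, w = 2: 0.25 + 0.5 * 0.75
        assert variance_quan(0.5, 0.5, 2.0) == pytest.approx(0.625)

    def test_raudenbush_and_quan_asymptotically_equal_when_v_is_tau2(self):
        v = tau2 = 0.7
        big_w = 1e8
        assert variance_raudenbush(v, tau2, big_w) == pytest.approx(
            variance_quan(v, tau2, big_w), rel=1e-6
        )
        assert variance_raudenbush(v, tau2, big_w) == pytest.approx(
            tau2 / 2.0, rel=1e-6
        )

    def test_large_w_monotonicity_in_v(self):
        # large-study-count limits: Raudenbush increasing in v, Quan decreasing
        v = np.linspace(0.05, 2.0, 50)
        raud = variance_raudenbush(v, 0.4, 1e9)
        quan = variance_quan(v, 0.4, 1e9)
        assert np.all(np.diff(raud) > 0)
        assert np.all(np.diff(quan) < 0)

    def test_crude_is_large_w_limit_of_raudenbush(self):
        assert variance_raudenbush(0.6, 0.3, 1e10) == pytest.approx(
            variance_crude(0.6, 0.3), rel=1e-8
        )

    @given(
        st.floats(0.01, 5.0),
        st.floats(0.0, 5.0),
        st.floats(0.05, 100.0),
    )
    def test_crude_below_raudenbush_below_within_variance(self, v, tau2, w):
        # an attainable total weight satisfies 1/(v + tau2) <= w <= n/(v + tau2);
        # clamp the draw into the n <= 2 band so the dominance bound applies
        w = float(np.clip(w, 1.0 / (v + tau2), 2.0 / (v + tau2)))
        raud = variance_raudenbush(v, tau2, w)
        assert variance_crude(v, tau2) <= raud + 1e-15 if tau2 > 0 else True
        assert raud <= v + 1e-12


class TestDecomposition:
    def test_terms_sum_to_raudenbush_hand_value(self):
        terms = blup_decomposition_terms(0.5, 0.5, 2.0)
        assert float(sum(t for t in terms)) == pytest.approx(0.375)

    def test_zero_tau2_terms(self):
        var_blup, var_theta, neg2cov = blup_decomposition_terms(0.4, 0.0, 5.0)
        assert var_blup == pytest.approx(0.2)
        assert var_theta == pytest.approx(0.0)
        assert neg2cov == pytest.approx(0.0)

    def test_identity_over_random_inputs(self, rng):
        size = 10_000
        v = rng.uniform(0.01, 5.0, size=size)
        tau2 = rng.uniform(0.0, 5.0, size=size)
        w = rng.uniform(0.05, 50.0, size=size)
        lhs = np.empty(size)
        rhs = np.empty(size)
        for i in range(size):
            a, b, c = blup_decomposition_terms(v[i], tau2[i], w[i])
            lhs[i] = a + b + c
            rhs[i] = variance_raudenbush(v[i], tau2[i], w[i])
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-15)


class TestStudyPredictionIntervals:
    def test_hand_worked_interval(self):
        data = StudySet(y=[0.0, 1.0], v=[0.5, 0.5])
        fit = fit_random_effects(data, 0.5)  # w = 2, theta_i = 0.25, 0.75
        shr = study_prediction_intervals(data, fit, formula="raudenbush")
        # V = 0.375, theta_1 = 0.25 -> 0.25 +/- 1.959964 sqrt(0.375)
        assert shr.lower[0] == pytest.approx(0.25 - Z975 * np.sqrt(0.375), abs=1e-4)
        assert shr.upper[0] == pytest.approx(0.25 + Z975 * np.sqrt(0.375), abs=1e-4)

    def test_intervals_symmetric_about_theta_i(self, toy_five):
        fit = fit_random_effects(toy_five, 0.2)
        shr = study_prediction_intervals(toy_five, fit)
        np.testing.assert_allclose(
            (shr.lower + shr.upper) / 2.0, shr.theta_i, atol=1e-12
        )

    def test_crude_zero_tau2_zero_width_with_warning(self, toy_five):
        fit = fit_random_effects(toy_five, 0.0)
        with pytest.warns(ZeroTau2Warning):
            shr = study_prediction_intervals(toy_five, fit, formula="crude")
        np.testing.assert_allclose(shr.upper - shr.lower, 0.0)
        np.testing.assert_allclose(shr.theta_i, fit.theta_hat)

    def test_unknown_formula_rejected(self, toy_five):
        fit = fit_random_effects(toy_five, 0.2)
        with pytest.raises(ValueError, match="formula"):
            study_prediction_intervals(toy_five, fit, formula="bayes")

    def test_kh_scales_only_the_pooled_variance_term(self, toy_five):
        from metablup.inference import with_knapp_hartung

        fit = with_knapp_hartung(toy_five, fit_random_effects(toy_five, 0.2))
        q = fit.kh_scale
        plain = study_prediction_intervals(toy_five, fit, use_kh=False)
        scaled = study_prediction_intervals(toy_five, fit, use_kh=True)
        tau2, w = 0.2, fit.total_weight
        s = toy_five.v + tau2
        expected = plain.var_raudenbush + (q - 1.0) / w * toy_five.v**2 / s**2
        half = (scaled.upper - scaled.lower) / 2.0
        np.testing.assert_allclose(half, Z975 * np.sqrt(expected), rtol=1e-4)

    def test_kh_leaves_crude_formula_unchanged(self, toy_five):
        from metablup.inference import with_knapp_hartung

        fit = with_knapp_hartung(toy_five, fit_random_effects(toy_five, 0.2))
        plain = study_prediction_intervals(toy_five, fit, formula="crude")
        scaled = study_prediction_intervals(
            toy_five, fit, formula="crude", use_kh=True
        )
        np.testing.assert_allclose(plain.lower, scaled.lower)
        np.testing.assert_allclose(plain.upper, scaled.upper)

    def test_blup_dominance_limits(self):
        # tau2 -> infinity: theta_i -> Y_i and Raudenbush variance -> v_i
        data = StudySet(y=[0.0, 2.0], v=[0.5, 0.8])
        fit = fit_random_effects(data, 1e9)
        shr = study_prediction_intervals(data, fit)
        np.testing.assert_allclose(shr.theta_i, data.y, atol=1e-6)
        np.testing.assert_allclose(shr.var_raudenbush, data.v, rtol=1e-6)
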