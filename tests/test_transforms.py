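"""The logistic-weight curve family: closed forms, limits, derivatives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crshape.transforms import (
    ExposureTransform,
    RiskCurve,
    delta_nu,
    hazard_ratio,
    hr_derivative,
    logistic_weight,
    make_special,
    transform_value,
)

transforms = st.builds(
    ExposureTransform,
    f_kind=st.sampled_from(["identity", "log"]),
    mu=st.floats(-50, 50),
    tau=st.floats(0.01, 1.0),
    range_r=st.floats(0.5, 100.0),
)


class TestLogisticWeight:
    def test_half_at_mu(self):
        t = ExposureTransform("identity", mu=8.0, tau=0.1, range_r=26.5)
        assert logistic_weight(8.0, t) == pytest.approx(0.5, abs=1e-15)

    def test_three_quarters_one_ln3_scale_above_mu(self):
        t = ExposureTransform("identity", mu=5.0, tau=0.2, range_r=10.0)
        z = 5.0 + 0.2 * 10.0 * math.log(3.0)
        assert logistic_weight(z, t) == pytest.approx(0.75, rel=1e-12)

    def test_indicator_behaviour_at_tiny_tau(self):
        # exponent is -100 at 0.01*r above mu: the weight saturates to 1
        # beyond any representable tolerance (1 - 1e-40 rounds to 1.0)
        t = ExposureTransform("identity", mu=10.0, tau=1e-4, range_r=26.5)
        assert logistic_weight(10.0 + 0.01 * 26.5, t) >= 1 - 1e-40
        assert logistic_weight(10.0 - 0.01 * 26.5, t) < 1e-40

    @pytest.mark.parametrize("bad", [{"tau": -0.1}, {"tau": 0.0}, {"range_r": 0.0}])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(f_kind="identity", mu=0.0, tau=0.1, range_r=10.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            ExposureTransform(**kw)

    @given(t=transforms, data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_strictly_increasing_and_bounded(self, t, data):
        z1 = data.draw(st.floats(-100, 100))
        z2 = data.draw(st.floats(-100, 100))
        lo, hi = sorted([z1, z2])
        w_lo, w_hi = logistic_weight(lo, t), logistic_weight(hi, t)
        # mathematically in (0,1); the upper end saturates to 1.0 in
        # float64 once the exponent passes ~37, so strictness is asserted
        # only where representable
        assert 0.0 < w_lo <= 1.0 and 0.0 < w_hi <= 1.0
        if (hi - t.mu) / (t.tau * t.range_r) < 36:
            assert w_hi < 1.0
        if hi - lo > 1e-9 * t.tau * t.range_r:
            assert w_hi >= w_lo  # equality only in saturated tails

    @given(t=transforms)
    @settings(max_examples=40, deadline=None)
    def test_indicator_limit(self, t):
        sharp = ExposureTransform(t.f_kind, t.mu, 1e-4, t.range_r)
        for z in (t.mu - 0.02 * t.range_r, t.mu + 0.02 * t.range_r):
            ind = float(z > sharp.mu)
            assert abs(logistic_weight(z, sharp) - ind) < 1e-3


class TestTransformValue:
    def test_log_of_one_is_zero(self):
        t = ExposureTransform("log", mu=5.0, tau=0.3, range_r=12.0)
        assert transform_value(1.0, t) == 0.0

    def test_saturated_weight_recovers_identity(self):
        t = ExposureTransform("identity", mu=-1e9, tau=0.1, range_r=26.5)
        for z in (1.4, 10.0, 27.9):
            assert transform_value(z, t) == pytest.approx(z, rel=1e-6)

    def test_threshold_vanishes_below_t(self):
        T, r = 10.0, 26.5
        t = make_special("threshold", 1.4, 27.9, threshold=T)
        assert abs(transform_value(T - 0.5 * r, t)) < 1e-12
        assert transform_value(T, t) == pytest.approx(0.0, abs=1e-12)

    def test_log_domain_error(self):
        t = ExposureTransform("log", mu=5.0, tau=0.1, range_r=10.0)
        with pytest.raises(ValueError):
            transform_value(0.0, t)
        with pytest.raises(ValueError):
            transform_value(-3.0, t)

    @given(t=transforms, data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_nu_nondecreasing_where_f_nonnegative(self, t, data):
        # for f=log, f(z) >= 0 means z >= 1
        lo_bound = 1.0 if t.f_kind == "log" else 0.0
        z1 = data.draw(st.floats(lo_bound, 100))
        z2 = data.draw(st.floats(lo_bound, 100))
        lo, hi = sorted([z1, z2])
        assert transform_value(hi, t) >= transform_value(lo, t) - 1e-12


class TestDeltaNu:
    def test_zero_at_equal_concentrations(self):
        t = ExposureTransform("log", mu=8.0, tau=0.1, range_r=26.5)
        assert delta_nu(12.0, 12.0, t) == 0.0

    @given(t=transforms, a=st.floats(0.5, 60), b=st.floats(0.5, 60))
    @settings(max_examples=60, deadline=None)
    def test_antisymmetric(self, t, a, b):
        assert delta_nu(a, b, t) == pytest.approx(-delta_nu(b, a, t), abs=1e-12)

    def test_saturated_log_limit_is_log_ratio(self):
        t = ExposureTransform("log", mu=-1e9, tau=0.1, range_r=26.5)
        assert delta_nu(15.0, 10.0, t) == pytest.approx(math.log(1.5), rel=1e-9)

    def test_two_term_formula(self):
        # independent evaluation of f(z)*omega(z) at each endpoint with
        # scalar math: mu=8.19, tau=0.1, r=26.5, zC=15, zF=10
        t = ExposureTransform("log", mu=8.19, tau=0.1, range_r=26.5)
        expected = 0.9856240121342206
        assert delta_nu(15.0, 10.0, t) == pytest.approx(expected, rel=1e-12)


class TestHazardRatio:
    def test_unity_when_beta_zero_or_at_reference(self):
        t = ExposureTransform("log", mu=8.0, tau=0.1, range_r=26.5)
        assert hazard_ratio(17.0, 5.0, RiskCurve(t, 0.0)) == 1.0
        assert hazard_ratio(5.0, 5.0, RiskCurve(t, 0.3)) == 1.0

    def test_saturated_log_limit_is_power_law(self):
        t = ExposureTransform("log", mu=-1e9, tau=0.1, range_r=26.5)
        c = RiskCurve(t, 0.4)
        assert hazard_ratio(20.0, 5.0, c) == pytest.approx(4.0**0.4, rel=1e-9)

    @given(
        t=transforms,
        beta=st.floats(-0.5, 0.5),
        a=st.floats(1, 40),
        b=st.floats(1, 40),
        c=st.floats(1, 40),
    )
    @settings(max_examples=60, deadline=None)
    def test_multiplicative_in_reference(self, t, beta, a, b, c):
        curve = RiskCurve(t, beta)
        assert hazard_ratio(a, c, curve) == pytest.approx(
            hazard_ratio(a, b, curve) * hazard_ratio(b, c, curve), rel=1e-10
        )


class TestHRDerivative:
    def test_zero_when_beta_zero(self):
        t = ExposureTransform("log", mu=8.0, tau=0.1, range_r=26.5)
        assert hr_derivative(12.0, RiskCurve(t, 0.0)) == 0.0

    def test_linear_limit_closed_form(self):
        t = ExposureTransform("identity", mu=-1e9, tau=0.1, range_r=26.5)
        c = RiskCurve(t, 0.05)
        z, z_ref = 14.0, 2.0
        expected = 0.05 * math.exp(0.05 * (z - z_ref))
        assert hr_derivative(z, c, z_ref=z_ref) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize(
        "f_kind,mu,tau,beta",
        [
            ("log", 8.19, 0.1, 0.0433),
            ("log", 1.38, 0.2, 0.0666),
            ("identity", 14.0, 0.1, 0.02),
            ("identity", -5.0, 0.5, -0.03),
        ],
    )
    def test_matches_finite_difference(self, f_kind, mu, tau, beta):
        t = ExposureTransform(f_kind, mu=mu, tau=tau, range_r=26.5)
        c = RiskCurve(t, beta)
        grid = np.linspace(1.5, 27.5, 50)
        h = 1e-6 * (1 + np.abs(grid))
        num = (
            np.exp(c.beta * transform_value(grid + h, t))
            - np.exp(c.beta * transform_value(grid - h, t))
        ) / (2 * h)
        ana = hr_derivative(grid, c)
        rel = np.abs(ana - num) / np.maximum(np.abs(num), 1e-12)
        assert rel.max() < 1e-5


class TestMakeSpecial:
    def test_linear_weight_saturated_over_range(self):
        t = make_special("linear", 1.4, 27.9)
        z = np.linspace(1.4, 27.9, 100)
        assert np.all(logistic_weight(z, t) > 1 - 1e-6)

    def test_power_like_sets_tau(self):
        t = make_special("power_like", 1.4, 27.9, mu=8.2)
        assert t.tau == 0.2 and t.f_kind == "log"

    def test_threshold_requires_t_in_range(self):
        with pytest.raises(ValueError):
            make_special("threshold", 1.4, 27.9, threshold=30.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_special("spline", 1.0, 2.0)

    def test_serialization_round_trip(self):
        t = make_special("threshold", 1.4, 27.9, threshold=9.5)
        t2 = ExposureTransform.from_dict(t.to_dict())
        assert t2 == t
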