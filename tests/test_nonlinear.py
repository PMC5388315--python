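"""Nonlinear thermal performance curves: evaluation, critical temperatures
and multi-start fitting."""

import math

import numpy as np
import pytest

import thermodev as td
from thermodev.nonlinear import analytis_t_fast, critical_temperatures, rate

# Published Lactin-2 parameter set for the pooled immature stages, used as a
# fixed evaluation point for derivative/zero-crossing checks.
LACTIN2_IMMATURE = td.Lactin2Params(
    p=0.1238102145, delta_t=8.0661967712, lam=-0.014783871, t_max_param=38.88
)


class TestRateEvaluation:
    def test_analytis_vanishes_at_thresholds(self):
        p = td.AnalytisParams(a=1e-4, t_min=10, t_max=35, n=1.2, m=0.4)
        assert rate("analytis", p, 10.0) == 0.0
        assert rate("analytis", p, 35.0) == 0.0
        assert rate("analytis", p, 5.0) == 0.0  # clamped outside range

    def test_briere2_vanishes_at_lower_threshold(self):
        p = td.Briere2Params(a=1.0, t_min=10, t_max=30, d=2)
        assert rate("briere2", p, 10.0) == 0.0
        assert rate("briere2", p, 35.0) == 0.0

    def test_briere2_accepts_negative_d(self):
        # published egg fits carry hugely negative d; the (t_max - T)^(1/d)
        # term then approaches 1 and the rate stays finite
        p = td.Briere2Params(a=6.457e-4, t_min=12.85, t_max=32.111, d=-4432866.14)
        r = rate("briere2", p, 25.0)
        assert math.isfinite(r) and r > 0
        assert r == pytest.approx(6.457e-4 * 25.0 * (25.0 - 12.85), rel=1e-4)

    def test_lactin2_derivative_zero_at_published_maximum(self):
        # analytic derivative p*e^{pT} - (1/dT)*e^{p*Tmax-(Tmax-T)/dT};
        # at the published immature T_fast = 30.8 both terms are ~5.61
        p = LACTIN2_IMMATURE
        term1 = p.p * math.exp(p.p * 30.8)
        term2 = (1.0 / p.delta_t) * math.exp(
            p.p * p.t_max_param - (p.t_max_param - 30.8) / p.delta_t
        )
        assert term1 == pytest.approx(5.61, abs=0.01)
        assert (term1 - term2) / term1 == pytest.approx(0.0, abs=1e-4)

    def test_lactin2_may_be_negative(self):
        assert rate("lactin2", LACTIN2_IMMATURE, 0.0) < 1.0
        assert rate("lactin2", LACTIN2_IMMATURE, 5.0) < rate(
            "lactin2", LACTIN2_IMMATURE, 25.0
        )

    def test_vectorized_matches_scalar(self):
        p = td.Briere2Params(a=2e-4, t_min=12, t_max=35, d=3)
        T = np.array([10.0, 15.0, 25.0, 34.0, 36.0])
        vec = rate("briere2", p, T)
        assert vec == pytest.approx([rate("briere2", p, float(t)) for t in T])


class TestCriticalTemperatures:
    def test_analytis_symmetric_case(self):
        p = td.AnalytisParams(a=1e-3, t_min=10, t_max=30, n=1, m=1)
        assert analytis_t_fast(p) == pytest.approx(20.0)

    def test_analytis_closed_form_equals_numeric_argmax(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            t_min = rng.uniform(0, 15)
            t_max = t_min + rng.uniform(8, 30)
            p = td.AnalytisParams(
                a=10 ** rng.uniform(-7, -3),
                t_min=t_min,
                t_max=t_max,
                n=rng.uniform(0.3, 3),
                m=rng.uniform(0.05, 3),
            )
            ct = critical_temperatures("analytis", p)
            grid = np.linspace(t_min, t_max, 20001)
            t_num = grid[np.argmax(rate("analytis", p, grid))]
            assert abs(ct.t_fast - t_num) < 1e-3
            assert ct.t_fast == pytest.approx(analytis_t_fast(p), abs=1e-9)

    def test_rate_nonnegative_and_maximal_at_t_fast(self):
        p = td.Briere2Params(a=2e-4, t_min=12, t_max=35, d=3)
        ct = critical_temperatures("briere2", p)
        grid = np.linspace(12, 35, 500)
        r = rate("briere2", p, grid)
        assert np.all(r >= 0)
        assert rate("briere2", p, ct.t_fast) >= r.max() - 1e-12

    def test_lactin2_thresholds_from_published_immature_params(self):
        ct = critical_temperatures("lactin2", LACTIN2_IMMATURE)
        assert ct.t_max == pytest.approx(38.88)
        assert ct.t_fast == pytest.approx(30.8, abs=0.05)
        assert ct.t_min == pytest.approx(9.0, abs=0.1)  # lower zero crossing
        assert dict(ct.provenance)["t_min"] == "numeric-root"

    def test_ordering_invariant(self):
        ct = critical_temperatures(
            "analytis", td.AnalytisParams(a=1e-4, t_min=10, t_max=35, n=1.2, m=0.4)
        )
        assert ct.t_min < ct.t_fast < ct.t_max


class TestFitting:
    def test_noiseless_briere2_parameter_recovery(self):
        truth = td.Briere2Params(a=2e-4, t_min=12, t_max=35, d=3)
        temps = np.linspace(13, 34.5, 8)
        pts = [td.RatePoint(float(t), rate("briere2", truth, float(t))) for t in temps]
        res = td.ThermalCurveModel("briere2", pts).fit()
        assert res.converged
        assert res.params.a == pytest.approx(truth.a, rel=1e-4)
        assert res.params.t_min == pytest.approx(truth.t_min, rel=1e-4)
        assert res.params.t_max == pytest.approx(truth.t_max, rel=1e-4)
        assert res.params.d == pytest.approx(truth.d, rel=1e-4)

    def test_immature_briere2_t_fast(self, immature_briere2_fit):
        # published estimate 31.1 degC for the pooled immature stages
        assert immature_briere2_fit.converged
        assert immature_briere2_fit.critical.t_fast == pytest.approx(31.1, abs=0.7)

    def test_immature_lactin2_t_fast(self, immature_lactin2_fit):
        assert immature_lactin2_fit.critical.t_fast == pytest.approx(30.8, abs=0.7)

    def test_immature_analytis_t_fast(self, immature_analytis_fit):
        assert immature_analytis_fit.critical.t_fast == pytest.approx(31.1, abs=0.7)

    def test_r2_adj_below_r2(self, immature_briere2_fit, immature_lactin2_fit):
        for res in (immature_briere2_fit, immature_lactin2_fit):
            assert res.r2_adj <= res.r2 <= 1.0

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            td.ThermalCurveModel("briere2", [td.RatePoint(20, 0.1), td.RatePoint(24, 0.2)])

    def test_deterministic_given_seed(self, immature_curve_points):
        cfg = td.MultistartConfig(n_starts=16, seed=99)
        a = td.ThermalCurveModel("briere2", immature_curve_points).fit(config=cfg)
        b = td.ThermalCurveModel("briere2", immature_curve_points).fit(config=cfg)
        assert a.params == b.params

    def test_seed_changes_result_only_negligibly(self, immature_curve_points):
        r1 = td.ThermalCurveModel("briere2", immature_curve_points).fit(
            config=td.MultistartConfig(seed=1)
        )
        r2 = td.ThermalCurveModel("briere2", immature_curve_points).fit(
            config=td.MultistartConfig(seed=2)
        )
        assert r1.critical.t_fast == pytest.approx(r2.critical.t_fast, abs=1e-5)

    def test_bound_hits_are_flagged(self, immature_lactin2_fit):
        # the immature Lactin-2 optimum sits on the t_max_param bound and
        # must be reported, not hidden
        assert isinstance(immature_lactin2_fit.at_bounds, tuple)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            td.AnalytisParams(a=1e-4, t_min=30, t_max=10, n=1, m=1)
        with pytest.raises(ValueError):
            td.Briere2Params(a=1e-4, t_min=10, t_max=30, d=0)
        with pytest.raises(ValueError):
            td.Lactin2Params(p=0.1, delta_t=0.0, lam=0.0, t_max_param=35)
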