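"""Linear degree-day models against a normal-equation oracle and the
published regression numbers for the packaged table."""

import math

import numpy as np
import pytest

import thermodev as td

from conftest import EGG_DURATIONS, IMMATURE_DURATIONS, LARVAE_DURATIONS


def ols_oracle(x, y):
    """Closed-form simple-regression normal equations (independent oracle)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    b = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    a = y.mean() - b * x.mean()
    return a, b


def immature_points():
    return [
        td.RatePoint(t, 1.0 / IMMATURE_DURATIONS[t]) for t in (20, 24, 28, 30)
    ]


class TestTraditional:
    def test_ols_matches_normal_equations_on_random_inputs(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            n = int(rng.integers(3, 10))
            x = np.sort(rng.uniform(10, 35, n))
            while len(set(x)) < 3:
                x = np.sort(rng.uniform(10, 35, n))
            y = rng.uniform(0.01, 0.5, n)
            res = td.fit_traditional(
                [td.RatePoint(float(xi), float(yi)) for xi, yi in zip(x, y)]
            )
            a, b = ols_oracle(x, y)
            assert res.slope == pytest.approx(b, rel=1e-12)
            assert res.intercept == pytest.approx(a, rel=1e-12)

    def test_immature_regression_coefficients(self):
        res = td.fit_traditional(immature_points())
        # normal equations on the four mean rates, frozen to full precision
        assert res.slope == pytest.approx(0.0023261, abs=1e-7)
        assert res.intercept == pytest.approx(-0.0238728, abs=1e-7)
        assert res.t_min == pytest.approx(10.263, abs=1e-3)
        assert res.se_t_min == pytest.approx(1.575, abs=1e-3)
        assert res.k == pytest.approx(429.90, abs=0.01)
        assert res.se_k == pytest.approx(43.10, abs=0.01)
        assert res.r2 == pytest.approx(0.9803, abs=1e-4)
        assert res.r2_adj == pytest.approx(0.9704, abs=1e-4)
        assert res.p_value == pytest.approx(0.0099, abs=5e-4)

    def test_noiseless_line_recovered_exactly(self):
        pts = [td.RatePoint(t, 0.01 * (t - 15)) for t in (20, 24, 28, 30)]
        res = td.fit_traditional(pts)
        assert res.t_min == pytest.approx(15.0, abs=1e-10)
        assert res.k == pytest.approx(100.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.se_t_min == pytest.approx(0.0, abs=1e-6)
        assert res.se_k == pytest.approx(0.0, abs=1e-6)

    def test_rate_at_threshold_is_zero_and_k_slope_unity(self):
        res = td.fit_traditional(immature_points())
        assert res.predict_rate(res.t_min) == pytest.approx(0.0, abs=1e-15)
        assert res.k * res.slope == pytest.approx(1.0, rel=1e-12)

    def test_negative_slope_flagged_not_raised(self):
        pts = [td.RatePoint(t, 0.5 - 0.01 * t) for t in (20, 24, 28, 30)]
        res = td.fit_traditional(pts)
        assert not res.ok
        assert math.isnan(res.t_min) and math.isnan(res.k)
        assert "WARNING" in res.summary()

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            td.fit_traditional([td.RatePoint(20, 0.1), td.RatePoint(24, 0.2)])


class TestIkemotoTakai:
    def test_egg_regression(self):
        pairs = [(t, d) for t, d in EGG_DURATIONS.items()]
        res = td.fit_ikemoto_takai(pairs)
        assert res.t_min == pytest.approx(10.986, abs=1e-3)
        assert res.k == pytest.approx(60.222, abs=1e-3)
        # published values: slope 10.977, intercept 60.278
        assert res.t_min == pytest.approx(10.977, abs=0.05)
        assert res.k == pytest.approx(60.278, abs=0.1)

    def test_immature_regression(self):
        pairs = [(t, IMMATURE_DURATIONS[t]) for t in (20, 24, 28, 30)]
        res = td.fit_ikemoto_takai(pairs)
        assert res.t_min == pytest.approx(11.211, abs=1e-3)
        assert res.k == pytest.approx(402.48, abs=0.01)

    def test_noiseless_construction(self):
        # pairs generated exactly from D*T = 100 + 12*D
        durations = [5.0, 8.0, 12.0, 20.0]
        pairs = [((100 + 12 * d) / d, d) for d in durations]
        res = td.fit_ikemoto_takai(pairs)
        assert res.t_min == pytest.approx(12.0, abs=1e-10)
        assert res.k == pytest.approx(100.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_traditional_on_exact_linear_data(self):
        t_min, k = 11.0, 350.0
        temps = [20.0, 24.0, 28.0, 30.0]
        pairs = [(t, k / (t - t_min)) for t in temps]
        it = td.fit_ikemoto_takai(pairs)
        tr = td.fit_traditional([td.RatePoint(t, 1.0 / d) for t, d in pairs])
        assert it.t_min == pytest.approx(tr.t_min, abs=1e-8)
        assert it.k == pytest.approx(tr.k, abs=1e-6)
        assert it.t_min == pytest.approx(t_min, abs=1e-8)

    def test_degenerate_equal_durations(self):
        with pytest.raises(ValueError, match="degenerate"):
            td.fit_ikemoto_takai([(20, 5.0), (24, 5.0), (28, 5.0)])


class TestDerivedSEs:
    def test_se_t_min_direct_evaluation(self):
        # (r/b)*sqrt(S2/(N r^2) + SEb^2/b^2) at hand-picked values
        val = td.se_t_min(rbar=0.1, b=0.01, s2=1e-6, n=4, se_b=1e-4)
        assert val == pytest.approx(10 * math.sqrt(2.5e-5 + 1e-4), rel=1e-12)

    def test_se_t_min_zero_for_perfect_fit(self):
        assert td.se_t_min(0.2, 0.01, 0.0, 4, 0.0) == 0.0

    def test_se_k_direct(self):
        assert td.se_k(0.01, 1e-4) == pytest.approx(1.0, rel=1e-12)
        assert td.se_k(0.01, 0.0) == 0.0

    def test_zero_slope_raises(self):
        with pytest.raises(ZeroDivisionError):
            td.se_t_min(0.1, 0.0, 1e-6, 4, 1e-4)
        with pytest.raises(ZeroDivisionError):
            td.se_k(0.0, 1e-4)

    def test_nonnegative(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            v = td.se_t_min(
                rbar=rng.uniform(0.01, 1),
                b=rng.uniform(1e-4, 0.1),
                s2=rng.uniform(0, 1e-4),
                n=int(rng.integers(3, 10)),
                se_b=rng.uniform(0, 1e-3),
            )
            assert v >= 0


class TestPredictDuration:
    def test_arithmetic(self):
        assert td.predict_duration(100.0, 12.0, 22.0) == pytest.approx(10.0)

    def test_immature_prediction(self):
        res = td.fit_traditional(immature_points())
        # K/(30 - T_min) with the fitted immature parameters
        assert res.predict_duration(30.0) == pytest.approx(21.78, abs=0.05)

    def test_at_or_below_threshold(self):
        with pytest.raises(ValueError, match="T_min"):
            td.predict_duration(100.0, 12.0, 12.0)


def test_from_stage_table_applies_selection(example_table):
    model = td.TraditionalDegreeDayModel.from_stage_table(
        example_table, "immature_total"
    )
    assert list(model.temperature) == [20.0, 24.0, 28.0, 30.0]
    res = model.fit()
    assert res.n_points == 4
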