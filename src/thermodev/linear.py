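"""Linear degree-day models: traditional and Ikemoto-Takai.

Within the moderate temperature range an insect's developmental rate
``r = 1/D`` rises linearly with temperature,

    r = -T_min/K + T/K,

so the lower developmental threshold ``T_min`` (degC, where the fitted rate
extrapolates to zero) and the thermal constant ``K`` (degree-days) follow
from the slope ``b`` and intercept ``a`` of an ordinary least-squares fit of
rate on temperature: ``T_min = -a/b`` and ``K = 1/b``.

The Ikemoto-Takai linearisation fits the same two quantities from the
equivalent identity ``D*T = K + T_min*D``: OLS of the product duration x
temperature on duration yields ``T_min`` as the slope and ``K`` as the
intercept directly, which stabilises the estimates when the observed
temperature span is narrow.

Standard errors of the derived quantities follow the delta-method formulas

    SE(T_min) = (rbar/b) * sqrt(S^2/(N*rbar^2) + SE_b^2/b^2)
    SE(K)     = SE_b / b^2

with ``rbar`` the sample mean rate, ``S^2`` the residual mean square and
``SE_b`` the standard error of the slope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .data import RatePoint, StageTable, compute_rates, select_linear_range

__all__ = [
    "LinearThresholdResults",
    "TraditionalDegreeDayModel",
    "IkemotoTakaiModel",
    "fit_traditional",
    "fit_ikemoto_takai",
    "se_t_min",
    "se_k",
    "predict_duration",
]


def se_t_min(rbar: float, b: float, s2: float, n: int, se_b: float) -> float:
    """Delta-method SE of the lower threshold from a traditional fit.

    Parameters are the sample mean rate ``rbar``, slope ``b``, residual mean
    square ``s2``, sample size ``n`` and slope standard error ``se_b``.
    """
    if b == 0:
        raise ZeroDivisionError("slope is zero; T_min undefined")
    if n < 3:
        raise ValueError("need at least 3 points")
    return abs(rbar / b) * math.sqrt(s2 / (n * rbar**2) + se_b**2 / b**2)


def se_k(b: float, se_b: float) -> float:
    """Delta-method SE of the thermal constant K = 1/b."""
    if b == 0:
        raise ZeroDivisionError("slope is zero; K undefined")
    return se_b / b**2


def predict_duration(k: float, t_min: float, temperature_C: float) -> float:
    """Days to complete the stage at a constant temperature, K/(T - T_min)."""
    if temperature_C <= t_min:
        raise ValueError(
            f"temperature {temperature_C} degC is at or below T_min={t_min}; "
            "duration undefined"
        )
    return k / (temperature_C - t_min)


@dataclass(frozen=True)
class LinearThresholdResults:
    """Fitted linear model with derived threshold and thermal constant.

    ``ok`` is False when the slope is non-positive, in which case ``t_min``
    and ``k`` are NaN rather than raising, so batch runs over many stages
    complete and the offending stage is flagged in the report.
    """

    model_id: str  # "traditional" | "ikemoto_takai"
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    t_min: float
    se_t_min: float
    k: float
    se_k: float
    r2: float
    r2_adj: float
    p_value: float
    n_points: int
    residual_mean_square: float
    ok: bool = True

    def predict_duration(self, temperature_C: float) -> float:
        return predict_duration(self.k, self.t_min, temperature_C)

    def predict_rate(self, temperature_C: float) -> float:
        """Fitted rate (T - T_min)/K; exactly zero at T = T_min."""
        return (temperature_C - self.t_min) / self.k

    @property
    def equation(self) -> str:
        if self.model_id == "traditional":
            return f"1/D = {self.intercept:+.5g} + {self.slope:.5g} T"
        return f"DT = {self.intercept:.5g} + {self.slope:.5g} D"

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "equation": self.equation,
            "slope": self.slope,
            "intercept": self.intercept,
            "se_slope": self.se_slope,
            "se_intercept": self.se_intercept,
            "t_min": self.t_min,
            "se_t_min": self.se_t_min,
            "k": self.k,
            "se_k": self.se_k,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "p_value": self.p_value,
            "n_points": self.n_points,
            "residual_mean_square": self.residual_mean_square,
            "ok": self.ok,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        lines = [
            f"{self.model_id} linear model ({self.n_points} points)",
            f"  {self.equation}",
            f"  T_min = {self.t_min:8.3f} +/- {self.se_t_min:.3f} degC",
            f"  K     = {self.k:8.2f} +/- {self.se_k:.2f} degree-days",
            f"  R2 = {self.r2:.4f}   R2_adj = {self.r2_adj:.4f}   P = {self.p_value:.4f}",
        ]
        if not self.ok:
            lines.append("  WARNING: non-positive slope; threshold undefined")
        return "\n".join(lines)


def _ols(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None):
    X = sm.add_constant(x)
    if weights is None:
        fit = sm.OLS(y, X).fit()
    else:
        fit = sm.WLS(y, X, weights=weights).fit()
    n = len(x)
    r2 = float(fit.rsquared)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return fit, r2, r2_adj


class TraditionalDegreeDayModel:
    """OLS of developmental rate on temperature (the classic degree-day fit).

    Parameters
    ----------
    points : sequence of RatePoint
        At least 3 points at 3 distinct temperatures.
    """

    model_id = "traditional"

    def __init__(self, points: Sequence[RatePoint]):
        if len(points) < 3:
            raise ValueError("need at least 3 rate points")
        temps = [p.temperature_C for p in points]
        if len(set(temps)) < 3:
            raise ValueError("need at least 3 distinct temperatures")
        self.points = sorted(points, key=lambda p: p.temperature_C)
        self.temperature = np.array([p.temperature_C for p in self.points])
        self.rate = np.array([p.rate for p in self.points])
        self.weights = (
            np.array([p.weight for p in self.points])
            if all(p.weight is not None for p in self.points)
            else None
        )

    @classmethod
    def from_stage_table(
        cls,
        table: StageTable,
        stage: str,
        include_temperatures: Sequence[float] | None = None,
        min_survival: float = 0.05,
        exclude_above_peak: bool = True,
    ) -> "TraditionalDegreeDayModel":
        points = compute_rates(table, stage)
        points = select_linear_range(
            points,
            survival_by_temp=table.survival_by_temp(stage),
            min_survival=min_survival,
            exclude_above_peak=exclude_above_peak,
            include_temperatures=include_temperatures,
        )
        return cls(points)

    def fit(self, weighted: bool = False) -> LinearThresholdResults:
        x, y = self.temperature, self.rate
        w = self.weights if weighted else None
        fit, r2, r2_adj = _ols(x, y, w)
        a, b = float(fit.params[0]), float(fit.params[1])
        se_a, se_b = float(fit.bse[0]), float(fit.bse[1])
        s2 = float(fit.mse_resid)
        p = float(fit.pvalues[1])
        n = len(x)
        ok = b > 0
        if ok:
            tmin = -a / b
            kk = 1.0 / b
            se_tmin = se_t_min(float(np.mean(y)), b, s2, n, se_b)
            se_kk = se_k(b, se_b)
        else:
            tmin = kk = se_tmin = se_kk = float("nan")
        return LinearThresholdResults(
            model_id=self.model_id,
            slope=b,
            intercept=a,
            se_slope=se_b,
            se_intercept=se_a,
            t_min=tmin,
            se_t_min=se_tmin,
            k=kk,
            se_k=se_kk,
            r2=r2,
            r2_adj=r2_adj,
            p_value=p,
            n_points=n,
            residual_mean_square=s2,
            ok=ok,
        )


class IkemotoTakaiModel:
    """OLS of duration x temperature on duration.

    The regression ``DT = K + T_min * D`` reads the lower threshold off the
    slope and the thermal constant off the intercept; their standard errors
    are the ordinary slope/intercept standard errors of this regression.
    """

    model_id = "ikemoto_takai"

    def __init__(self, pairs: Sequence[tuple[float, float]]):
        """``pairs`` are (temperature_C, duration_d) tuples, >= 3 of them."""
        if len(pairs) < 3:
            raise ValueError("need at least 3 (temperature, duration) pairs")
        durations = [d for _, d in pairs]
        if len(set(durations)) < 2:
            raise ValueError("degenerate input: all durations equal")
        self.pairs = sorted(pairs, key=lambda td: td[0])
        self.temperature = np.array([t for t, _ in self.pairs])
        self.duration = np.array([d for _, d in self.pairs])

    @classmethod
    def from_stage_table(
        cls,
        table: StageTable,
        stage: str,
        include_temperatures: Sequence[float] | None = None,
        min_survival: float = 0.05,
        exclude_above_peak: bool = True,
    ) -> "IkemotoTakaiModel":
        points = compute_rates(table, stage)
        points = select_linear_range(
            points,
            survival_by_temp=table.survival_by_temp(stage),
            min_survival=min_survival,
            exclude_above_peak=exclude_above_peak,
            include_temperatures=include_temperatures,
        )
        return cls([(p.temperature_C, 1.0 / p.rate) for p in points])

    def fit(self) -> LinearThresholdResults:
        d = self.duration
        dt = self.duration * self.temperature
        fit, r2, r2_adj = _ols(d, dt, None)
        a, b = float(fit.params[0]), float(fit.params[1])
        se_a, se_b = float(fit.bse[0]), float(fit.bse[1])
        return LinearThresholdResults(
            model_id=self.model_id,
            slope=b,
            intercept=a,
            se_slope=se_b,
            se_intercept=se_a,
            t_min=b,
            se_t_min=se_b,
            k=a,
            se_k=se_a,
            r2=r2,
            r2_adj=r2_adj,
            p_value=float(fit.pvalues[1]),
            n_points=len(d),
            residual_mean_square=float(fit.mse_resid),
            ok=True,
        )


def fit_traditional(points: Sequence[RatePoint], weighted: bool = False) -> LinearThresholdResults:
    """Convenience wrapper: build and fit a :class:`TraditionalDegreeDayModel`."""
    return TraditionalDegreeDayModel(points).fit(weighted=weighted)


def fit_ikemoto_takai(pairs: Sequence[tuple[float, float]]) -> LinearThresholdResults:
    """Convenience wrapper: build and fit an :class:`IkemotoTakaiModel`."""
    return IkemotoTakaiModel(pairs).fit()
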