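"""Nonlinear thermal performance curves: Analytis, Briere-2, Lactin-2.

Each model maps temperature T (degC) to developmental rate 1/D (per day)
over the full curvilinear response:

* Analytis:  ``r = a * (T - T_min)^n * (T_max - T)^m`` (zero outside
  [T_min, T_max]); its rate maximum has the closed form
  ``T_fast = (n*T_max + m*T_min) / (n + m)``.
* Briere-2:  ``r = a * T * (T - T_min) * (T_max - T)^(1/d)``, likewise
  clamped to zero outside the thresholds.
* Lactin-2:  ``r = exp(p*T) - exp(p*T_max - (T_max - T)/dT) + lam``; a raw
  formula value that may be negative, its thermal limits being the zero
  crossings of the curve rather than explicit parameters.

Fitting is bounded nonlinear least squares on the rate scale, restarted
from a Latin hypercube of initial points within the bounds so the result is
deterministic given the seed; these small-n, many-parameter fits are
multi-modal and a single local search is not trustworthy.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares, minimize_scalar
from scipy.stats import qmc

from .data import RatePoint, StageTable, compute_rates

__all__ = [
    "MODEL_IDS",
    "AnalytisParams",
    "Briere2Params",
    "Lactin2Params",
    "CriticalTemps",
    "NonlinearFitResults",
    "MultistartConfig",
    "ThermalCurveModel",
    "rate",
    "fit",
    "critical_temperatures",
    "analytis_t_fast",
    "default_bounds",
]

MODEL_IDS = ("analytis", "briere2", "lactin2")

#: Default multi-start seed; any positive integer below 2**31 is accepted.
DEFAULT_SEED = 20170228


@dataclass(frozen=True)
class AnalytisParams:
    a: float
    t_min: float
    t_max: float
    n: float
    m: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("require t_min < t_max")
        if not self.a > 0:
            raise ValueError("require a > 0")
        if not self.n > 0:
            raise ValueError("require n > 0")
        if self.m < 0:
            raise ValueError("require m >= 0")


@dataclass(frozen=True)
class Briere2Params:
    a: float
    t_min: float
    t_max: float
    d: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("require t_min < t_max")
        if not self.a > 0:
            raise ValueError("require a > 0")
        if self.d == 0:
            raise ValueError("require d != 0")


@dataclass(frozen=True)
class Lactin2Params:
    p: float
    delta_t: float
    lam: float
    t_max_param: float

    def __post_init__(self) -> None:
        if not self.delta_t > 0:
            raise ValueError("require delta_t > 0")


@dataclass(frozen=True)
class CriticalTemps:
    """Derived critical temperatures of a fitted rate curve (degC)."""

    t_min: float
    t_max: float
    t_fast: float
    t_opt: float | None = None
    provenance: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        vals = (self.t_min, self.t_fast, self.t_max)
        if all(math.isfinite(v) for v in vals):
            if not (self.t_min < self.t_fast < self.t_max):
                raise ValueError(
                    f"require t_min < t_fast < t_max, got {vals}"
                )

    def to_dict(self) -> dict:
        return {
            "t_min": self.t_min,
            "t_max": self.t_max,
            "t_fast": self.t_fast,
            "t_opt": self.t_opt,
            "provenance": dict(self.provenance),
        }


_PARAM_TYPES = {
    "analytis": AnalytisParams,
    "briere2": Briere2Params,
    "lactin2": Lactin2Params,
}

_PARAM_NAMES = {
    "analytis": ("a", "t_min", "t_max", "n", "m"),
    "briere2": ("a", "t_min", "t_max", "d"),
    "lactin2": ("p", "delta_t", "lam", "t_max_param"),
}


def rate(model_id: str, params, temperature_C):
    """Model developmental rate at one or many temperatures.

    Analytis and Briere-2 evaluate to 0 outside (t_min, t_max); Lactin-2 is
    the raw formula value and may be negative.
    """
    T = np.asarray(temperature_C, dtype=float)
    scalar = T.ndim == 0
    T = np.atleast_1d(T)
    if model_id == "analytis":
        out = np.zeros_like(T)
        mask = (T >= params.t_min) & (T <= params.t_max)
        out[mask] = (
            params.a
            * np.power(T[mask] - params.t_min, params.n)
            * np.power(params.t_max - T[mask], params.m)
        )
    elif model_id == "briere2":
        out = np.zeros_like(T)
        mask = (T > params.t_min) & (T < params.t_max)
        # the 1/d exponent applies only to the nonnegative base (t_max - T)
        out[mask] = (
            params.a
            * T[mask]
            * (T[mask] - params.t_min)
            * np.power(params.t_max - T[mask], 1.0 / params.d)
        )
        at_min = T == params.t_min
        out[at_min] = 0.0
    elif model_id == "lactin2":
        out = (
            np.exp(params.p * T)
            - np.exp(
                params.p * params.t_max_param
                - (params.t_max_param - T) / params.delta_t
            )
            + params.lam
        )
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return float(out[0]) if scalar else out


def analytis_t_fast(params: AnalytisParams) -> float:
    """Closed-form temperature of the Analytis rate maximum."""
    return (params.n * params.t_max + params.m * params.t_min) / (params.n + params.m)


def _argmax_rate(model_id: str, params, lo: float, hi: float) -> float:
    res = minimize_scalar(
        lambda t: -rate(model_id, params, float(t)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def critical_temperatures(model_id: str, params) -> CriticalTemps:
    """Derive (T_min, T_max, T_fast) from fitted curve parameters.

    Analytis and Briere-2 carry their thresholds as parameters; Lactin-2
    reports the fitted ``t_max_param`` and finds T_min as the lower zero
    crossing of the rate below T_fast (NaN, flagged in provenance, when the
    curve never crosses zero there).  T_fast is located by bounded scalar
    maximisation to 1e-6 degC; for Analytis the closed form is used.
    """
    if model_id == "analytis":
        return CriticalTemps(
            t_min=params.t_min,
            t_max=params.t_max,
            t_fast=analytis_t_fast(params),
            provenance=(
                ("t_min", "fitted-parameter"),
                ("t_max", "fitted-parameter"),
                ("t_fast", "analytic"),
            ),
        )
    if model_id == "briere2":
        return CriticalTemps(
            t_min=params.t_min,
            t_max=params.t_max,
            t_fast=_argmax_rate(model_id, params, params.t_min, params.t_max),
            provenance=(
                ("t_min", "fitted-parameter"),
                ("t_max", "fitted-parameter"),
                ("t_fast", "numeric-argmax"),
            ),
        )
    if model_id == "lactin2":
        t_max = params.t_max_param
        t_fast = _argmax_rate(model_id, params, -20.0, t_max)
        f = lambda t: rate(model_id, params, float(t))
        t_min = float("nan")
        prov_tmin = "undefined-no-sign-change"
        # scan downward from t_fast for a sign change bracketing the root
        lo_grid = np.linspace(t_fast, t_fast - 60.0, 241)
        vals = [f(t) for t in lo_grid]
        for i in range(len(lo_grid) - 1):
            if vals[i] > 0 >= vals[i + 1]:
                t_min = brentq(f, lo_grid[i + 1], lo_grid[i], xtol=1e-10)
                prov_tmin = "numeric-root"
                break
        return CriticalTemps(
            t_min=t_min,
            t_max=t_max,
            t_fast=t_fast,
            provenance=(
                ("t_min", prov_tmin),
                ("t_max", "fitted-parameter"),
                ("t_fast", "numeric-argmax"),
            ),
        )
    raise ValueError(f"unknown model_id {model_id!r}")


def default_bounds(model_id: str) -> dict[str, tuple[float, float]]:
    """Biologically plausible parameter boxes for temperate insects.

    Thresholds bracket the values seen across the Lepidoptera literature
    (T_min in [0, 20] degC, T_max in [30, 45] degC); shape exponents stay in
    (0, 5]; scale coefficients span several decades and are sampled
    log-uniformly at start generation.
    """
    if model_id == "analytis":
        return {
            "a": (1e-8, 1e-2),
            "t_min": (0.0, 20.0),
            "t_max": (30.0, 45.0),
            "n": (1e-2, 5.0),
            "m": (1e-4, 5.0),
        }
    if model_id == "briere2":
        return {
            "a": (1e-7, 1e-2),
            "t_min": (0.0, 20.0),
            "t_max": (30.0, 45.0),
            "d": (0.1, 10.0),
        }
    if model_id == "lactin2":
        return {
            "p": (1e-3, 0.5),
            "delta_t": (0.01, 20.0),
            "lam": (-2.0, 1.0),
            "t_max_param": (30.0, 45.0),
        }
    raise ValueError(f"unknown model_id {model_id!r}")


#: parameters started log-uniformly within their bounds
_LOG_SCALE = {"analytis": ("a",), "briere2": ("a",), "lactin2": ()}


@dataclass(frozen=True)
class MultistartConfig:
    """Latin-hypercube multi-start settings for the nonlinear fits."""

    n_starts: int = 64
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class NonlinearFitResults:
    """Fitted nonlinear curve with derived critical temperatures."""

    model_id: str
    params: object
    critical: CriticalTemps
    r2: float
    r2_adj: float
    rss: float
    n_points: int
    converged: bool
    n_starts_used: int
    at_bounds: tuple[str, ...] = ()

    def predict_rate(self, temperature_C):
        return rate(self.model_id, self.params, temperature_C)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": dataclasses.asdict(self.params),
            "critical": self.critical.to_dict(),
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "at_bounds": list(self.at_bounds),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        pd = dataclasses.asdict(self.params)
        lines = [f"{self.model_id} fit ({self.n_points} points)"]
        for k, v in pd.items():
            flag = "  [at bound]" if k in self.at_bounds else ""
            lines.append(f"  {k:12s} = {v:.10g}{flag}")
        c = self.critical
        lines.append(
            f"  T_min = {c.t_min:.2f}  T_max = {c.t_max:.2f}  T_fast = {c.t_fast:.2f} degC"
        )
        r2a = f"{self.r2_adj:.4f}" if math.isfinite(self.r2_adj) else "n/a"
        lines.append(f"  RSS = {self.rss:.3e}   R2 = {self.r2:.4f}   R2_adj = {r2a}")
        if not self.converged:
            lines.append("  WARNING: no start converged")
        return "\n".join(lines)


class ThermalCurveModel:
    """Multi-start bounded least squares for one thermal performance curve.

    Parameters
    ----------
    model_id : {"analytis", "briere2", "lactin2"}
    points : sequence of RatePoint
        At least 3 points; fewer points than parameters is permitted (the
        fit is then interpolatory and judged by its derived temperatures).
    """

    def __init__(self, model_id: str, points: Sequence[RatePoint]):
        if model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {model_id!r}")
        if len(points) < 3:
            raise ValueError("need at least 3 rate points")
        self.model_id = model_id
        self.points = sorted(points, key=lambda p: p.temperature_C)
        self.temperature = np.array([p.temperature_C for p in self.points])
        self.rate_obs = np.array([p.rate for p in self.points])

    @classmethod
    def from_stage_table(cls, model_id: str, table: StageTable, stage: str,
                         include_temperatures: Sequence[float] | None = None):
        points = compute_rates(table, stage)
        if include_temperatures is not None:
            keep = {float(t) for t in include_temperatures}
            points = [p for p in points if p.temperature_C in keep]
        return cls(model_id, points)

    def _theta_to_params(self, theta: np.ndarray):
        names = _PARAM_NAMES[self.model_id]
        return _PARAM_TYPES[self.model_id](**dict(zip(names, map(float, theta))))

    def fit(
        self,
        bounds: dict[str, tuple[float, float]] | None = None,
        config: MultistartConfig | None = None,
    ) -> NonlinearFitResults:
        config = config or MultistartConfig()
        names = _PARAM_NAMES[self.model_id]
        bdict = dict(default_bounds(self.model_id))
        if bounds:
            bdict.update(bounds)
        lo = np.array([bdict[n][0] for n in names])
        hi = np.array([bdict[n][1] for n in names])
        if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
            raise ValueError("bounds must be finite")
        log_idx = [names.index(n) for n in _LOG_SCALE[self.model_id]]

        sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
        unit = sampler.random(config.n_starts)
        T, robs = self.temperature, self.rate_obs

        def resid(theta: np.ndarray) -> np.ndarray:
            p = self._theta_to_params(theta)
            return rate(self.model_id, p, T) - robs

        best = None
        n_used = 0
        for u in unit:
            x0 = lo + u * (hi - lo)
            for i in log_idx:
                x0[i] = lo[i] * (hi[i] / lo[i]) ** u[i]
            try:
                res = least_squares(
                    resid, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except (ValueError, FloatingPointError):
                continue
            if not res.success:
                continue
            n_used += 1
            if best is None or res.cost < best.cost:
                best = res

        if best is None:
            return NonlinearFitResults(
                model_id=self.model_id,
                params=None,
                critical=CriticalTemps(float("nan"), float("nan"), float("nan")),
                r2=float("nan"), r2_adj=float("nan"), rss=float("nan"),
                n_points=len(T), converged=False, n_starts_used=0,
            )

        theta = best.x
        params = self._theta_to_params(theta)
        rss = float(2.0 * best.cost)
        ss_tot = float(np.sum((robs - robs.mean()) ** 2))
        r2 = 1.0 - rss / ss_tot
        n, k = len(T), len(names)
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if n > k else float("nan")
        tol = 1e-8 * np.maximum(1.0, np.abs(hi - lo))
        at_bounds = tuple(
            names[i]
            for i in range(len(names))
            if theta[i] - lo[i] <= tol[i] or hi[i] - theta[i] <= tol[i]
        )
        return NonlinearFitResults(
            model_id=self.model_id,
            params=params,
            critical=critical_temperatures(self.model_id, params),
            r2=r2,
            r2_adj=r2_adj,
            rss=rss,
            n_points=n,
            converged=True,
            n_starts_used=n_used,
            at_bounds=at_bounds,
        )


def fit(
    model_id: str,
    points: Sequence[RatePoint],
    bounds: dict[str, tuple[float, float]] | None = None,
    config: MultistartConfig | None = None,
) -> NonlinearFitResults:
    """Convenience wrapper: build and fit a :class:`ThermalCurveModel`."""
    return ThermalCurveModel(model_id, points).fit(bounds=bounds, config=config)
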