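"""Sharpe-Schoolfield-Ikemoto (SSI) thermodynamic development-rate model.

The SSI model treats development as controlled by a single rate-limiting
enzyme that is reversibly inactivated at temperature extremes.  With all
temperatures in Kelvin the rate is

            rho_phi * (T/T_opt) * exp[(dH_A/R) * (1/T_opt - 1/T)]
    r(T) = ------------------------------------------------------------
            1 + exp[(dH_L/R)(1/T_L - 1/T)] + exp[(dH_H/R)(1/T_H - 1/T)]

where ``rho_phi`` is the mean developmental rate at the intrinsic optimum
``T_opt``; ``dH_A`` is the activation enthalpy of the catalysed reaction
(cal/mol); ``dH_L < 0`` and ``dH_H > 0`` are the enthalpy changes of low-
and high-temperature inactivation; ``T_L``/``T_H`` are the temperatures at
which the enzyme is half active and half inactivated in the cold/heat; and
``R = 1.987`` cal/deg/mol is the gas constant.

``T_opt`` is the temperature maximising the probability that the enzyme is
in its active state.  That stationarity condition has a closed form,

    1/T_opt = [dH_H/T_H - dH_L/T_L - R ln(-dH_L/dH_H)] / (dH_H - dH_L),

so T_opt is never a free parameter here: it is derived from the four
inactivation parameters, which makes the enzyme-probability argmax and the
reported T_opt identical by construction.

Fitting minimises squared rate residuals by a nested strategy: an exhaustive
grid over (T_L, T_H) with an inner bounded least-squares solve for
(rho_phi, dH_A, dH_L, dH_H), followed by a local polish of the best
candidate over all six free parameters.  The interface is Celsius
throughout; Kelvin conversion happens only inside the evaluations.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .data import RatePoint, StageTable, compute_rates

__all__ = [
    "GAS_CONSTANT_CAL",
    "KELVIN_OFFSET",
    "SSIParams",
    "SSIFitConfig",
    "SSIFitResults",
    "SSIModel",
    "rate_ssi",
    "enzyme_active_probability",
    "intrinsic_optimum",
    "fit_ssi",
]

#: Gas constant in cal / (deg mol); fixed, not configurable.
GAS_CONSTANT_CAL = 1.987
KELVIN_OFFSET = 273.15


def intrinsic_optimum(t_l: float, t_h: float, dh_l: float, dh_h: float) -> float:
    """Closed-form intrinsic optimum temperature (degC).

    Solves d/dT of the enzyme-active probability = 0 for the temperature at
    which the active fraction is maximal.  Requires ``dh_l < 0 < dh_h``.
    """
    if not (dh_l < 0 < dh_h):
        raise ValueError("require dh_l < 0 < dh_h")
    TL = t_l + KELVIN_OFFSET
    TH = t_h + KELVIN_OFFSET
    inv = (dh_h / TH - dh_l / TL - GAS_CONSTANT_CAL * math.log(-dh_l / dh_h)) / (
        dh_h - dh_l
    )
    return 1.0 / inv - KELVIN_OFFSET


@dataclass(frozen=True)
class SSIParams:
    """SSI parameter set; temperatures in degC, enthalpies in cal/mol."""

    rho_phi: float
    t_opt: float
    t_l: float
    t_h: float
    dh_a: float
    dh_l: float
    dh_h: float

    def __post_init__(self) -> None:
        if not self.rho_phi > 0:
            raise ValueError("require rho_phi > 0")
        if not (self.dh_l < 0 < self.dh_h):
            raise ValueError("require dh_l < 0 < dh_h")
        if not (self.t_l < self.t_opt < self.t_h):
            raise ValueError("require t_l < t_opt < t_h")

    @classmethod
    def from_inactivation(
        cls, rho_phi: float, t_l: float, t_h: float, dh_a: float,
        dh_l: float, dh_h: float,
    ) -> "SSIParams":
        """Build a parameter set with t_opt derived from the closed form."""
        return cls(
            rho_phi=rho_phi,
            t_opt=intrinsic_optimum(t_l, t_h, dh_l, dh_h),
            t_l=t_l,
            t_h=t_h,
            dh_a=dh_a,
            dh_l=dh_l,
            dh_h=dh_h,
        )


def _denominator(params: SSIParams, TK: np.ndarray) -> np.ndarray:
    R = GAS_CONSTANT_CAL
    TL = params.t_l + KELVIN_OFFSET
    TH = params.t_h + KELVIN_OFFSET
    return (
        1.0
        + np.exp(params.dh_l / R * (1.0 / TL - 1.0 / TK))
        + np.exp(params.dh_h / R * (1.0 / TH - 1.0 / TK))
    )


def rate_ssi(params: SSIParams, temperature_C):
    """SSI developmental rate (per day) at one or many temperatures (degC)."""
    T = np.asarray(temperature_C, dtype=float)
    scalar = T.ndim == 0
    TK = np.atleast_1d(T) + KELVIN_OFFSET
    TO = params.t_opt + KELVIN_OFFSET
    num = (
        params.rho_phi
        * (TK / TO)
        * np.exp(params.dh_a / GAS_CONSTANT_CAL * (1.0 / TO - 1.0 / TK))
    )
    out = num / _denominator(params, TK)
    return float(out[0]) if scalar else out


def enzyme_active_probability(params: SSIParams, temperature_C):
    """Probability that the rate-controlling enzyme is in its active state."""
    T = np.asarray(temperature_C, dtype=float)
    scalar = T.ndim == 0
    TK = np.atleast_1d(T) + KELVIN_OFFSET
    out = 1.0 / _denominator(params, TK)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class SSIFitConfig:
    """Search design for the nested SSI fit.

    The (T_L, T_H) grid spans half-inactivation temperatures plausibly
    below/above the observed rearing range; the enthalpy boxes encode the
    magnitudes reported across the SSI literature for insect development
    (activation enthalpies of roughly 10-30 kcal/mol, inactivation
    enthalpies one order larger).  All values are user-overridable.
    """

    t_l_range: tuple[float, float] = (8.0, 18.0)
    t_h_range: tuple[float, float] = (30.0, 40.0)
    grid_step: float = 0.5
    rho_bounds: tuple[float, float] = (1e-4, 1.0)
    dh_a_bounds: tuple[float, float] = (1.0e4, 3.0e4)
    dh_l_bounds: tuple[float, float] = (-2.0e5, -1.0e4)
    dh_h_bounds: tuple[float, float] = (1.0e4, 1.0e6)
    seed: int = 20170228

    def __post_init__(self) -> None:
        for lo, hi in (
            self.t_l_range, self.t_h_range, self.rho_bounds,
            self.dh_a_bounds, self.dh_l_bounds, self.dh_h_bounds,
        ):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"infeasible bounds ({lo}, {hi})")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")


@dataclass(frozen=True)
class SSIFitResults:
    """Fitted SSI model plus derived temperatures and goodness of fit."""

    params: SSIParams | None
    t_fast: float
    chi_square: float
    rss: float
    r2: float
    r2_adj: float
    n_points: int
    converged: bool
    at_bounds: tuple[str, ...] = ()

    def predict_rate(self, temperature_C):
        return rate_ssi(self.params, temperature_C)

    def to_dict(self) -> dict:
        return {
            "params": dataclasses.asdict(self.params) if self.params else None,
            "t_fast": self.t_fast,
            "chi_square": self.chi_square,
            "rss": self.rss,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "n_points": self.n_points,
            "converged": self.converged,
            "at_bounds": list(self.at_bounds),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        if self.params is None:
            return "SSI fit: no converged candidate"
        p = self.params
        lines = [
            f"SSI thermodynamic model ({self.n_points} points)",
            f"  rho_phi = {p.rho_phi:.8g} /day   dH_A = {p.dh_a:.6g} cal/mol",
            f"  T_L = {p.t_l:.3f} degC  dH_L = {p.dh_l:.6g} cal/mol",
            f"  T_H = {p.t_h:.3f} degC  dH_H = {p.dh_h:.6g} cal/mol",
            f"  T_opt  = {p.t_opt:.3f} degC (intrinsic optimum)",
            f"  T_fast = {self.t_fast:.3f} degC (rate maximum)",
            f"  X2 = {self.chi_square:.6g}   RSS = {self.rss:.3e}   "
            f"R2_adj = {self.r2_adj:.4f}" if math.isfinite(self.r2_adj)
            else f"  X2 = {self.chi_square:.6g}   RSS = {self.rss:.3e}",
        ]
        if self.at_bounds:
            lines.append(f"  parameters at bounds: {', '.join(self.at_bounds)}")
        return "\n".join(lines)


class SSIModel:
    """Nested grid + polish least-squares fit of the SSI model.

    Parameters
    ----------
    points : sequence of RatePoint
        Rate observations at >= 3 distinct temperatures (>= 5 recommended;
        with six effective free parameters the fit is otherwise purely
        interpolatory).
    """

    def __init__(self, points: Sequence[RatePoint]):
        if len(points) < 3:
            raise ValueError("need at least 3 rate points")
        temps = {p.temperature_C for p in points}
        if len(temps) < 3:
            raise ValueError("need at least 3 distinct temperatures")
        self.points = sorted(points, key=lambda p: p.temperature_C)
        self.temperature = np.array([p.temperature_C for p in self.points])
        self.rate_obs = np.array([p.rate for p in self.points])

    @classmethod
    def from_stage_table(cls, table: StageTable, stage: str,
                         include_temperatures: Sequence[float] | None = None):
        points = compute_rates(table, stage)
        if include_temperatures is not None:
            keep = {float(t) for t in include_temperatures}
            points = [p for p in points if p.temperature_C in keep]
        return cls(points)

    @staticmethod
    def _params_from_theta(theta: np.ndarray) -> SSIParams:
        rho, dh_a, dh_l, dh_h, t_l, t_h = map(float, theta)
        return SSIParams.from_inactivation(rho, t_l, t_h, dh_a, dh_l, dh_h)

    def fit(self, config: SSIFitConfig | None = None) -> SSIFitResults:
        config = config or SSIFitConfig()
        T, robs = self.temperature, self.rate_obs

        def resid4(x: np.ndarray, t_l: float, t_h: float) -> np.ndarray:
            p = self._params_from_theta(np.r_[x, t_l, t_h])
            return rate_ssi(p, T) - robs

        lo4 = np.array([config.rho_bounds[0], config.dh_a_bounds[0],
                        config.dh_l_bounds[0], config.dh_h_bounds[0]])
        hi4 = np.array([config.rho_bounds[1], config.dh_a_bounds[1],
                        config.dh_l_bounds[1], config.dh_h_bounds[1]])
        x0 = np.array([
            float(robs.max()),
            math.sqrt(config.dh_a_bounds[0] * config.dh_a_bounds[1]),
            -8.0e4,
            1.0e5,
        ])
        x0 = np.clip(x0, lo4, hi4)

        t_l_grid = np.arange(config.t_l_range[0], config.t_l_range[1] + 1e-9,
                             config.grid_step)
        t_h_grid = np.arange(config.t_h_range[0], config.t_h_range[1] + 1e-9,
                             config.grid_step)
        best = None
        for t_l in t_l_grid:
            for t_h in t_h_grid:
                try:
                    res = least_squares(
                        resid4, x0, args=(float(t_l), float(t_h)),
                        bounds=(lo4, hi4), method="trf",
                    )
                except (ValueError, FloatingPointError):
                    continue
                if not res.success:
                    continue
                if best is None or res.cost < best[0]:
                    best = (res.cost, res.x, float(t_l), float(t_h))

        if best is None:
            return SSIFitResults(
                params=None, t_fast=float("nan"), chi_square=float("nan"),
                rss=float("nan"), r2=float("nan"), r2_adj=float("nan"),
                n_points=len(T), converged=False,
            )

        _, x4, t_l0, t_h0 = best
        lo6 = np.r_[lo4, config.t_l_range[0], config.t_h_range[0]]
        hi6 = np.r_[hi4, config.t_l_range[1], config.t_h_range[1]]

        def resid6(theta: np.ndarray) -> np.ndarray:
            p = self._params_from_theta(theta)
            return rate_ssi(p, T) - robs

        theta = np.r_[x4, t_l0, t_h0]
        try:
            polish = least_squares(
                resid6, theta, bounds=(lo6, hi6), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if polish.success:
                theta = polish.x
        except (ValueError, FloatingPointError):
            pass  # keep the best grid candidate
        params = self._params_from_theta(theta)
        fitted = rate_ssi(params, T)
        rss = float(np.sum((robs - fitted) ** 2))
        chi2 = float(np.sum((robs - fitted) ** 2 / fitted))
        ss_tot = float(np.sum((robs - robs.mean()) ** 2))
        r2 = 1.0 - rss / ss_tot
        n, k = len(T), 7
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if n > k else float("nan")
        t_fast = float(
            minimize_scalar(
                lambda t: -rate_ssi(params, float(t)),
                bounds=(params.t_l - 10.0, params.t_h + 5.0),
                method="bounded", options={"xatol": 1e-8},
            ).x
        )
        names = ("rho_phi", "dh_a", "dh_l", "dh_h", "t_l", "t_h")
        tol = 1e-8 * np.maximum(1.0, np.abs(hi6 - lo6))
        at_bounds = tuple(
            names[i]
            for i in range(6)
            if theta[i] - lo6[i] <= tol[i] or hi6[i] - theta[i] <= tol[i]
        )
        return SSIFitResults(
            params=params, t_fast=t_fast, chi_square=chi2, rss=rss,
            r2=r2, r2_adj=r2_adj, n_points=n, converged=True,
            at_bounds=at_bounds,
        )


def fit_ssi(points: Sequence[RatePoint], config: SSIFitConfig | None = None) -> SSIFitResults:
    """Convenience wrapper: build and fit an :class:`SSIModel`."""
    return SSIModel(points).fit(config=config)
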