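"""Synthetic developmental cohorts for parameter-recovery experiments.

The generator emulates a constant-temperature rearing study: at each
temperature a cohort of eggs (or larvae) is followed daily, each individual
either dies (independent Bernoulli survival per temperature) or completes
the stage after a duration drawn around the true curve.  Durations are the
deterministic duration 1/r(T) of a chosen true rate model multiplied by
lognormal noise with a given coefficient of variation -- durations are
positive and right-skewed, and the observed SE/mean ratios of laboratory
stage tables (a few percent) map directly onto the cv.  A daily census
rounds each duration up to the next whole day: a moult found at the 24 h
check is recorded on that day's count.

The derived stage table of a simulated cohort (means, SE, n, survival of
survivors) feeds straight back into the fitting models, closing the loop
for bias/RMSE studies of the derived quantities (T_min, K, T_fast, T_opt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import nonlinear, ssi
from .data import RatePoint, StageObservation, StageTable
from .linear import fit_ikemoto_takai, fit_traditional

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "RecoveryReport",
    "true_rate",
    "simulate_cohort",
    "recovery_experiment",
]


def true_rate(true_model: str, params, temperature_C: float) -> float:
    """Rate of the generating model at one temperature.

    ``true_model`` is ``"traditional"`` (``params`` a mapping with ``t_min``
    and ``k``; rate ``(T - t_min)/k``), one of the nonlinear model ids, or
    ``"ssi"`` with an :class:`~thermodev.ssi.SSIParams`.
    """
    if true_model == "traditional":
        return (temperature_C - params["t_min"]) / params["k"]
    if true_model == "ssi":
        return ssi.rate_ssi(params, temperature_C)
    return nonlinear.rate(true_model, params, temperature_C)


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated rearing experiment.

    Defaults mirror a typical laboratory study: cohorts of 100-300
    individuals per temperature, duration noise of a few percent, daily
    census, and high survival except near thermal limits.
    """

    true_model: str
    params: object
    temperatures: tuple[float, ...]
    n_per_temp: int = 100
    cv: float = 0.05
    census_interval: float = 1.0
    survival_curve: Mapping[float, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_temp < 1:
            raise ValueError("n_per_temp must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.census_interval < 0:
            raise ValueError("census_interval must be >= 0")
        for t, s in self.survival_curve.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"survival at {t} degC must lie in [0,1], got {s}")


@dataclass
class SimulatedCohort:
    """Individual records plus the derived stage table of survivors."""

    individuals: pd.DataFrame  # columns: temperature_C, duration_d, survived
    config: SimulationConfig

    def to_stage_table(self, stage: str = "immature_total") -> StageTable:
        obs = []
        for t, grp in self.individuals.groupby("temperature_C", sort=True):
            surv = grp[grp["survived"]]
            n_total = len(grp)
            if len(surv) == 0:
                continue
            d = surv["duration_d"].to_numpy()
            se = float(d.std(ddof=1) / math.sqrt(len(d))) if len(d) > 1 else 0.0
            obs.append(
                StageObservation(
                    stage=stage,
                    temperature_C=float(t),
                    mean_duration_d=float(d.mean()),
                    se_d=se,
                    n=len(d),
                    survival=len(surv) / n_total,
                )
            )
        return StageTable(obs, metadata={"simulated": True, "seed": self.config.seed})


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort per temperature; bit-identical given the seed."""
    rng = np.random.default_rng(config.seed)
    rows = []
    sigma = math.sqrt(math.log(1.0 + config.cv**2))
    for t in config.temperatures:
        surv_p = config.survival_curve.get(t, 1.0)
        r = true_rate(config.true_model, config.params, t)
        if r <= 0 and surv_p > 0:
            raise ValueError(
                f"true rate is non-positive at {t} degC but survival is {surv_p}"
            )
        for _ in range(config.n_per_temp):
            survived = bool(rng.random() < surv_p)
            if config.cv > 0:
                # mean-one lognormal multiplier
                noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
            else:
                noise = 1.0
            duration = (1.0 / r) * noise if r > 0 else math.nan
            if config.census_interval > 0 and r > 0:
                ci = config.census_interval
                duration = math.ceil(duration / ci) * ci
            rows.append((t, duration, survived))
    df = pd.DataFrame(rows, columns=["temperature_C", "duration_d", "survived"])
    return SimulatedCohort(individuals=df, config=config)


@dataclass
class RecoveryReport:
    """Bias and RMSE of derived quantities over simulation replicates."""

    truth: dict[str, float]
    estimates: pd.DataFrame  # one row per replicate
    n_failed: int

    @property
    def bias(self) -> pd.Series:
        return self.estimates.mean() - pd.Series(self.truth)[self.estimates.columns]

    @property
    def rmse(self) -> pd.Series:
        t = pd.Series(self.truth)[self.estimates.columns]
        return ((self.estimates - t) ** 2).mean() ** 0.5

    def summary(self) -> str:
        lines = [f"recovery over {len(self.estimates)} replicates "
                 f"({self.n_failed} failed fits)"]
        for q in self.estimates.columns:
            lines.append(
                f"  {q:8s} truth={self.truth[q]:10.4f} "
                f"mean={self.estimates[q].mean():10.4f} "
                f"bias={self.bias[q]:+.4f} rmse={self.rmse[q]:.4f}"
            )
        return "\n".join(lines)


def _linear_truth(config: SimulationConfig) -> dict[str, float]:
    if config.true_model == "traditional":
        return {"t_min": float(config.params["t_min"]), "k": float(config.params["k"])}
    # for curved truths, the reference is the curve itself
    return {}


def recovery_experiment(
    config: SimulationConfig,
    fit_model: str = "traditional",
    replicates: int = 50,
) -> RecoveryReport:
    """Simulate-fit-compare loop for the linear threshold estimators.

    ``fit_model`` is ``"traditional"`` or ``"ikemoto_takai"``.  Each
    replicate re-seeds the generator deterministically from ``config.seed``;
    fit failures are counted, not fatal.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if fit_model not in ("traditional", "ikemoto_takai"):
        raise ValueError(f"unknown fit_model {fit_model!r}")
    rows = []
    n_failed = 0
    for i in range(replicates):
        cfg = SimulationConfig(
            true_model=config.true_model,
            params=config.params,
            temperatures=config.temperatures,
            n_per_temp=config.n_per_temp,
            cv=config.cv,
            census_interval=config.census_interval,
            survival_curve=config.survival_curve,
            seed=(config.seed + i) % (2**31 - 1),
        )
        cohort = simulate_cohort(cfg)
        table = cohort.to_stage_table()
        try:
            points = [
                RatePoint(o.temperature_C, 1.0 / o.mean_duration_d, float(o.n))
                for o in table.observations
            ]
            if fit_model == "traditional":
                res = fit_traditional(points)
            else:
                res = fit_ikemoto_takai(
                    [(o.temperature_C, o.mean_duration_d) for o in table.observations]
                )
            if not res.ok or not math.isfinite(res.t_min):
                raise ValueError("degenerate fit")
            rows.append({"t_min": res.t_min, "k": res.k})
        except (ValueError, ZeroDivisionError):
            n_failed += 1
    est = pd.DataFrame(rows, columns=["t_min", "k"])
    return RecoveryReport(truth=_linear_truth(config), estimates=est, n_failed=n_failed)
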