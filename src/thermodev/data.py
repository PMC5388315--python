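"""Stage-duration tables and developmental rates.

The empirical unit of this package is the stage-duration table: one row per
(life stage, constant rearing temperature) carrying the cohort mean
development duration in days, its standard error, the cohort size, and the
fraction of individuals that completed the stage.  Developmental rate is the
reciprocal of the mean duration (per day); all model fitting downstream
consumes ``RatePoint`` collections produced here.

A laboratory table for the lesser mulberry pyralid *Glyphodes pyloalis*
reared at 16-32 degC ships as a packaged fixture (``load_example_table``).
For the pooled ``immature_total`` rows of that fixture the 16 degC survival
(4%, six emerged adults) is as reported; the remaining pooled cohort sizes
and survivals are derived from the per-stage values (product of stage
survivals, surviving pupae as cohort size) because they were not reported
per cell.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "STAGES",
    "StageObservation",
    "StageTable",
    "RatePoint",
    "StageTableError",
    "load_stage_table",
    "write_stage_table",
    "load_example_table",
    "compute_rates",
    "select_linear_range",
]

#: Recognised stage labels, innermost to outermost aggregation.
STAGES = (
    "egg",
    "larva_I",
    "larva_II",
    "larva_III",
    "larva_IV",
    "larva_V",
    "larva_VI",
    "larvae_total",
    "prepupa",
    "pupa",
    "immature_total",
)

CSV_COLUMNS = ("stage", "temperature_C", "mean_duration_d", "se_d", "n", "survival")


class StageTableError(ValueError):
    """Raised for malformed stage-duration tables or invalid selections."""


@dataclass(frozen=True)
class StageObservation:
    """One (stage, temperature) record of a rearing experiment.

    Parameters
    ----------
    stage : str
        One of :data:`STAGES`.
    temperature_C : float
        Constant rearing temperature in degrees Celsius.
    mean_duration_d : float
        Mean development duration of the surviving cohort, days (> 0).
    se_d : float, optional
        Standard error of the mean duration, days.
    n : int
        Cohort size entering the stage (>= 1).
    survival : float, optional
        Fraction of the cohort completing the stage, in [0, 1].
    """

    stage: str
    temperature_C: float
    mean_duration_d: float
    se_d: float | None = None
    n: int = 1
    survival: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageTableError(f"unknown stage label {self.stage!r}")
        if not self.mean_duration_d > 0:
            raise StageTableError(
                f"{self.stage} at {self.temperature_C} degC: "
                f"mean_duration_d must be > 0, got {self.mean_duration_d}"
            )
        if self.n < 1:
            raise StageTableError(
                f"{self.stage} at {self.temperature_C} degC: n must be >= 1, got {self.n}"
            )
        if self.se_d is not None and self.se_d < 0:
            raise StageTableError(
                f"{self.stage} at {self.temperature_C} degC: se_d must be >= 0"
            )
        if self.survival is not None and not 0.0 <= self.survival <= 1.0:
            raise StageTableError(
                f"{self.stage} at {self.temperature_C} degC: "
                f"survival must lie in [0, 1], got {self.survival}"
            )

    @property
    def rate(self) -> float:
        """Developmental rate 1/D, per day."""
        return 1.0 / self.mean_duration_d


@dataclass(frozen=True)
class RatePoint:
    """A (temperature, developmental rate) pair fed to the model fits."""

    temperature_C: float
    rate: float
    weight: float | None = None

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise StageTableError(f"rate must be > 0, got {self.rate}")


@dataclass
class StageTable:
    """An ordered collection of :class:`StageObservation` with provenance notes."""

    observations: list[StageObservation]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, float]] = set()
        for obs in self.observations:
            key = (obs.stage, obs.temperature_C)
            if key in seen:
                raise StageTableError(
                    f"duplicate (stage, temperature) pair {key}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def stages(self) -> list[str]:
        out: list[str] = []
        for obs in self.observations:
            if obs.stage not in out:
                out.append(obs.stage)
        return out

    def temperatures(self, stage: str) -> list[float]:
        return [o.temperature_C for o in self.observations if o.stage == stage]

    def observation(self, stage: str, temperature_C: float) -> StageObservation:
        for o in self.observations:
            if o.stage == stage and o.temperature_C == temperature_C:
                return o
        raise StageTableError(f"no observation for {stage} at {temperature_C} degC")

    def survival_by_temp(self, stage: str) -> dict[float, float]:
        return {
            o.temperature_C: o.survival
            for o in self.observations
            if o.stage == stage and o.survival is not None
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": o.stage,
                    "temperature_C": o.temperature_C,
                    "mean_duration_d": o.mean_duration_d,
                    "se_d": o.se_d,
                    "n": o.n,
                    "survival": o.survival,
                }
                for o in self.observations
            ],
            columns=list(CSV_COLUMNS),
        )


def _parse_row(row: Mapping[str, str], index: int, survival_dialect: str) -> StageObservation:
    def _opt(name: str) -> float | None:
        raw = (row.get(name) or "").strip()
        return float(raw) if raw else None

    try:
        surv = _opt("survival")
        if surv is not None and survival_dialect == "percent":
            surv = surv / 100.0
        return StageObservation(
            stage=(row.get("stage") or "").strip(),
            temperature_C=float(row["temperature_C"]),
            mean_duration_d=float(row["mean_duration_d"]),
            se_d=_opt("se_d"),
            n=int(float(row["n"])),
            survival=surv,
        )
    except StageTableError as exc:
        raise StageTableError(f"row {index}: {exc}") from None
    except (KeyError, TypeError, ValueError) as exc:
        raise StageTableError(f"row {index}: malformed value ({exc})") from None


def load_stage_table(path: str | Path, survival_dialect: str = "fraction") -> StageTable:
    """Read a validated stage-duration table from CSV.

    The schema is ``stage,temperature_C,mean_duration_d,se_d,n,survival``
    (``se_d`` and ``survival`` may be blank).  ``survival_dialect`` must be
    ``"fraction"`` or ``"percent"`` and states explicitly how the survival
    column is scaled; there is no auto-detection.
    """
    if survival_dialect not in ("fraction", "percent"):
        raise StageTableError(f"unknown survival dialect {survival_dialect!r}")
    path = Path(path)
    if not path.exists():
        raise StageTableError(f"no such file: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise StageTableError("no observations: empty file")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise StageTableError(f"missing column(s): {', '.join(missing)}")
        observations = [
            _parse_row(row, i, survival_dialect) for i, row in enumerate(reader, start=2)
        ]
    if not observations:
        raise StageTableError("no observations")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    return StageTable(observations, metadata={"source": str(path), "sha256": digest})


def write_stage_table(table: StageTable, path: str | Path) -> None:
    """Write a table back to the canonical CSV schema (survival as fraction)."""
    df = table.to_dataframe()
    df.to_csv(path, index=False)


def load_example_table() -> StageTable:
    """The packaged *G. pyloalis* stage-duration table (16-32 degC)."""
    ref = resources.files("thermodev") / "fixtures" / "glyphodes_table1.csv"
    with resources.as_file(ref) as path:
        table = load_stage_table(path)
    table.metadata["description"] = "G. pyloalis laboratory stage durations"
    return table


def compute_rates(table: StageTable, stage: str) -> list[RatePoint]:
    """Developmental rates 1/D for one stage, ordered by temperature.

    The rate at each temperature is the reciprocal of the per-temperature
    mean duration (not the mean of individual reciprocals); the cohort size
    is carried as an optional weight.
    """
    obs = [o for o in table.observations if o.stage == stage]
    if not obs:
        raise StageTableError(f"unknown stage {stage!r}; table has {table.stages}")
    obs.sort(key=lambda o: o.temperature_C)
    return [RatePoint(o.temperature_C, o.rate, weight=float(o.n)) for o in obs]


def select_linear_range(
    points: Sequence[RatePoint],
    survival_by_temp: Mapping[float, float] | None = None,
    min_survival: float = 0.05,
    exclude_above_peak: bool = True,
    include_temperatures: Iterable[float] | None = None,
) -> list[RatePoint]:
    """Restrict rate points to the linear part of the thermal response.

    Two exclusion rules mirror standard degree-day practice: temperatures
    whose survival falls below ``min_survival`` are unreliable and dropped,
    and (for linear fits) temperatures strictly above the temperature of the
    maximum observed rate lie beyond the linear segment and are dropped when
    ``exclude_above_peak`` is set.  ``include_temperatures`` instead pins an
    explicit inclusion set, overriding both rules.  At least three points
    must survive selection.
    """
    if not points:
        raise StageTableError("no rate points to select from")
    pts = sorted(points, key=lambda p: p.temperature_C)
    if include_temperatures is not None:
        keep_set = {float(t) for t in include_temperatures}
        kept = [p for p in pts if p.temperature_C in keep_set]
    else:
        kept = pts
        if survival_by_temp:
            kept = [
                p
                for p in kept
                if survival_by_temp.get(p.temperature_C, 1.0) >= min_survival
            ]
        if exclude_above_peak and kept:
            t_peak = max(kept, key=lambda p: p.rate).temperature_C
            kept = [p for p in kept if p.temperature_C <= t_peak]
    if len(kept) < 3:
        raise StageTableError(
            f"fewer than 3 points survive selection ({len(kept)} kept)"
        )
    return kept
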