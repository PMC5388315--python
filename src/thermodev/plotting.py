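"""Rate-curve plots for fitted models.

One helper covers all result types: observed rate points as dots, the
fitted curve as a line, and the derived critical temperatures as vertical
markers.  Matplotlib is imported lazily so headless/batch use of the
fitting machinery never pays for it.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .data import RatePoint
from .linear import LinearThresholdResults
from .ssi import SSIFitResults

__all__ = ["plot_rate_curve"]


def plot_rate_curve(
    result,
    points: Sequence[RatePoint] = (),
    ax=None,
    t_range: tuple[float, float] | None = None,
):
    """Plot a fitted development-rate curve with its data and thresholds.

    ``result`` may be a linear, nonlinear or SSI results object.  Returns
    the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()

    if t_range is None:
        if points:
            temps = [p.temperature_C for p in points]
            t_range = (min(temps) - 5.0, max(temps) + 5.0)
        else:
            t_range = (5.0, 40.0)
    grid = np.linspace(*t_range, 400)

    marks: dict[str, float] = {}
    if isinstance(result, LinearThresholdResults):
        curve = np.array([result.predict_rate(t) for t in grid])
        label = f"{result.model_id} linear"
        marks["T_min"] = result.t_min
    elif isinstance(result, SSIFitResults):
        curve = result.predict_rate(grid)
        label = "SSI"
        marks["T_opt"] = result.params.t_opt
        marks["T_fast"] = result.t_fast
    else:
        curve = result.predict_rate(grid)
        label = result.model_id
        marks["T_min"] = result.critical.t_min
        marks["T_max"] = result.critical.t_max
        marks["T_fast"] = result.critical.t_fast

    ax.plot(grid, np.clip(curve, 0.0, None), label=label)
    if points:
        ax.plot(
            [p.temperature_C for p in points],
            [p.rate for p in points],
            "o", color="black", label="observed",
        )
    for name, value in marks.items():
        if value is not None and math.isfinite(value):
            ax.axvline(value, ls=":", lw=0.8, color="grey")
            ax.annotate(name, (value, ax.get_ylim()[1] * 0.95), fontsize=8,
                        rotation=90, va="top")
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel("developmental rate (1/day)")
    ax.legend(fontsize=8)
    return ax
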