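"""Tabular reports of fitted models, mirroring the classic two-table layout
of thermal-biology papers: one table of linear regressions with thresholds
and thermal constants, one table of nonlinear parameter estimates with
T_fast and goodness of fit.  Every report embeds provenance (package
version, input checksum, seed, inclusion set) so a run can be reproduced."""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .linear import LinearThresholdResults
from .nonlinear import NonlinearFitResults
from .ssi import SSIFitResults

__all__ = ["table2_frame", "table3_frame", "provenance", "fits_json"]


def provenance(
    input_sha256: str | None,
    seed: int | None,
    inclusion: Sequence[float] | None,
    extra: Mapping | None = None,
) -> dict:
    out = {
        "package": "thermodev",
        "version": __version__,
        "input_sha256": input_sha256,
        "seed": seed,
        "included_temperatures": list(inclusion) if inclusion is not None else None,
    }
    if extra:
        out.update(extra)
    return out


def table2_frame(results: Sequence[tuple[str, LinearThresholdResults]]) -> pd.DataFrame:
    """Linear-model report: one row per (stage, model)."""
    rows = []
    for stage, res in results:
        rows.append(
            {
                "stage": stage,
                "model": res.model_id,
                "equation": res.equation,
                "R2_pct": 100.0 * res.r2,
                "R2_adj_pct": 100.0 * res.r2_adj,
                "P": res.p_value,
                "T_min": res.t_min,
                "SE_T_min": res.se_t_min,
                "K": res.k,
                "SE_K": res.se_k,
                "n_points": res.n_points,
                "ok": res.ok,
            }
        )
    return pd.DataFrame(rows)


def table3_frame(
    results: Sequence[tuple[str, NonlinearFitResults | SSIFitResults]],
) -> pd.DataFrame:
    """Nonlinear-model report: one row per (stage, model, parameter/derived)."""
    rows = []
    for stage, res in results:
        if isinstance(res, SSIFitResults):
            model = "ssi"
            items = list(dataclasses.asdict(res.params).items()) if res.params else []
            items += [("T_fast", res.t_fast), ("X2", res.chi_square),
                      ("R2_adj", res.r2_adj)]
        else:
            model = res.model_id
            items = list(dataclasses.asdict(res.params).items()) if res.params else []
            items += [
                ("T_min", res.critical.t_min),
                ("T_max", res.critical.t_max),
                ("T_fast", res.critical.t_fast),
                ("R2_adj", res.r2_adj),
            ]
        for name, value in items:
            rows.append({"stage": stage, "model": model, "quantity": name,
                         "value": value})
    return pd.DataFrame(rows)


def fits_json(
    linear: Sequence[tuple[str, LinearThresholdResults]] = (),
    nonlinear: Sequence[tuple[str, NonlinearFitResults | SSIFitResults]] = (),
    prov: Mapping | None = None,
) -> str:
    payload = {
        "provenance": dict(prov) if prov else {},
        "linear": [
            {"stage": s, **r.to_dict()} for s, r in linear
        ],
        "nonlinear": [
            {"stage": s, **r.to_dict()} for s, r in nonlinear
        ],
    }
    return json.dumps(payload, indent=2, default=str)
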