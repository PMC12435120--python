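"""Serialization of results to CSV and JSON.

Floating-point values are written with 9 significant digits; for a
deterministic input the output bytes are deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Union

import pandas as pd

from .cohort import BoundsReport, EmpiricalMetrics
from .exceptions import ParameterError
from .model import Bounds, ScenarioMetrics
from .sweeps import LikelyBand, SweepResult

FLOAT_FORMAT = "%.9g"


def _round9(value: float) -> float:
    return float(f"{value:.9g}")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Bounds):
        return {"lower": _round9(obj.lower), "upper": _round9(obj.upper)}
    if isinstance(obj, float):
        return _round9(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def result_to_dict(result) -> dict:
    """A JSON-ready dict for any supported result object."""
    if isinstance(result, SweepResult):
        return {
            "kind": "sweep",
            "parameter": result.spec.parameter,
            "columns": list(result.table.columns),
            "rows": _jsonable(result.table.to_numpy().tolist()),
        }
    if isinstance(result, ScenarioMetrics):
        return {
            "kind": "scenario",
            "strategy": result.strategy,
            "rr": _jsonable(result.rr),
            "epd": _jsonable(result.epd),
            "units": {"rr": "fraction", "epd": "seconds"},
        }
    if isinstance(result, LikelyBand):
        return {
            "kind": "band",
            "mode": result.mode,
            "agreement_interval": _jsonable(list(result.agreement_interval)),
            "columns": list(result.table.columns),
            "rows": _jsonable(result.table.to_numpy().tolist()),
        }
    if isinstance(result, EmpiricalMetrics):
        return {
            "kind": "empirical",
            "rr": _round9(result.rr),
            "epd": _round9(result.epd),
            "counts": dict(result.counts),
            "units": {"rr": "fraction", "epd": "seconds"},
        }
    if isinstance(result, BoundsReport):
        return {
            "kind": "bounds_report",
            "analytic": result_to_dict(result.analytic),
            "n_couplings": len(result.outcomes),
            "n_violations": len(result.violations),
            "extremes_attained": result.extremes_attained,
            "tolerance": _round9(result.tolerance),
            "violations": [
                {
                    "coupling": {"mode": o.coupling.mode, "value": o.coupling.value},
                    "rr": _round9(o.rr),
                    "epd": _round9(o.epd),
                }
                for o in result.violations
            ],
            "outcomes": [
                {
                    "coupling": {
                        "mode": o.coupling.mode,
                        "value": None
                        if o.coupling.value is None
                        else _round9(o.coupling.value),
                    },
                    "rr": _round9(o.rr),
                    "epd": _round9(o.epd),
                    "within_bounds": o.within_bounds,
                }
                for o in result.outcomes
            ],
        }
    raise ParameterError(f"unsupported result type: {type(result).__name__}")


def write_results(result, path: Union[str, Path], format: str = "csv") -> Path:
    """Write a result object to ``path`` as CSV or JSON; returns the path.

    Tabular results (sweeps, bands, cohort records) support both formats;
    scalar results (scenario metrics, reports) are JSON only.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format not in ("csv", "json"):
        raise ParameterError(f"format must be 'csv' or 'json', got {format!r}")
    if format == "csv":
        if isinstance(result, (SweepResult, LikelyBand)):
            table = result.table
        elif isinstance(result, pd.DataFrame):
            table = result
        else:
            raise ParameterError(
                f"{type(result).__name__} has no tabular form; use format='json'"
            )
        table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    else:
        if isinstance(result, pd.DataFrame):
            payload = {
                "kind": "records",
                "columns": list(result.columns),
                "rows": _jsonable(result.to_numpy().tolist()),
            }
        else:
            payload = result_to_dict(result)
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    return path


def read_sweep_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a sweep/band CSV written by :func:`write_results`."""
    return pd.read_csv(path)
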