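"""One-at-a-time parameter sweeps, breakpoint detection and likely bands.

A sweep varies a single model parameter over an ordered grid, holding every
other parameter at its configured value, and evaluates all three strategies
at each grid point.  The bound curves are piecewise linear in any single
parameter; :func:`detect_breakpoints` locates the kinks and refines them by
bisection on the analytic curve.  :func:`likely_band` narrows the
theoretical corridor using an agreement-accuracy interval for an AI reader
trained to emulate the radiologist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .model import (
    ModelConfig,
    OperatingPoint,
    ProtocolTiming,
    adaptive_bounds,
    confusion_rates,
    default_config,
    epd_abbreviated_only,
    metrics_full_only,
    rr_abbreviated_only,
)

#: Sweepable parameter names mapped to (kind, domain description).
SWEEPABLE_PARAMETERS = {
    "ai_sensitivity": "rate",
    "ai_specificity": "rate",
    "rad_sensitivity_abbr": "rate",
    "rad_specificity_abbr": "rate",
    "t_full": "duration",
    "t_abbr": "duration",
}

METRIC_COLUMNS = (
    "rr_abbr_only",
    "rr_full_only",
    "rr_adaptive_lower",
    "rr_adaptive_upper",
    "epd_abbr_only",
    "epd_full_only",
    "epd_adaptive_lower",
    "epd_adaptive_upper",
)

#: Slope-change detection thresholds on second differences.
RR_BREAK_TOL = 1e-8
EPD_BREAK_TOL = 1e-5


def _validate_grid(parameter: str, grid: Sequence[float]) -> Tuple[float, ...]:
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ParameterError(
            f"parameter must be one of {sorted(SWEEPABLE_PARAMETERS)}, "
            f"got {parameter!r}"
        )
    values = tuple(float(v) for v in grid)
    if len(values) == 0:
        raise ParameterError("grid must be non-empty")
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ParameterError("grid must be strictly increasing")
    kind = SWEEPABLE_PARAMETERS[parameter]
    for v in values:
        if kind == "rate" and not 0.0 <= v <= 1.0:
            raise ParameterError(f"grid value {v!r} outside [0, 1] for {parameter}")
        if kind == "duration" and v <= 0.0:
            raise ParameterError(f"grid value {v!r} not positive for {parameter}")
    return values


def default_grid(parameter: str, config: ModelConfig | None = None, n: int = 1001):
    """Uniform default grid: [0, 1] for rates, [d/2, 2d] for durations."""
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ParameterError(f"unknown parameter {parameter!r}")
    if SWEEPABLE_PARAMETERS[parameter] == "rate":
        return np.linspace(0.0, 1.0, n)
    config = config or default_config()
    d = getattr(config, parameter)
    return np.linspace(0.5 * d, 2.0 * d, n)


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter sweep: which parameter, over which grid, around
    which fixed configuration."""

    parameter: str
    grid: Tuple[float, ...]
    fixed: ModelConfig = field(default_factory=default_config)

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", _validate_grid(self.parameter, self.grid))

    def config_at(self, value: float) -> ModelConfig:
        return self.fixed.with_value(**{self.parameter: value})


@dataclass(frozen=True)
class SweepResult:
    """Evaluated sweep: one row per grid value, in grid order."""

    spec: SweepSpec
    table: pd.DataFrame

    def curve(self, column: str) -> np.ndarray:
        return self.table[column].to_numpy()


def evaluate_config(config: ModelConfig) -> Dict[str, float]:
    """All strategy metrics for one full parameter set."""
    cohort = config.cohort()
    timing = config.timing()
    rad = confusion_rates(config.rad_abbr, cohort)
    adaptive = adaptive_bounds(config.rad_abbr, config.ai, cohort, timing)
    full = metrics_full_only(timing)
    return {
        "rr_abbr_only": rr_abbreviated_only(rad),
        "rr_full_only": full.rr,
        "rr_adaptive_lower": adaptive.rr.lower,
        "rr_adaptive_upper": adaptive.rr.upper,
        "epd_abbr_only": epd_abbreviated_only(rad, timing),
        "epd_full_only": full.epd,
        "epd_adaptive_lower": adaptive.epd.lower,
        "epd_adaptive_upper": adaptive.epd.upper,
    }


def run_sweep(spec: SweepSpec, normalized: bool = False) -> SweepResult:
    """Evaluate all three strategies at every grid value.

    With ``normalized=True``, adds ``*_pct_full`` columns expressing each
    duration as a percentage of that row's full-protocol duration.
    """
    rows = []
    for value in spec.grid:
        metrics = evaluate_config(spec.config_at(value))
        metrics["value"] = value
        rows.append(metrics)
    table = pd.DataFrame(rows, columns=["value", *METRIC_COLUMNS])
    if normalized:
        for col in ("epd_abbr_only", "epd_full_only",
                    "epd_adaptive_lower", "epd_adaptive_upper"):
            table[col + "_pct_full"] = 100.0 * table[col] / table["epd_full_only"]
    return SweepResult(spec=spec, table=table)


# ---------------------------------------------------------------------------
# Breakpoint detection
# ---------------------------------------------------------------------------


def curve_function(spec: SweepSpec, column: str) -> Callable[[float], float]:
    """The analytic curve behind one sweep column, evaluable anywhere."""
    if column.endswith("_pct_full"):
        base = column[: -len("_pct_full")]

        def f(x: float) -> float:
            m = evaluate_config(spec.config_at(x))
            return 100.0 * m[base] / m["epd_full_only"]

        return f
    if column not in METRIC_COLUMNS:
        raise ParameterError(f"unknown curve column {column!r}")

    def f(x: float) -> float:
        return evaluate_config(spec.config_at(x))[column]

    return f


def _is_linear(f: Callable[[float], float], a: float, b: float, tol: float) -> bool:
    mid = f(0.5 * (a + b))
    return abs(mid - 0.5 * (f(a) + f(b))) <= tol


def _refine_kink(
    f: Callable[[float], float],
    a: float,
    b: float,
    lin_tol: float,
    xtol: float = 1e-9,
) -> float:
    """Bisect for the kink of a piecewise-linear f known to lie in (a, b)."""
    while b - a > xtol:
        m = 0.5 * (a + b)
        if not _is_linear(f, a, m, lin_tol):
            b = m
        elif not _is_linear(f, m, b, lin_tol):
            a = m
        else:  # kink sits exactly at m (both halves affine)
            return m
    return 0.5 * (a + b)


def detect_breakpoints(
    result: SweepResult,
    column: str,
    tolerance: float | None = None,
) -> List[float]:
    """Locations where a sweep curve's slope changes.

    Scans second differences on the (uniform) grid, then refines each
    candidate to at least 1e-6 by bisection on the analytic curve.
    Returns an empty list for affine curves.
    """
    x = result.table["value"].to_numpy()
    if len(x) < 3:
        raise ParameterError("grid too short for breakpoint detection")
    steps = np.diff(x)
    h = steps[0]
    if not np.allclose(steps, h, rtol=1e-9, atol=1e-12 * max(1.0, abs(h))):
        raise ParameterError("breakpoint detection requires a uniform grid")
    if tolerance is None:
        tolerance = RR_BREAK_TOL if column.startswith("rr") else EPD_BREAK_TOL

    y = result.curve(column)
    d2 = y[2:] - 2.0 * y[1:-1] + y[:-2]
    flagged = np.flatnonzero(np.abs(d2) > tolerance) + 1  # index into x

    f = curve_function(result.spec, column)
    scale = max(1.0, float(np.max(np.abs(y))))
    lin_tol = 1e-12 * scale

    breakpoints: List[float] = []
    i = 0
    while i < len(flagged):
        j = i
        while j + 1 < len(flagged) and flagged[j + 1] == flagged[j] + 1:
            j += 1
        a, b = x[flagged[i] - 1], x[flagged[j] + 1]
        bp = _refine_kink(f, a, b, lin_tol)
        if not breakpoints or abs(bp - breakpoints[-1]) > 1e-6:
            breakpoints.append(bp)
        i = j + 1
    return breakpoints


# ---------------------------------------------------------------------------
# Likely band
# ---------------------------------------------------------------------------

BAND_MODES = ("emulation", "restricted_limits")


def emulated_operating_point(rad_op: OperatingPoint, q: float) -> OperatingPoint:
    """Operating point of an AI that reproduces each radiologist decision
    independently with per-person agreement probability q."""
    return OperatingPoint(
        sensitivity=q * rad_op.sensitivity + (1.0 - q) * (1.0 - rad_op.sensitivity),
        specificity=q * rad_op.specificity + (1.0 - q) * (1.0 - rad_op.specificity),
    )


def emulation_metrics(
    config: ModelConfig, q: float
) -> Tuple[float, float]:
    """(rr, epd) of the adaptive strategy with an agreement-q emulating AI.

    The AI agrees with the radiologist's flag decision with probability q,
    so overlap = q * flag_rate and the AI flag rate is
    q * flag_rate + (1 - q) * (1 - flag_rate); both metrics follow from
    the standard formulas.
    """
    if not 0.0 <= q <= 1.0:
        raise ParameterError(f"agreement q must lie in [0, 1], got {q!r}")
    timing = config.timing()
    rad = confusion_rates(config.rad_abbr, config.cohort())
    flag = rad.flag_rate
    rr = (1.0 - q) * flag
    ai_flag = q * flag + (1.0 - q) * (1.0 - flag)
    epd = timing.t_full * (ai_flag + rr) + timing.t_abbr * (1.0 - ai_flag)
    return rr, epd


@dataclass(frozen=True)
class LikelyBand:
    """Per-grid-value plausible corridor, clipped to the theoretical limits."""

    agreement_interval: Tuple[float, float]
    mode: str
    table: pd.DataFrame  # value, rr_band_lower/upper, epd_band_lower/upper


def _clip_band(lo: float, hi: float, th_lo: float, th_hi: float) -> Tuple[float, float]:
    lo = min(max(lo, th_lo), th_hi)
    hi = min(max(hi, th_lo), th_hi)
    return (lo, hi) if lo <= hi else (hi, lo)


def likely_band(
    spec: SweepSpec,
    agreement_interval: Tuple[float, float] = (0.75, 0.91),
    mode: str = "emulation",
    result: SweepResult | None = None,
) -> LikelyBand:
    """Band of plausible adaptive performance along a sweep.

    Modes:

    ``emulation`` (default)
        The AI reproduces each radiologist decision independently with
        agreement probability q ranging over the interval; the band is the
        envelope over q (both metrics are affine in q, so the endpoints
        suffice).

    ``restricted_limits``
        The theoretical limits re-evaluated with the AI operating point
        restricted to the interval: a swept AI parameter is clamped into
        it, and for non-AI sweeps both AI parameters range over the
        interval (envelope over an 11x11 grid).

    Either way the band is clipped into the theoretical corridor at every
    grid value.
    """
    low, high = (float(agreement_interval[0]), float(agreement_interval[1]))
    if not 0.0 <= low <= high <= 1.0:
        raise ParameterError(
            f"agreement_interval must satisfy 0 <= low <= high <= 1, "
            f"got ({low!r}, {high!r})"
        )
    if mode not in BAND_MODES:
        raise ParameterError(
            f"unknown band mode {mode!r}; available modes: {BAND_MODES}"
        )
    if result is None:
        result = run_sweep(spec)

    rows = []
    for _, row in result.table.iterrows():
        value = row["value"]
        config = spec.config_at(value)
        if mode == "emulation":
            pts = [emulation_metrics(config, q) for q in (low, high)]
        else:
            if spec.parameter.startswith("ai_"):
                clamped = min(max(value, low), high)
                ai_grid = [spec.config_at(clamped).ai]
            else:
                qs = np.linspace(low, high, 11)
                ai_grid = [
                    OperatingPoint(se, sp) for se in qs for sp in qs
                ]
            pts = []
            for ai_op in ai_grid:
                m = adaptive_bounds(
                    config.rad_abbr, ai_op, config.cohort(), config.timing()
                )
                pts.append((m.rr.lower, m.epd.lower))
                pts.append((m.rr.upper, m.epd.upper))
        rr_vals = [p[0] for p in pts]
        epd_vals = [p[1] for p in pts]
        rr_lo, rr_hi = _clip_band(
            min(rr_vals), max(rr_vals),
            row["rr_adaptive_lower"], row["rr_adaptive_upper"],
        )
        epd_lo, epd_hi = _clip_band(
            min(epd_vals), max(epd_vals),
            row["epd_adaptive_lower"], row["epd_adaptive_upper"],
        )
        rows.append(
            {
                "value": value,
                "rr_band_lower": rr_lo,
                "rr_band_upper": rr_hi,
                "epd_band_lower": epd_lo,
                "epd_band_upper": epd_hi,
            }
        )
    return LikelyBand(
        agreement_interval=(low, high), mode=mode, table=pd.DataFrame(rows)
    )


def percent_reduction_vs_full(epd: float, timing: ProtocolTiming) -> float:
    """Reduction of an expected duration relative to the full protocol, in %."""
    return 100.0 * (timing.t_full - epd) / timing.t_full
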