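"""Cohort-level oracle for the analytic bounds.

Generates per-person (diseased, rad_flag, ai_flag) records under a
controllable coupling between the two readers, accounts recall rate and
expected duration empirically, and checks that the empirical values stay
inside the analytic corridor.  Within each disease stratum the joint flag
distribution is a 2x2 table whose marginals come from the operating points
and whose both-flag cell is set by the coupling: the Frechet extremes
(max/min overlap), independence, or a fixed overlap value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import FeasibilityError, ParameterError
from .model import (
    Cohort,
    ConfusionRates,
    OperatingPoint,
    ProtocolTiming,
    ScenarioMetrics,
    adaptive_bounds,
    confusion_rates,
    overlap_bounds,
)

COUPLING_MODES = ("max_overlap", "min_overlap", "independent", "fixed_overlap")

RECORD_COLUMNS = ("person", "diseased", "rad_flag", "ai_flag")


@dataclass(frozen=True)
class CouplingSpec:
    """How the radiologist's and AI's flag decisions are coupled.

    ``fixed_overlap`` requires ``value``: the target unconditional
    probability that both readers flag the same person.  It must lie in
    the feasible range implied by the operating points; the per-stratum
    split is chosen linearly between the stratified extremes so the total
    matches exactly.
    """

    mode: str
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in COUPLING_MODES:
            raise ParameterError(
                f"mode must be one of {COUPLING_MODES}, got {self.mode!r}"
            )
        if self.mode == "fixed_overlap":
            if self.value is None:
                raise ParameterError("fixed_overlap coupling requires a value")
            if not 0.0 <= float(self.value) <= 1.0:
                raise ParameterError(
                    f"fixed overlap value must lie in [0, 1], got {self.value!r}"
                )
        elif self.value is not None:
            raise ParameterError(f"coupling mode {self.mode!r} takes no value")


@dataclass(frozen=True)
class EmpiricalMetrics:
    """Empirically accounted recall rate, duration and confusion counts."""

    rr: float
    epd: float
    counts: Dict[str, int]


def _stratum_overlaps(
    rad: ConfusionRates, ai: ConfusionRates, coupling: CouplingSpec
) -> Tuple[float, float]:
    """Unconditional both-flag probability per (diseased, healthy) stratum."""
    p = rad.prevalence
    # Per-stratum Frechet extremes, unconditional.
    d_min = max(0.0, rad.tp + ai.tp - p)
    d_max = min(rad.tp, ai.tp)
    h_min = max(0.0, rad.fp + ai.fp - (1.0 - p))
    h_max = min(rad.fp, ai.fp)
    if coupling.mode == "max_overlap":
        return d_max, h_max
    if coupling.mode == "min_overlap":
        return d_min, h_min
    if coupling.mode == "independent":
        d = rad.tp * ai.tp / p if p > 0 else 0.0
        h = rad.fp * ai.fp / (1.0 - p) if p < 1 else 0.0
        return d, h
    # fixed_overlap: linear interpolation between the stratified extremes
    total_min, total_max = d_min + h_min, d_max + h_max
    value = float(coupling.value)
    if not total_min - 1e-12 <= value <= total_max + 1e-12:
        raise FeasibilityError(
            f"fixed overlap {value!r} outside feasible interval "
            f"[{total_min!r}, {total_max!r}]"
        )
    span = total_max - total_min
    t = 0.0 if span <= 0 else (value - total_min) / span
    return d_min + t * (d_max - d_min), h_min + t * (h_max - h_min)


def _largest_remainder(expected: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative expected counts to integers summing to ``total``.

    Ties and the distribution of leftover units follow descending
    fractional remainder, with earlier cells (the overlap cell is listed
    first) winning ties, so the rounding is deterministic.
    """
    expected = np.asarray(expected, dtype=float)
    floors = np.floor(expected + 1e-9).astype(np.int64)  # absorb fp dust
    short = total - int(floors.sum())
    if short < 0:  # over-allocated by the dust absorption; trim largest cells
        for idx in np.argsort(-floors, kind="stable")[:-short]:
            floors[idx] -= 1
    else:
        remainder = expected - floors
        for idx in np.argsort(-remainder, kind="stable")[:short]:
            floors[idx] += 1
    return floors


def _stratum_cells(
    n: int, rad_rate: float, ai_rate: float, overlap: float
) -> np.ndarray:
    """Expected counts of (both, rad only, ai only, neither) in a stratum."""
    cells = np.array(
        [
            overlap,
            rad_rate - overlap,
            ai_rate - overlap,
            1.0 - rad_rate - ai_rate + overlap,
        ]
    )
    if np.any(cells < -1e-9):
        raise FeasibilityError(
            f"infeasible stratum table for overlap {overlap!r} with "
            f"marginals ({rad_rate!r}, {ai_rate!r})"
        )
    return np.clip(cells, 0.0, None) * n


def simulate_cohort(
    cohort: Cohort,
    rad_op: OperatingPoint,
    ai_op: OperatingPoint,
    coupling: CouplingSpec,
    seed: Optional[int] = None,
    sampling: str = "expected_counts",
) -> pd.DataFrame:
    """Generate per-person records under a chosen reader coupling.

    ``expected_counts`` emits deterministic counts rounded by largest
    remainder (overlap cell first) so totals are exact; ``multinomial``
    draws a seeded random cohort with the same cell probabilities.
    Returns a DataFrame with columns person, diseased, rad_flag, ai_flag.
    """
    if cohort.size is None:
        raise ParameterError("simulate_cohort requires a cohort with a finite size")
    if sampling not in ("multinomial", "expected_counts"):
        raise ParameterError(
            f"sampling must be 'multinomial' or 'expected_counts', got {sampling!r}"
        )
    n = cohort.size
    p = cohort.prevalence
    rad = confusion_rates(rad_op, cohort)
    ai = confusion_rates(ai_op, cohort)
    ov_d, ov_h = _stratum_overlaps(rad, ai, coupling)

    if sampling == "expected_counts":
        n_diseased = int(_largest_remainder(np.array([n * p, n * (1 - p)]), n)[0])
    else:
        rng = np.random.default_rng(seed)
        n_diseased = int(rng.binomial(n, p))
    strata = []
    for diseased, n_s, mass, r_rate, a_rate, ov in (
        (1, n_diseased, p, rad_op.sensitivity, ai_op.sensitivity, ov_d),
        (
            0,
            n - n_diseased,
            1.0 - p,
            1.0 - rad_op.specificity,
            1.0 - ai_op.specificity,
            ov_h,
        ),
    ):
        if n_s == 0:
            continue
        cond_ov = ov / mass if mass > 0 else 0.0
        cells = _stratum_cells(n_s, r_rate, a_rate, cond_ov)
        if sampling == "expected_counts":
            counts = _largest_remainder(cells, n_s)
        else:
            pvals = cells / cells.sum()
            counts = rng.multinomial(n_s, pvals)
        strata.append((diseased, counts))

    # cell order: (rad=1, ai=1), (rad=1, ai=0), (rad=0, ai=1), (rad=0, ai=0)
    flags = np.array([(1, 1), (1, 0), (0, 1), (0, 0)], dtype=np.int8)
    diseased_col = np.concatenate(
        [np.full(int(c.sum()), d, dtype=np.int8) for d, c in strata]
    )
    rad_col = np.concatenate([np.repeat(flags[:, 0], c) for _, c in strata])
    ai_col = np.concatenate([np.repeat(flags[:, 1], c) for _, c in strata])
    return pd.DataFrame(
        {
            "person": np.arange(n, dtype=np.int64),
            "diseased": diseased_col,
            "rad_flag": rad_col,
            "ai_flag": ai_col,
        }
    )


def empirical_metrics(records: pd.DataFrame, timing: ProtocolTiming) -> EmpiricalMetrics:
    """Account recall rate and expected duration from raw records.

    A person is recalled when the radiologist flags but the AI does not.
    AI-flagged people get a full scan up front; everyone else gets the
    abbreviated scan; recalled people add a full-protocol visit.
    """
    if len(records) == 0:
        raise ParameterError("records must be non-empty")
    n = len(records)
    diseased = records["diseased"].to_numpy(dtype=bool)
    rad = records["rad_flag"].to_numpy(dtype=bool)
    ai = records["ai_flag"].to_numpy(dtype=bool)
    recalled = int(np.sum(rad & ~ai))
    n_ai = int(np.sum(ai))
    counts = {
        "n": n,
        "rad_tp": int(np.sum(rad & diseased)),
        "rad_fp": int(np.sum(rad & ~diseased)),
        "rad_tn": int(np.sum(~rad & ~diseased)),
        "rad_fn": int(np.sum(~rad & diseased)),
        "ai_tp": int(np.sum(ai & diseased)),
        "ai_fp": int(np.sum(ai & ~diseased)),
        "ai_tn": int(np.sum(~ai & ~diseased)),
        "ai_fn": int(np.sum(~ai & diseased)),
        "overlap": int(np.sum(rad & ai)),
        "recalled": recalled,
    }
    total_time = timing.t_full * (n_ai + recalled) + timing.t_abbr * (n - n_ai)
    return EmpiricalMetrics(rr=recalled / n, epd=total_time / n, counts=counts)


@dataclass(frozen=True)
class CouplingOutcome:
    """One coupling's empirical metrics and containment status."""

    coupling: CouplingSpec
    rr: float
    epd: float
    within_bounds: bool


@dataclass(frozen=True)
class BoundsReport:
    """Outcome of validating the analytic bounds against simulated cohorts."""

    analytic: ScenarioMetrics
    outcomes: List[CouplingOutcome]
    violations: List[CouplingOutcome]
    extremes_attained: bool
    tolerance: float


def validate_bounds(
    cohort: Cohort,
    rad_op: OperatingPoint,
    ai_op: OperatingPoint,
    timing: ProtocolTiming,
    n_random_couplings: int = 100,
    seed: Optional[int] = None,
    sampling: str = "expected_counts",
) -> BoundsReport:
    """Empirically confirm the analytic corridor.

    Simulates the two extreme couplings plus ``n_random_couplings`` random
    feasible fixed-overlap couplings and checks every empirical (rr, epd)
    against the analytic bounds, with a 1/N allowance for count rounding.
    Violations are reported, not raised.
    """
    if cohort.size is None:
        raise ParameterError("validate_bounds requires a cohort with a finite size")
    analytic = adaptive_bounds(rad_op, ai_op, cohort, timing)
    rad = confusion_rates(rad_op, cohort)
    ai = confusion_rates(ai_op, cohort)
    ov = overlap_bounds(rad, ai)

    rng = np.random.default_rng(seed)
    couplings = [CouplingSpec("max_overlap"), CouplingSpec("min_overlap")]
    hi = max(ov.minimum, ov.maximum)  # forced-equal bounds can differ by fp dust
    for _ in range(n_random_couplings):
        value = min(float(rng.uniform(ov.minimum, hi)), ov.maximum)
        couplings.append(CouplingSpec("fixed_overlap", value))

    tol_rr = 4.0 / cohort.size
    tol_epd = tol_rr * 2.0 * max(timing.t_abbr, timing.t_full)
    outcomes: List[CouplingOutcome] = []
    for i, coupling in enumerate(couplings):
        records = simulate_cohort(
            cohort, rad_op, ai_op, coupling,
            seed=None if seed is None else seed + i,
            sampling=sampling,
        )
        emp = empirical_metrics(records, timing)
        ok = (
            analytic.rr.lower - tol_rr <= emp.rr <= analytic.rr.upper + tol_rr
            and analytic.epd.lower - tol_epd <= emp.epd <= analytic.epd.upper + tol_epd
        )
        outcomes.append(CouplingOutcome(coupling, emp.rr, emp.epd, ok))

    extremes_attained = (
        abs(outcomes[0].rr - analytic.rr.lower) <= tol_rr
        and abs(outcomes[0].epd - analytic.epd.lower) <= tol_epd
        and abs(outcomes[1].rr - analytic.rr.upper) <= tol_rr
        and abs(outcomes[1].epd - analytic.epd.upper) <= tol_epd
    )
    violations = [o for o in outcomes if not o.within_bounds]
    return BoundsReport(
        analytic=analytic,
        outcomes=outcomes,
        violations=violations,
        extremes_attained=extremes_attained,
        tolerance=tol_rr,
    )
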