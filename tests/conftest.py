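"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from screenbounds import (
    Cohort,
    ModelConfig,
    OperatingPoint,
    ProtocolTiming,
    default_config,
)


@pytest.fixture
def config() -> ModelConfig:
    return default_config()


@pytest.fixture
def rad_op() -> OperatingPoint:
    return OperatingPoint(0.90, 0.92)


@pytest.fixture
def ai_op() -> OperatingPoint:
    return OperatingPoint(0.80, 0.80)


@pytest.fixture
def cohort() -> Cohort:
    return Cohort(0.0146)


@pytest.fixture
def timing() -> ProtocolTiming:
    return ProtocolTiming(262.0, 776.0)


def brute_force_overlap_bounds(
    rad_op: OperatingPoint,
    ai_op: OperatingPoint,
    prevalence: float,
    step: float = 1e-6,
) -> tuple[float, float]:
    """Feasible-overlap extremes found by exhaustive scan, not by formula.

    Per disease stratum, scans every candidate both-flag probability on a
    uniform grid over [0, stratum mass] and keeps those for which all four
    cells of the joint 2x2 flag table are non-negative.  The stratum-wise
    extremes sum to the global extremes because the strata are disjoint.
    """
    total_min = total_max = 0.0
    strata = (
        (prevalence, prevalence * rad_op.sensitivity, prevalence * ai_op.sensitivity),
        (
            1.0 - prevalence,
            (1.0 - prevalence) * (1.0 - rad_op.specificity),
            (1.0 - prevalence) * (1.0 - ai_op.specificity),
        ),
    )
    for mass, r, a in strata:
        if mass <= 0.0:
            continue
        cand = np.arange(0.0, mass + step, step)
        # slack of just over half a grid step: a zero-width feasible
        # interval always has a candidate within step/2 of it
        tol = 0.6 * step
        feasible = (
            (r - cand >= -tol)
            & (a - cand >= -tol)
            & (mass - r - a + cand >= -tol)
        )
        values = cand[feasible]
        assert values.size > 0, "no feasible joint table found"
        total_min += float(values.min())
        total_max += float(values.max())
    return total_min, total_max


def expected_count_table(
    n: int, op: OperatingPoint, prevalence: float
) -> dict[str, float]:
    """Expected confusion counts for a finite cohort, by direct enumeration
    of the four outcome categories."""
    n_dis = n * prevalence
    n_heal = n - n_dis
    return {
        "tp": n_dis * op.sensitivity,
        "fn": n_dis * (1.0 - op.sensitivity),
        "tn": n_heal * op.specificity,
        "fp": n_heal * (1.0 - op.specificity),
    }
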