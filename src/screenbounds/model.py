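"""Analytic engine for adaptive two-stage screening protocols.

Everything is computed per screened person (probability form): true/false
positive symbols denote per-person probabilities, and counts for a finite
cohort are recovered by multiplying by the cohort size.  Three strategies
are modelled:

``abbreviated_only``
    Everyone receives the short protocol; people flagged by the radiologist
    return for a full-protocol visit (recall).

``full_only``
    Everyone receives the full protocol immediately; recall rate is zero.

``adaptive``
    Everyone starts on the short protocol; an AI reader decides on the spot
    whether to continue with the full protocol.  People flagged by the
    radiologist but *not* by the AI are recalled.  Because the joint
    behaviour of the two readers is unknown, the recall rate and the
    expected duration are reported as sharp lower/upper limits obtained
    from the extreme admissible overlaps between the two readers' flag
    sets (Frechet-Hoeffding bounds applied within each disease stratum).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Union

from .exceptions import ConsistencyError, FeasibilityError, ParameterError

logger = logging.getLogger(__name__)

#: Absolute tolerance for probability comparisons.
PROB_ATOL = 1e-9
#: Absolute tolerance for duration comparisons, in seconds.
DURATION_ATOL = 1e-6


def _check_fraction(value: float, name: str) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ParameterError(f"{name} must be a number, got {value!r}")
    value = float(value)
    if math.isnan(value) or not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")
    return value


def _check_positive(value: float, name: str) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ParameterError(f"{name} must be a number, got {value!r}")
    value = float(value)
    if math.isnan(value) or value <= 0.0:
        raise ParameterError(f"{name} must be positive, got {value!r}")
    return value


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OperatingPoint:
    """A reader's (sensitivity, specificity) pair, both fractions in [0, 1]."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sensitivity", _check_fraction(self.sensitivity, "sensitivity")
        )
        object.__setattr__(
            self, "specificity", _check_fraction(self.specificity, "specificity")
        )


@dataclass(frozen=True)
class Cohort:
    """A screened population: disease prevalence and optional finite size.

    ``size=None`` marks a rates-only cohort where all quantities stay
    per-person probabilities.
    """

    prevalence: float
    size: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "prevalence", _check_fraction(self.prevalence, "prevalence")
        )
        if self.size is not None:
            if not isinstance(self.size, int) or isinstance(self.size, bool) or self.size <= 0:
                raise ParameterError(
                    f"size must be a positive integer or None, got {self.size!r}"
                )


@dataclass(frozen=True)
class ProtocolTiming:
    """Durations in seconds of the abbreviated and full protocols."""

    t_abbr: float
    t_full: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_abbr", _check_positive(self.t_abbr, "t_abbr"))
        object.__setattr__(self, "t_full", _check_positive(self.t_full, "t_full"))
        if self.t_abbr > self.t_full:
            # Permitted (duration sweeps range freely) but worth flagging.
            logger.warning(
                "abbreviated duration (%.6g s) exceeds full duration (%.6g s)",
                self.t_abbr,
                self.t_full,
            )


@dataclass(frozen=True)
class ConfusionRates:
    """Per-person outcome probabilities for one reader at one prevalence.

    ``tp + fn`` equals the prevalence the rates were built from and the
    four cells sum to one.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    prevalence: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "prevalence"):
            object.__setattr__(self, name, _check_fraction(getattr(self, name), name))
        total = self.tp + self.fp + self.tn + self.fn
        if abs(total - 1.0) > PROB_ATOL:
            raise ParameterError(f"tp+fp+tn+fn must equal 1, got {total!r}")
        if abs(self.tp + self.fn - self.prevalence) > PROB_ATOL:
            raise ParameterError(
                f"tp+fn must equal prevalence ({self.prevalence!r}), "
                f"got {self.tp + self.fn!r}"
            )

    @property
    def flag_rate(self) -> float:
        """Probability that this reader flags a person (tp + fp)."""
        return self.tp + self.fp


@dataclass(frozen=True)
class OverlapBounds:
    """Sharp limits on P(both readers flag the same person)."""

    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "minimum", _check_fraction(self.minimum, "minimum"))
        object.__setattr__(self, "maximum", _check_fraction(self.maximum, "maximum"))
        if self.minimum > self.maximum + PROB_ATOL:
            raise ParameterError(
                f"minimum ({self.minimum!r}) exceeds maximum ({self.maximum!r})"
            )

    def contains(self, overlap: float, atol: float = PROB_ATOL) -> bool:
        return self.minimum - atol <= overlap <= self.maximum + atol


class Bounds(NamedTuple):
    """A closed (lower, upper) interval for one metric."""

    lower: float
    upper: float


MetricValue = Union[float, Bounds]

STRATEGIES = ("abbreviated_only", "full_only", "adaptive")


@dataclass(frozen=True)
class ScenarioMetrics:
    """Recall rate and expected duration for one strategy.

    Point strategies carry floats; the adaptive strategy carries
    :class:`Bounds` pairs (lower <= upper).
    """

    strategy: str
    rr: MetricValue
    epd: MetricValue

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ParameterError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}"
            )
        for name, value in (("rr", self.rr), ("epd", self.epd)):
            if isinstance(value, Bounds):
                if value.lower > value.upper + PROB_ATOL:
                    raise ParameterError(f"{name} bounds out of order: {value!r}")

    def rr_bounds(self) -> Bounds:
        return self.rr if isinstance(self.rr, Bounds) else Bounds(self.rr, self.rr)

    def epd_bounds(self) -> Bounds:
        return self.epd if isinstance(self.epd, Bounds) else Bounds(self.epd, self.epd)


@dataclass(frozen=True)
class ModelConfig:
    """A complete parameter set for the model.

    ``rad_full`` (the radiologist's full-protocol operating point) is
    carried for completeness but does not enter the limit formulas.
    """

    rad_abbr: OperatingPoint = field(
        default_factory=lambda: OperatingPoint(0.90, 0.92)
    )
    rad_full: OperatingPoint = field(
        default_factory=lambda: OperatingPoint(0.92, 0.95)
    )
    ai: OperatingPoint = field(default_factory=lambda: OperatingPoint(0.80, 0.80))
    prevalence: float = 0.0146
    t_abbr: float = 262.0
    t_full: float = 776.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "prevalence", _check_fraction(self.prevalence, "prevalence")
        )
        # Delegate duration validation (and the t_abbr > t_full warning).
        self.timing()

    def cohort(self, size: Optional[int] = None) -> Cohort:
        return Cohort(self.prevalence, size)

    def timing(self) -> ProtocolTiming:
        return ProtocolTiming(self.t_abbr, self.t_full)

    def with_value(self, **changes) -> "ModelConfig":
        """Return a copy with scalar or operating-point fields replaced.

        Accepts the ModelConfig field names plus the flattened aliases
        ``ai_sensitivity``, ``ai_specificity``, ``rad_sensitivity_abbr``
        and ``rad_specificity_abbr``.
        """
        flat = {
            "ai_sensitivity": ("ai", "sensitivity"),
            "ai_specificity": ("ai", "specificity"),
            "rad_sensitivity_abbr": ("rad_abbr", "sensitivity"),
            "rad_specificity_abbr": ("rad_abbr", "specificity"),
        }
        direct = {}
        for key, value in changes.items():
            if key in flat:
                attr, part = flat[key]
                current = direct.get(attr, getattr(self, attr))
                direct[attr] = replace(current, **{part: value})
            else:
                direct[key] = value
        return replace(self, **direct)


def default_config() -> ModelConfig:
    """The default parameter set (all fields at their published defaults)."""
    return ModelConfig()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def confusion_rates(op: OperatingPoint, cohort: Cohort) -> ConfusionRates:
    """Per-person confusion probabilities for a reader at a prevalence.

    tp = prevalence * sensitivity, fn = prevalence * (1 - sensitivity),
    tn = (1 - prevalence) * specificity, fp = (1 - prevalence) * (1 - specificity).
    """
    p = cohort.prevalence
    return ConfusionRates(
        tp=p * op.sensitivity,
        fn=p * (1.0 - op.sensitivity),
        tn=(1.0 - p) * op.specificity,
        fp=(1.0 - p) * (1.0 - op.specificity),
        prevalence=p,
    )


def overlap_bounds(rad: ConfusionRates, ai: ConfusionRates) -> OverlapBounds:
    """Sharp limits on the probability that both readers flag a person.

    Flags can only co-occur within a disease stratum (a true positive of
    one reader cannot coincide with a false positive of the other), so the
    Frechet-Hoeffding bounds are applied separately to the diseased and
    non-diseased strata and summed:

    maximum = min(tp_rad, tp_ai) + min(fp_rad, fp_ai)
    minimum = max(0, tp_rad + tp_ai - prevalence)
              + max(0, fp_rad + fp_ai - (1 - prevalence))
    """
    if abs(rad.prevalence - ai.prevalence) > PROB_ATOL:
        raise ConsistencyError(
            "confusion rates built on different prevalences: "
            f"{rad.prevalence!r} vs {ai.prevalence!r}"
        )
    p = rad.prevalence
    maximum = min(rad.tp, ai.tp) + min(rad.fp, ai.fp)
    minimum = max(0.0, rad.tp + ai.tp - p) + max(0.0, rad.fp + ai.fp - (1.0 - p))
    return OverlapBounds(minimum=minimum, maximum=maximum)


def rr_adaptive(
    rad: ConfusionRates,
    overlap: float,
    ai: Optional[ConfusionRates] = None,
) -> float:
    """Adaptive recall rate for a given reader overlap.

    rr = tp_rad + fp_rad - overlap.  Passing the maximum feasible overlap
    yields the best-case (lower) limit; the minimum yields the worst-case
    (upper) limit.  When ``ai`` is supplied the overlap is checked against
    the full feasible range; otherwise only 0 <= overlap <= flag rate is
    enforced.
    """
    overlap = _check_fraction(overlap, "overlap")
    if ai is not None:
        bounds = overlap_bounds(rad, ai)
        if not bounds.contains(overlap):
            raise FeasibilityError(
                f"overlap {overlap!r} outside feasible range "
                f"[{bounds.minimum!r}, {bounds.maximum!r}]"
            )
    elif overlap > rad.flag_rate + PROB_ATOL:
        raise FeasibilityError(
            f"overlap {overlap!r} exceeds radiologist flag rate {rad.flag_rate!r}"
        )
    return max(0.0, rad.flag_rate - overlap)


def epd_adaptive(ai: ConfusionRates, rr: float, timing: ProtocolTiming) -> float:
    """Expected per-person duration of the adaptive strategy, in seconds.

    AI-flagged people get the full protocol immediately; AI-negative people
    get the abbreviated protocol; recalled people (rate ``rr``) additionally
    return for a full-protocol visit:

    epd = t_full * (tp_ai + fp_ai + rr) + t_abbr * (tn_ai + fn_ai)
    """
    rr = _check_fraction(rr, "rr")
    return timing.t_full * (ai.tp + ai.fp + rr) + timing.t_abbr * (ai.tn + ai.fn)


def rr_abbreviated_only(rad: ConfusionRates) -> float:
    """Recall rate when everyone is screened with the abbreviated protocol."""
    return rad.flag_rate


def epd_abbreviated_only(rad: ConfusionRates, timing: ProtocolTiming) -> float:
    """Expected duration of abbreviated-only screening, in seconds.

    Every person gets the short scan; radiologist-flagged people return
    for a full-protocol visit.
    """
    return timing.t_abbr + rad.flag_rate * timing.t_full


def metrics_abbreviated_only(
    rad: ConfusionRates, timing: ProtocolTiming
) -> ScenarioMetrics:
    return ScenarioMetrics(
        strategy="abbreviated_only",
        rr=rr_abbreviated_only(rad),
        epd=epd_abbreviated_only(rad, timing),
    )


def metrics_full_only(timing: ProtocolTiming) -> ScenarioMetrics:
    """Full-only strategy: no recalls, every exam takes t_full."""
    return ScenarioMetrics(strategy="full_only", rr=0.0, epd=timing.t_full)


def adaptive_bounds(
    rad_op: OperatingPoint,
    ai_op: OperatingPoint,
    cohort: Cohort,
    timing: ProtocolTiming,
) -> ScenarioMetrics:
    """Lower/upper limits on adaptive recall rate and expected duration.

    The lower recall limit corresponds to maximum reader overlap (best
    case) and the upper to minimum overlap (worst case); each recall limit
    is inserted into the duration formula to give the matching duration
    limit.
    """
    rad = confusion_rates(rad_op, cohort)
    ai = confusion_rates(ai_op, cohort)
    ov = overlap_bounds(rad, ai)
    rr_lower = rr_adaptive(rad, ov.maximum)
    rr_upper = rr_adaptive(rad, ov.minimum)
    epd_lower = epd_adaptive(ai, rr_lower, timing)
    epd_upper = epd_adaptive(ai, rr_upper, timing)
    return ScenarioMetrics(
        strategy="adaptive",
        rr=Bounds(rr_lower, rr_upper),
        epd=Bounds(epd_lower, epd_upper),
    )
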