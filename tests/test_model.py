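"""Unit tests for the analytic engine."""

import math

import pytest

from screenbounds import (
    Bounds,
    Cohort,
    ConsistencyError,
    FeasibilityError,
    OperatingPoint,
    ParameterError,
    ProtocolTiming,
    ScenarioMetrics,
    adaptive_bounds,
    confusion_rates,
    epd_abbreviated_only,
    epd_adaptive,
    metrics_full_only,
    overlap_bounds,
    rr_abbreviated_only,
    rr_adaptive,
)

from conftest import brute_force_overlap_bounds, expected_count_table

PROB_ATOL = 1e-9
DUR_ATOL = 1e-6


class TestConfusionRates:
    def test_table_values(self, rad_op, cohort):
        # frozen from direct arithmetic; cross-checked against a
        # 1,000,000-person expected-count enumeration below
        rates = confusion_rates(rad_op, cohort)
        assert rates.tp == pytest.approx(0.013140, abs=PROB_ATOL)
        assert rates.fp == pytest.approx(0.078832, abs=PROB_ATOL)
        assert rates.fn == pytest.approx(0.001460, abs=PROB_ATOL)
        assert rates.tn == pytest.approx(0.906568, abs=PROB_ATOL)

    def test_matches_expected_count_enumeration(self, rad_op, cohort):
        rates = confusion_rates(rad_op, cohort)
        counts = expected_count_table(1_000_000, rad_op, cohort.prevalence)
        for cell in ("tp", "fp", "tn", "fn"):
            assert getattr(rates, cell) * 1_000_000 == pytest.approx(
                counts[cell], abs=1e-3
            )

    @pytest.mark.parametrize("p", [0.0, 0.0146, 0.5, 1.0])
    def test_perfect_reader(self, p):
        rates = confusion_rates(OperatingPoint(1.0, 1.0), Cohort(p))
        assert rates.tp == pytest.approx(p, abs=PROB_ATOL)
        assert rates.tn == pytest.approx(1.0 - p, abs=PROB_ATOL)
        assert rates.fp == 0.0
        assert rates.fn == 0.0

    def test_eighty_eighty(self, cohort):
        rates = confusion_rates(OperatingPoint(0.80, 0.80), cohort)
        assert rates.tp == pytest.approx(0.011680, abs=PROB_ATOL)
        assert rates.fp == pytest.approx(0.197080, abs=PROB_ATOL)
        assert rates.fn == pytest.approx(0.002920, abs=PROB_ATOL)
        assert rates.tn == pytest.approx(0.788320, abs=PROB_ATOL)

    def test_sums(self, rad_op, cohort):
        rates = confusion_rates(rad_op, cohort)
        assert rates.tp + rates.fp + rates.tn + rates.fn == pytest.approx(
            1.0, abs=1e-12
        )
        assert rates.tp + rates.fn == pytest.approx(cohort.prevalence, abs=1e-12)

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"sensitivity": 1.2, "specificity": 0.9}, "sensitivity"),
            ({"sensitivity": -0.1, "specificity": 0.9}, "sensitivity"),
            ({"sensitivity": 0.9, "specificity": math.nan}, "specificity"),
        ],
    )
    def test_rejects_out_of_range_naming_field(self, kwargs, field):
        with pytest.raises(ParameterError, match=field):
            OperatingPoint(**kwargs)

    def test_rejects_bad_prevalence(self):
        with pytest.raises(ParameterError, match="prevalence"):
            Cohort(prevalence=1.5)

    def test_rejects_bad_size(self):
        with pytest.raises(ParameterError, match="size"):
            Cohort(prevalence=0.1, size=0)


class TestOverlapBounds:
    def test_table_pair(self, rad_op, ai_op, cohort):
        rad = confusion_rates(rad_op, cohort)
        ai = confusion_rates(ai_op, cohort)
        ov = overlap_bounds(rad, ai)
        assert ov.maximum == pytest.approx(0.090512, abs=PROB_ATOL)
        assert ov.minimum == pytest.approx(0.010220, abs=PROB_ATOL)

    def test_against_brute_force(self, rad_op, ai_op, cohort):
        rad = confusion_rates(rad_op, cohort)
        ai = confusion_rates(ai_op, cohort)
        ov = overlap_bounds(rad, ai)
        lo, hi = brute_force_overlap_bounds(rad_op, ai_op, cohort.prevalence)
        assert ov.minimum == pytest.approx(lo, abs=2e-6)
        assert ov.maximum == pytest.approx(hi, abs=2e-6)

    def test_always_flagging_ai_forces_overlap(self, rad_op, cohort):
        rad = confusion_rates(rad_op, cohort)
        ai = confusion_rates(OperatingPoint(1.0, 0.0), cohort)
        ov = overlap_bounds(rad, ai)
        assert ov.minimum == pytest.approx(0.091972, abs=PROB_ATOL)
        assert ov.maximum == pytest.approx(0.091972, abs=PROB_ATOL)

    def test_identical_readers(self, rad_op, cohort):
        rad = confusion_rates(rad_op, cohort)
        ov = overlap_bounds(rad, rad)
        assert ov.maximum == pytest.approx(0.091972, abs=PROB_ATOL)
        # tp stratum forced to 2*0.013140 - 0.0146; fp stratum can reach 0
        assert ov.minimum == pytest.approx(0.011680, abs=PROB_ATOL)
        lo, hi = brute_force_overlap_bounds(rad_op, rad_op, cohort.prevalence)
        assert ov.minimum == pytest.approx(lo, abs=2e-6)
        assert ov.maximum == pytest.approx(hi, abs=2e-6)

    def test_prevalence_mismatch(self, rad_op):
        rad = confusion_rates(rad_op, Cohort(0.0146))
        ai = confusion_rates(rad_op, Cohort(0.02))
        with pytest.raises(ConsistencyError):
            overlap_bounds(rad, ai)


class TestRecallRate:
    def test_lower_limit_zero_when_ai_matches_sensitivity(self, rad_op, cohort):
        # AI sensitivity equal to the radiologist's zeroes the best case
        rad = confusion_rates(rad_op, cohort)
        ai = confusion_rates(OperatingPoint(0.90, 0.80), cohort)
        ov = overlap_bounds(rad, ai)
        assert rr_adaptive(rad, ov.maximum) == pytest.approx(0.0, abs=PROB_ATOL)

    def test_best_and_worst_case(self, rad_op, ai_op, cohort):
        rad = confusion_rates(rad_op, cohort)
        ai = confusion_rates(ai_op, cohort)
        ov = overlap_bounds(rad, ai)
        assert rr_adaptive(rad, ov.maximum) == pytest.approx(0.001460, abs=PROB_ATOL)
        assert rr_adaptive(rad, ov.minimum) == pytest.approx(0.081752, abs=PROB_ATOL)
        # lower limit equals prevalence * (sens_rad - sens_ai)
        assert rr_adaptive(rad, ov.maximum) == pytest.approx(
            0.0146 * (0.90 - 0.80), abs=PROB_ATOL
        )

    def test_infeasible_overlap_rejected(self, rad_op, ai_op, cohort):
        rad = confusion_rates(rad_op, cohort)
        ai = confusion_rates(ai_op, cohort)
        with pytest.raises(FeasibilityError):
            rr_adaptive(rad, 0.5, ai)
        with pytest.raises(FeasibilityError):
            rr_adaptive(rad, 0.0, ai)  # below the feasible minimum

    def test_overlap_above_flag_rate_rejected(self, rad_op, cohort):
        rad = confusion_rates(rad_op, cohort)
        with pytest.raises(FeasibilityError):
            rr_adaptive(rad, 0.5)

    def test_abbreviated_only(self, rad_op, cohort):
        rad = confusion_rates(rad_op, cohort)
        assert rr_abbreviated_only(rad) == pytest.approx(0.091972, abs=PROB_ATOL)

    def test_abbreviated_only_degenerate(self):
        rad = confusion_rates(OperatingPoint(0.9, 1.0), Cohort(0.0))
        assert rr_abbreviated_only(rad) == 0.0
        rad = confusion_rates(OperatingPoint(1.0, 0.0), Cohort(0.3))
        assert rr_abbreviated_only(rad) == pytest.approx(1.0, abs=PROB_ATOL)


class TestDurations:
    def test_best_and_worst_case(self, ai_op, cohort, timing):
        ai = confusion_rates(ai_op, cohort)
        assert epd_adaptive(ai, 0.001460, timing) == pytest.approx(
            370.4356, abs=DUR_ATOL
        )
        assert epd_adaptive(ai, 0.081752, timing) == pytest.approx(
            432.742192, abs=DUR_ATOL
        )

    def test_never_flagging_ai_reduces_to_abbreviated(self, rad_op, cohort, timing):
        rad = confusion_rates(rad_op, cohort)
        ai = confusion_rates(OperatingPoint(0.0, 1.0), cohort)
        rr = rr_abbreviated_only(rad)
        assert epd_adaptive(ai, rr, timing) == pytest.approx(
            epd_abbreviated_only(rad, timing), abs=DUR_ATOL
        )

    def test_abbreviated_only(self, rad_op, cohort, timing):
        rad = confusion_rates(rad_op, cohort)
        assert epd_abbreviated_only(rad, timing) == pytest.approx(
            333.370272, abs=DUR_ATOL
        )

    def test_abbreviated_only_extremes(self, timing):
        rad0 = confusion_rates(OperatingPoint(0.5, 1.0), Cohort(0.0))
        assert epd_abbreviated_only(rad0, timing) == pytest.approx(262.0)
        rad1 = confusion_rates(OperatingPoint(1.0, 0.0), Cohort(0.5))
        assert epd_abbreviated_only(rad1, timing) == pytest.approx(262.0 + 776.0)

    def test_abbr_longer_than_full_warns(self, caplog):
        with caplog.at_level("WARNING", logger="screenbounds.model"):
            ProtocolTiming(t_abbr=800.0, t_full=262.0)
        assert any("exceeds" in r.message for r in caplog.records)


class TestFullOnly:
    def test_table_timing(self, timing):
        m = metrics_full_only(timing)
        assert m.rr == 0.0
        assert m.epd == pytest.approx(776.0)

    def test_any_timing(self):
        assert metrics_full_only(ProtocolTiming(100.0, 100.0)).epd == 100.0
        assert metrics_full_only(ProtocolTiming(1.0, 5.0)).rr == 0.0


class TestAdaptiveBounds:
    def test_table_composition(self, rad_op, ai_op, cohort, timing):
        m = adaptive_bounds(rad_op, ai_op, cohort, timing)
        assert m.rr.lower == pytest.approx(0.001460, abs=PROB_ATOL)
        assert m.rr.upper == pytest.approx(0.081752, abs=PROB_ATOL)
        assert m.epd.lower == pytest.approx(370.4356, abs=DUR_ATOL)
        assert m.epd.upper == pytest.approx(432.742192, abs=DUR_ATOL)

    def test_always_flagging_ai_degenerates_to_full_only(self, rad_op, cohort, timing):
        m = adaptive_bounds(rad_op, OperatingPoint(1.0, 0.0), cohort, timing)
        assert m.rr == Bounds(0.0, 0.0)
        assert m.epd.lower == pytest.approx(776.0, abs=DUR_ATOL)
        assert m.epd.upper == pytest.approx(776.0, abs=DUR_ATOL)

    def test_never_flagging_ai_degenerates_to_abbreviated(
        self, rad_op, cohort, timing
    ):
        m = adaptive_bounds(rad_op, OperatingPoint(0.0, 1.0), cohort, timing)
        assert m.rr.lower == pytest.approx(0.091972, abs=PROB_ATOL)
        assert m.rr.upper == pytest.approx(0.091972, abs=PROB_ATOL)
        assert m.epd.lower == pytest.approx(333.370272, abs=DUR_ATOL)
        assert m.epd.upper == pytest.approx(333.370272, abs=DUR_ATOL)

    def test_ordering(self, rad_op, ai_op, cohort, timing):
        m = adaptive_bounds(rad_op, ai_op, cohort, timing)
        assert m.rr.lower <= m.rr.upper
        assert m.epd.lower <= m.epd.upper

    def test_degenerate_prevalence_allowed(self, rad_op, ai_op, timing):
        for p in (0.0, 1.0):
            m = adaptive_bounds(rad_op, ai_op, Cohort(p), timing)
            assert m.rr.lower <= m.rr.upper

    def test_scenario_metrics_validation(self):
        with pytest.raises(ParameterError, match="strategy"):
            ScenarioMetrics(strategy="nope", rr=0.0, epd=1.0)
        with pytest.raises(ParameterError, match="rr"):
            ScenarioMetrics(strategy="adaptive", rr=Bounds(0.5, 0.1), epd=1.0)
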