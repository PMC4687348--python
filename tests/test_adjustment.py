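"""Titration precedence, windowed averaging, variability, bedtime rule."""

from datetime import timedelta

import pytest
from hypothesis import given, settings as hsettings, strategies as st

from insulincalc import (
    AdjustmentAction,
    InsufficientMeasurementsError,
    NutritionalStatus,
    PatientProfile,
    RegimenType,
    apply_adjustment,
    average_bg,
    bedtime_supplement,
    build_prescription,
    detect_variability,
    recommend_adjustment,
)
from insulincalc.adjustment import AdjustmentRecommendation, BedtimeRuleError
from insulincalc.config import DEFAULT_SETTINGS

from conftest import NOW, make_series


@pytest.fixture
def basal_bolus_rx(baseline_profile):
    return build_prescription(baseline_profile, 300.0, at=NOW)


@pytest.fixture
def step_wise_rx(baseline_profile):
    rx = build_prescription(baseline_profile, 200.0, at=NOW)
    assert rx.regimen is RegimenType.STEP_WISE
    return rx


class TestAverageBg:
    def test_mean_of_three(self):
        assert average_bg(make_series([120, 160, 200]), now=NOW) == pytest.approx(160.0)

    def test_single_value_identity(self):
        assert average_bg(make_series([140])) == pytest.approx(140.0)

    def test_values_outside_window_excluded(self):
        series = make_series([100, 200], hours_ago=[50, 10])
        assert average_bg(series, window=24.0, now=NOW) == pytest.approx(200.0)

    def test_window_is_half_open(self):
        series = make_series([100, 200], hours_ago=[24, 0])
        # exactly 24 h old falls outside (now-24, now]
        assert average_bg(series, window=24.0, now=NOW) == pytest.approx(200.0)

    def test_empty_window_raises_named_error(self):
        series = make_series([120], hours_ago=[60])
        with pytest.raises(InsufficientMeasurementsError, match="insufficient measurements"):
            average_bg(series, window=24.0, now=NOW)

    def test_window_bounds_enforced(self):
        with pytest.raises(ValueError):
            average_bg(make_series([120]), window=12.0)


class TestDetectVariability:
    def test_hypo_plus_hyper_in_window(self):
        assert detect_variability(make_series([65, 250]), now=NOW)

    def test_all_in_range_not_variable(self):
        assert not detect_variability(make_series([110, 130, 125]), now=NOW)

    def test_hypo_only_not_variable(self):
        assert not detect_variability(make_series([65, 68]), now=NOW)

    def test_empty_series_not_variable(self):
        assert not detect_variability([], now=NOW)


class TestRecommendAdjustment:
    def test_hyperglycemic_average_raises_category(self, basal_bolus_rx):
        rec = recommend_adjustment(basal_bolus_rx, make_series([150, 170]), now=NOW)
        assert rec.action is AdjustmentAction.INCREASE_CATEGORY
        assert rec.average_bg == pytest.approx(160.0)

    def test_in_band_average_maintains(self, basal_bolus_rx):
        rec = recommend_adjustment(basal_bolus_rx, make_series([115, 125]), now=NOW)
        assert rec.action is AdjustmentAction.MAINTAIN

    def test_low_average_lowers_category(self, basal_bolus_rx):
        rec = recommend_adjustment(basal_bolus_rx, make_series([85, 95]), now=NOW)
        assert rec.action is AdjustmentAction.DECREASE_CATEGORY

    def test_step_wise_high_average_adds_basal(self, step_wise_rx):
        rec = recommend_adjustment(step_wise_rx, make_series([190, 190]), now=NOW)
        assert rec.action is AdjustmentAction.ADD_BASAL

    def test_step_wise_moderate_average_still_increases_category(self, step_wise_rx):
        rec = recommend_adjustment(step_wise_rx, make_series([160, 170]), now=NOW)
        assert rec.action is AdjustmentAction.INCREASE_CATEGORY

    def test_variability_preempts_category_change(self, basal_bolus_rx):
        rec = recommend_adjustment(basal_bolus_rx, make_series([60, 260]), now=NOW)
        assert rec.action is AdjustmentAction.CONSULT_SPECIALIST

    @pytest.mark.parametrize("regimen_fixture", ["basal_bolus_rx", "step_wise_rx"])
    def test_threshold_sweep_matches_brute_force_precedence(
        self, regimen_fixture, request
    ):
        """Integer-average sweep 40-600 agrees with an independent re-statement
        of the precedence list, and respects the strict 100/140 boundaries."""
        rx = request.getfixturevalue(regimen_fixture)
        for avg in range(40, 601):
            rec = recommend_adjustment(rx, make_series([avg]), now=NOW)
            if rx.regimen is RegimenType.STEP_WISE and avg > 180:
                expected = AdjustmentAction.ADD_BASAL
            elif avg > 140:
                expected = AdjustmentAction.INCREASE_CATEGORY
            elif avg < 100:
                expected = AdjustmentAction.DECREASE_CATEGORY
            else:
                expected = AdjustmentAction.MAINTAIN
            assert rec.action is expected, f"avg={avg}"
            if avg >= 100:
                assert rec.action is not AdjustmentAction.DECREASE_CATEGORY
            if avg <= 140:
                assert rec.action is not AdjustmentAction.INCREASE_CATEGORY


class TestApplyAdjustment:
    def test_increase_recomputes_doses(self, basal_bolus_rx):
        rec = recommend_adjustment(basal_bolus_rx, make_series([160, 180]), now=NOW)
        updated = apply_adjustment(basal_bolus_rx, rec)
        assert updated.category.category == 9
        assert updated.dose_split.tddi == pytest.approx(0.45 * 80.0)
        assert updated.followup[-1]["action"] == "INCREASE_CATEGORY"

    def test_add_basal_converts_step_wise_to_basal_bolus(self, step_wise_rx):
        rec = recommend_adjustment(step_wise_rx, make_series([200, 220]), now=NOW)
        updated = apply_adjustment(step_wise_rx, rec)
        assert updated.regimen is RegimenType.BASAL_BOLUS
        assert updated.dose_split.basal_total == pytest.approx(16.0)

    def test_maintain_and_consult_freeze_doses(self, basal_bolus_rx):
        for values in ([120], [60, 260]):
            rec = recommend_adjustment(basal_bolus_rx, make_series(values), now=NOW)
            updated = apply_adjustment(basal_bolus_rx, rec)
            assert updated.dose_split == basal_bolus_rx.dose_split
            assert updated.category == basal_bolus_rx.category

    def test_repeated_increases_reach_fixed_point_at_upper_bound(self, basal_bolus_rx):
        rx = basal_bolus_rx
        rec = AdjustmentRecommendation(
            action=AdjustmentAction.INCREASE_CATEGORY,
            average_bg=200.0, window=24.0, rationale=("test",),
        )
        for _ in range(20):
            rx = apply_adjustment(rx, rec)
        assert rx.category.category == DEFAULT_SETTINGS.category_max
        again = apply_adjustment(rx, rec)
        assert again.category.category == DEFAULT_SETTINGS.category_max


class TestBedtimeSupplement:
    @pytest.mark.parametrize(
        "bg,units", [(180.0, 0), (249.0, 0), (250.0, 2), (300.0, 2),
                     (350.0, 2), (351.0, 4), (400.0, 4)],
    )
    def test_bands_with_printed_breakpoints(self, bg, units):
        assert bedtime_supplement(bg, NutritionalStatus.EATING) == units

    @pytest.mark.parametrize("status", [NutritionalStatus.NPO, NutritionalStatus.ENTERAL])
    def test_rule_restricted_to_eating_patients(self, status):
        with pytest.raises(BedtimeRuleError, match="eating"):
            bedtime_supplement(300.0, status)

    def test_nondecreasing_piecewise_constant_with_exact_breakpoints(self):
        previous = 0
        changes = []
        for bg in range(100, 601):
            units = bedtime_supplement(float(bg), NutritionalStatus.EATING)
            assert units >= previous
            if units != previous:
                changes.append(bg)
            previous = units
        assert changes == [250, 351]
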