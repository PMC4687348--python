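"""Dose category arithmetic, sensitivity rules, correction scale, splits."""

import itertools
from dataclasses import replace

import pytest
from hypothesis import given, settings as hsettings, strategies as st

from insulincalc import (
    ActionClass,
    DoseCategory,
    NutritionalStatus,
    PatientProfile,
    RegimenType,
    build_correction_scale,
    category_to_tddi,
    classify_insulin,
    compute_category,
    sensitivity_factor,
    split_doses,
)
from insulincalc.config import DEFAULT_SETTINGS
from insulincalc.dosing import DoseComputationError, round_half_up

MODIFIER_FLAGS = (
    ("elderly", -1),
    ("renal_impairment", -1),
    ("hepatic_impairment", -1),
    ("obesity", +1),
    ("high_dose_corticosteroids", +1),
)


def profile_with_flags(flags: dict) -> PatientProfile:
    return PatientProfile(
        weight=80.0,
        age=75.0 if flags.get("elderly") else 50.0,
        renal_impairment=flags.get("renal_impairment", False),
        hepatic_impairment=flags.get("hepatic_impairment", False),
        obesity=flags.get("obesity", False),
        high_dose_corticosteroids=flags.get("high_dose_corticosteroids", False),
    )


class TestDoseCategory:
    @pytest.mark.parametrize(
        "category,coefficient", [(8, 0.4), (6, 0.3), (9, 0.45), (2, 0.1), (14, 0.7)]
    )
    def test_coefficient_formula(self, category, coefficient):
        assert DoseCategory(category).coefficient == pytest.approx(coefficient)

    def test_shift_clamps_at_bounds(self):
        top = DoseCategory(DEFAULT_SETTINGS.category_max)
        bottom = DoseCategory(DEFAULT_SETTINGS.category_min)
        assert top.shifted(+1).category == DEFAULT_SETTINGS.category_max
        assert bottom.shifted(-1).category == DEFAULT_SETTINGS.category_min


class TestComputeCategory:
    def test_no_modifiers_standard_category(self, baseline_profile):
        cat = compute_category(baseline_profile)
        assert cat.category == 8
        assert cat.coefficient == pytest.approx(0.4)

    def test_elderly_plus_renal(self):
        cat = compute_category(profile_with_flags({"elderly": True, "renal_impairment": True}))
        assert (cat.category, cat.coefficient) == (6, pytest.approx(0.3))

    def test_mixed_up_and_down_modifiers(self):
        flags = {"obesity": True, "high_dose_corticosteroids": True, "renal_impairment": True}
        cat = compute_category(profile_with_flags(flags))
        assert (cat.category, cat.coefficient) == (9, pytest.approx(0.45))

    def test_matches_brute_force_offset_oracle_over_all_32_combinations(self):
        for bits in itertools.product([False, True], repeat=len(MODIFIER_FLAGS)):
            flags = {name: on for (name, _), on in zip(MODIFIER_FLAGS, bits)}
            expected = 8 + sum(
                off for (name, off), on in zip(MODIFIER_FLAGS, bits) if on
            )
            expected = min(
                DEFAULT_SETTINGS.category_max,
                max(DEFAULT_SETTINGS.category_min, expected),
            )
            assert compute_category(profile_with_flags(flags)).category == expected


class TestTddi:
    @pytest.mark.parametrize(
        "category,weight,expected", [(8, 80.0, 32.0), (8, 100.0, 40.0), (7, 80.0, 28.0)]
    )
    def test_worked_examples(self, category, weight, expected):
        assert category_to_tddi(DoseCategory(category), weight) == pytest.approx(expected)

    def test_standard_category_recovers_point_four_units_per_kg(self):
        tddi = category_to_tddi(DoseCategory(8), 100.0)
        assert tddi / 100.0 == pytest.approx(0.4)

    @hsettings(derandomize=True, max_examples=100)
    @given(
        st.integers(min_value=2, max_value=13),
        st.floats(min_value=30.0, max_value=200.0),
    )
    def test_strictly_monotone_in_category_and_weight(self, category, weight):
        base = category_to_tddi(DoseCategory(category), weight)
        assert category_to_tddi(DoseCategory(category + 1), weight) > base
        assert category_to_tddi(DoseCategory(category), weight * 1.1) > base


class TestSensitivityFactor:
    @pytest.mark.parametrize(
        "tddi,klass,expected",
        [(60.0, ActionClass.RAPID, 30.0), (50.0, ActionClass.SHORT, 30.0),
         (45.0, ActionClass.RAPID, 40.0)],
    )
    def test_worked_examples(self, tddi, klass, expected):
        assert sensitivity_factor(tddi, klass) == pytest.approx(expected)

    @hsettings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=1.0, max_value=300.0))
    def test_rule_constants_recovered_exactly(self, tddi):
        assert sensitivity_factor(tddi, ActionClass.RAPID) * tddi == pytest.approx(1800.0)
        assert sensitivity_factor(tddi, ActionClass.SHORT) * tddi == pytest.approx(1500.0)

    def test_nonpositive_tddi_rejected(self):
        with pytest.raises(DoseComputationError):
            sensitivity_factor(0.0, ActionClass.RAPID)

    @pytest.mark.parametrize("klass", [ActionClass.LONG, ActionClass.INTERMEDIATE])
    def test_basal_classes_rejected(self, klass):
        with pytest.raises(DoseComputationError):
            sensitivity_factor(40.0, klass)


class TestCorrectionScale:
    @pytest.mark.parametrize(
        "sf,target,bg,expected",
        [(40.0, 140.0, 140.0, 0), (40.0, 140.0, 220.0, 2), (30.0, 140.0, 139.0, 0)],
    )
    def test_worked_examples(self, sf, target, bg, expected):
        scale = build_correction_scale(sf, target)
        assert scale.correction_units(bg) == expected

    def test_units_nondecreasing_and_zero_at_or_below_target(self):
        scale = build_correction_scale(35.0, 140.0)
        previous = 0
        for bg in range(40, 601):
            units = scale.correction_units(float(bg))
            assert units >= previous
            if bg <= 140:
                assert units == 0
            previous = units

    def test_table_entries_agree_with_formula(self):
        scale = build_correction_scale(45.0, 140.0)
        for lo, hi, units in scale.entries:
            for bg in (lo + 0.01, min(hi, 1000.0) - 0.01):
                if bg > lo:
                    assert scale.correction_units(bg) == units

    def test_bands_contiguous_and_units_increment_by_one(self):
        scale = build_correction_scale(50.0, 140.0)
        for (lo1, hi1, u1), (lo2, hi2, u2) in zip(scale.entries, scale.entries[1:]):
            assert hi1 == lo2
            assert u2 == u1 + 1

    def test_cap_and_escalation(self):
        scale = build_correction_scale(30.0, 140.0)
        assert scale.correction_units(2000.0) == scale.cap_units == 8
        assert scale.requires_escalation(2000.0)
        assert not scale.requires_escalation(150.0)

    def test_out_of_band_target_rejected(self):
        with pytest.raises(DoseComputationError):
            build_correction_scale(40.0, 90.0)


class TestSplitDoses:
    def test_basal_bolus_glargine(self):
        split = split_doses(
            32.0, RegimenType.BASAL_BOLUS, classify_insulin("GLARGINE"),
            NutritionalStatus.EATING,
        )
        assert split.basal_schedule == (("morning", 16),)
        assert split.prandial_per_meal == 5
        assert split.basal_total == split.prandial_total == 16.0

    def test_basal_plus_nph_two_thirds_one_third(self):
        split = split_doses(
            32.0, RegimenType.BASAL_PLUS, classify_insulin("NPH"),
            NutritionalStatus.NPO,
        )
        assert split.basal_schedule == (("morning", 11), ("evening", 5))
        assert split.prandial_per_meal == 0
        assert split.prandial_schedule == ()

    def test_nph_thrice_daily_config(self):
        from insulincalc import Settings

        thirds = Settings(nph_doses_per_day=3)
        split = split_doses(
            30.0, RegimenType.BASAL_BOLUS, classify_insulin("NPH"),
            NutritionalStatus.EATING, settings=thirds,
        )
        assert split.basal_schedule == (("morning", 5), ("afternoon", 5), ("evening", 5))

    def test_step_wise_withholds_basal_keeps_prandial_share(self):
        split = split_doses(
            32.0, RegimenType.STEP_WISE, classify_insulin("NPH"),
            NutritionalStatus.EATING,
        )
        assert split.basal_total == 0.0
        assert split.basal_schedule == ()
        assert split.prandial_per_meal == 5

    @hsettings(derandomize=True, max_examples=300)
    @given(st.floats(min_value=5.0, max_value=140.0),
           st.sampled_from(["NPH", "GLARGINE", "DETEMIR"]))
    def test_basal_bolus_conserves_tddi(self, tddi, basal_name):
        split = split_doses(
            tddi, RegimenType.BASAL_BOLUS, classify_insulin(basal_name),
            NutritionalStatus.EATING,
        )
        # exact before rounding
        assert split.basal_total + split.prandial_total == pytest.approx(tddi)
        # rounding slack only after scheduling
        assert abs(split.scheduled_total - tddi) <= 2.0


@pytest.mark.parametrize("x,expected", [(5.5, 6), (5.49, 5), (10.5, 11), (0.0, 0)])
def test_round_half_up_convention(x, expected):
    assert round_half_up(x) == expected
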