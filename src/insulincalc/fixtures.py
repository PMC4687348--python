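"""Synthetic patient scenarios for end-to-end testing.

Each :class:`ScenarioFixture` bundles a patient profile, an admission BG,
one day of bedside glucose readings consistent with the profile's
monitoring schedule, and the regimen and titration action the scenario was
constructed to elicit.  Twelve templates cover the cross-product that
matters: all three regimens, all three nutritional statuses and all five
titration actions.  BG traces are drawn from uniform bands chosen so the
windowed average lands unambiguously in the intended titration region
(e.g. 160-240 mg/dL for a category increase, 75-95 for a decrease).

Everything is driven by one explicit seed; the same seed always reproduces
the same fixtures, including timestamps (anchored to a fixed reference day,
not the wall clock).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

from .adjustment import AdjustmentAction
from .dosing import RegimenType
from .io import profile_to_dict
from .patient import (
    GlucoseMeasurement,
    MeasurementContext,
    NutritionalStatus,
    OutpatientTreatment,
    PatientProfile,
    classify_insulin,
)
from .regimen import monitoring_schedule

__all__ = ["ScenarioFixture", "generate_fixtures", "fixture_to_dict"]

_BASE_DAY = datetime(2024, 3, 1, tzinfo=timezone.utc)

# Clock times for the eating monitoring schedule (pre-meals + bedtime) and
# the q6h schedule.
_EATING_TIMES = {
    MeasurementContext.PRE_BREAKFAST: 7,
    MeasurementContext.PRE_LUNCH: 12,
    MeasurementContext.PRE_DINNER: 18,
    MeasurementContext.BEDTIME: 22,
}
_Q6H_TIMES = (0, 6, 12, 18)


@dataclass(frozen=True)
class ScenarioFixture:
    name: str
    seed: int
    profile: PatientProfile
    initial_bg: float
    bg_trace: tuple[GlucoseMeasurement, ...]
    expected_regimen: RegimenType
    expected_action: AdjustmentAction


# (regimen, nutritional status, action) templates; cycled to fill n.
_TEMPLATES: tuple[tuple[RegimenType, NutritionalStatus, AdjustmentAction], ...] = (
    (RegimenType.STEP_WISE, NutritionalStatus.EATING, AdjustmentAction.MAINTAIN),
    (RegimenType.STEP_WISE, NutritionalStatus.EATING, AdjustmentAction.ADD_BASAL),
    (RegimenType.STEP_WISE, NutritionalStatus.EATING, AdjustmentAction.INCREASE_CATEGORY),
    (RegimenType.STEP_WISE, NutritionalStatus.EATING, AdjustmentAction.DECREASE_CATEGORY),
    (RegimenType.BASAL_BOLUS, NutritionalStatus.EATING, AdjustmentAction.INCREASE_CATEGORY),
    (RegimenType.BASAL_BOLUS, NutritionalStatus.EATING, AdjustmentAction.DECREASE_CATEGORY),
    (RegimenType.BASAL_BOLUS, NutritionalStatus.EATING, AdjustmentAction.MAINTAIN),
    (RegimenType.BASAL_BOLUS, NutritionalStatus.EATING, AdjustmentAction.CONSULT_SPECIALIST),
    (RegimenType.BASAL_PLUS, NutritionalStatus.NPO, AdjustmentAction.INCREASE_CATEGORY),
    (RegimenType.BASAL_PLUS, NutritionalStatus.NPO, AdjustmentAction.MAINTAIN),
    (RegimenType.BASAL_PLUS, NutritionalStatus.ENTERAL, AdjustmentAction.DECREASE_CATEGORY),
    (RegimenType.BASAL_PLUS, NutritionalStatus.ENTERAL, AdjustmentAction.CONSULT_SPECIALIST),
)

# Uniform BG bands (mg/dL) per intended titration action.  The step-wise
# increase band stays at or below 180 so the add-basal rule cannot fire
# first; the add-basal band stays above 180.
_ACTION_BANDS = {
    AdjustmentAction.MAINTAIN: (105, 135),
    AdjustmentAction.INCREASE_CATEGORY: (160, 240),
    AdjustmentAction.DECREASE_CATEGORY: (75, 95),
    AdjustmentAction.ADD_BASAL: (190, 260),
}
_STEPWISE_INCREASE_BAND = (145, 175)
_CONSULT_HYPO_BAND = (45, 65)
_CONSULT_HYPER_BAND = (200, 300)
_CONSULT_FILL_BAND = (100, 180)


def _draw_profile(
    rng: random.Random,
    regimen: RegimenType,
    status: NutritionalStatus,
) -> tuple[PatientProfile, float]:
    """Random profile + admission BG guaranteed to select ``regimen``."""
    weight = float(rng.randint(50, 110))
    age = float(rng.randint(25, 65))  # below the elderly cutoff
    if rng.random() < 0.5:
        basal, bolus = classify_insulin("NPH"), classify_insulin("REGULAR")
    else:
        basal = classify_insulin(rng.choice(["GLARGINE", "DETEMIR"]))
        bolus = classify_insulin(rng.choice(["LISPRO", "ASPART", "GLULISINE"]))

    if regimen is RegimenType.BASAL_PLUS:
        treatment = rng.choice(list(OutpatientTreatment))
        tdd = float(rng.randint(20, 60)) if treatment is OutpatientTreatment.INSULIN else None
        initial_bg = float(rng.randint(160, 320))
    elif regimen is RegimenType.STEP_WISE:
        treatment = rng.choice(
            [OutpatientTreatment.INSULIN_NAIVE, OutpatientTreatment.ORAL_AGENTS]
        )
        tdd = None
        initial_bg = float(rng.randint(160, 240))  # below the 250 cutoff
    else:  # BASAL_BOLUS while eating: hyperglycemic or on substantial home insulin
        if rng.random() < 0.5:
            treatment = OutpatientTreatment.INSULIN_NAIVE
            tdd = None
            initial_bg = float(rng.randint(260, 400))  # at/above the cutoff
        else:
            treatment = OutpatientTreatment.INSULIN
            tdd = 0.5 * weight  # well above 0.2 IU/kg
            initial_bg = float(rng.randint(160, 320))
    profile = PatientProfile(
        weight=weight,
        age=age,
        nutritional_status=status,
        outpatient_treatment=treatment,
        outpatient_insulin_tdd=tdd,
        basal_product=basal,
        bolus_product=bolus,
    )
    return profile, initial_bg


def _trace_values(
    rng: random.Random, action: AdjustmentAction, regimen: RegimenType, k: int
) -> list[float]:
    if action is AdjustmentAction.CONSULT_SPECIALIST:
        values = [
            float(rng.randint(*_CONSULT_HYPO_BAND)),
            float(rng.randint(*_CONSULT_HYPER_BAND)),
        ]
        values += [float(rng.randint(*_CONSULT_FILL_BAND)) for _ in range(k - 2)]
        rng.shuffle(values)
        return values
    if action is AdjustmentAction.INCREASE_CATEGORY and regimen is RegimenType.STEP_WISE:
        band = _STEPWISE_INCREASE_BAND
    else:
        band = _ACTION_BANDS[action]
    return [float(rng.randint(*band)) for _ in range(k)]


def _trace(
    rng: random.Random,
    status: NutritionalStatus,
    action: AdjustmentAction,
    regimen: RegimenType,
) -> tuple[GlucoseMeasurement, ...]:
    contexts = monitoring_schedule(status)
    values = _trace_values(rng, action, regimen, len(contexts))
    out = []
    for i, (ctx, value) in enumerate(zip(contexts, values)):
        hour = (
            _EATING_TIMES[ctx]
            if status is NutritionalStatus.EATING
            else _Q6H_TIMES[i]
        )
        out.append(
            GlucoseMeasurement(
                timestamp=_BASE_DAY + timedelta(hours=hour), value=value, context=ctx
            )
        )
    return tuple(out)


def generate_fixtures(seed: int, n: int) -> list[ScenarioFixture]:
    """Generate ``n`` deterministic scenarios for the given seed.

    Templates are cycled in order, so any ``n >= 12`` covers every regimen,
    every nutritional status and every titration action at least once.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    fixtures: list[ScenarioFixture] = []
    for i in range(n):
        regimen, status, action = _TEMPLATES[i % len(_TEMPLATES)]
        rng = random.Random(seed * 100003 + i)
        profile, initial_bg = _draw_profile(rng, regimen, status)
        trace = _trace(rng, status, action, regimen)
        fixtures.append(
            ScenarioFixture(
                name=f"scenario_{i:03d}_{regimen.value.lower()}_{action.value.lower()}",
                seed=seed,
                profile=profile,
                initial_bg=initial_bg,
                bg_trace=trace,
                expected_regimen=regimen,
                expected_action=action,
            )
        )
    return fixtures


def fixture_to_dict(fixture: ScenarioFixture) -> dict:
    """Serialize a fixture: profile JSON plus the BG trace as CSV rows."""
    return {
        "name": fixture.name,
        "seed": fixture.seed,
        "profile": profile_to_dict(fixture.profile),
        "initial_bg": fixture.initial_bg,
        "bg_trace": [
            {
                "timestamp": m.timestamp.isoformat(),
                "value_mgdl": m.value,
                "context": m.context.value,
            }
            for m in fixture.bg_trace
        ],
        "expected_regimen": fixture.expected_regimen.value,
        "expected_action": fixture.expected_action.value,
    }
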