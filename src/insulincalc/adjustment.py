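"""Periodic dose titration from the bedside glucose record.

Every 24-48 h the average BG over the look-back window drives one of five
actions, in strict precedence order:

1. glycemic variability (hypo- and hyperglycemia in the same window) ->
   consult the endocrine/diabetes team; doses are left untouched;
2. step-wise regimen with average BG above 180 mg/dL -> add basal insulin;
3. average BG above 140 mg/dL -> raise the dose category one step;
4. average BG below 100 mg/dL -> lower the dose category one step;
5. otherwise (average inside the 100-140 mg/dL goal band) -> maintain.

Thresholds are strict inequalities, exactly as the protocol words them.
The bedtime supplemental rule for eating patients also lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from enum import Enum
from statistics import fmean

from .config import DEFAULT_SETTINGS, Settings
from .dosing import (
    RegimenType,
    build_correction_scale,
    category_to_tddi,
    sensitivity_factor,
    split_doses,
)
from .patient import GlucoseMeasurement, NutritionalStatus
from .regimen import Prescription

__all__ = [
    "AdjustmentAction",
    "AdjustmentRecommendation",
    "average_bg",
    "detect_variability",
    "recommend_adjustment",
    "bedtime_supplement",
    "apply_adjustment",
    "InsufficientMeasurementsError",
    "BedtimeRuleError",
]


class InsufficientMeasurementsError(ValueError):
    """No glucose measurements fall inside the review window."""


class BedtimeRuleError(ValueError):
    """Bedtime supplemental rule invoked for a patient who is not eating."""


class AdjustmentAction(str, Enum):
    INCREASE_CATEGORY = "INCREASE_CATEGORY"
    DECREASE_CATEGORY = "DECREASE_CATEGORY"
    MAINTAIN = "MAINTAIN"
    ADD_BASAL = "ADD_BASAL"
    CONSULT_SPECIALIST = "CONSULT_SPECIALIST"


@dataclass(frozen=True)
class AdjustmentRecommendation:
    """One titration decision with its rationale.

    ``rationale`` lists the identifiers of the rules that fired, in the
    order they were evaluated.
    """

    action: AdjustmentAction
    average_bg: float  # mg/dL, arithmetic mean over the window
    window: float  # hours
    rationale: tuple[str, ...]


def _in_window(
    measurements: list[GlucoseMeasurement] | tuple[GlucoseMeasurement, ...],
    window: float,
    now: datetime | None,
) -> list[GlucoseMeasurement]:
    if not measurements:
        return []
    anchor = now or max(m.timestamp for m in measurements)
    start = anchor - timedelta(hours=window)
    # half-open window (now - window, now]
    return [m for m in measurements if start < m.timestamp <= anchor]


def average_bg(
    measurements: list[GlucoseMeasurement] | tuple[GlucoseMeasurement, ...],
    window: float = 24.0,
    now: datetime | None = None,
) -> float:
    """Arithmetic mean BG over the half-open window (now - window, now].

    ``now`` defaults to the latest timestamp in the series, so a saved
    record re-analysed later gives the same answer.
    """
    if not 24.0 <= window <= 48.0:
        raise ValueError(f"review window must lie in [24, 48] hours, got {window}")
    inside = _in_window(measurements, window, now)
    if not inside:
        raise InsufficientMeasurementsError(
            "insufficient measurements: no BG values inside the review window"
        )
    return fmean(m.value for m in inside)


def detect_variability(
    measurements: list[GlucoseMeasurement] | tuple[GlucoseMeasurement, ...],
    window: float = 24.0,
    now: datetime | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> bool:
    """True when the window holds both a hypo- and a hyperglycemic value.

    Operationalizes "great glycemic variability" as at least one value
    below 70 mg/dL and at least one above 180 mg/dL in the same window.
    An empty series is not variable.
    """
    inside = _in_window(measurements, window, now)
    has_hypo = any(m.value < settings.variability_hypo_mgdl for m in inside)
    has_hyper = any(m.value > settings.variability_hyper_mgdl for m in inside)
    return has_hypo and has_hyper


def recommend_adjustment(
    prescription: Prescription,
    measurements: list[GlucoseMeasurement] | tuple[GlucoseMeasurement, ...],
    window: float = 24.0,
    now: datetime | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> AdjustmentRecommendation:
    """Apply the titration precedence list to the windowed BG record."""
    avg = average_bg(measurements, window, now)
    rationale: list[str] = [f"average_bg:{avg:.1f}mg/dL/{window:.0f}h"]

    if detect_variability(measurements, window, now, settings):
        rationale.append("variability:hypo+hyper->consult")
        action = AdjustmentAction.CONSULT_SPECIALIST
    elif (
        prescription.regimen is RegimenType.STEP_WISE
        and avg > settings.stepwise_add_basal_above_mgdl
    ):
        rationale.append(
            f"stepwise:avg>{settings.stepwise_add_basal_above_mgdl:.0f}->add_basal"
        )
        action = AdjustmentAction.ADD_BASAL
    elif avg > settings.avg_bg_increase_above_mgdl:
        rationale.append(f"avg>{settings.avg_bg_increase_above_mgdl:.0f}->increase")
        action = AdjustmentAction.INCREASE_CATEGORY
    elif avg < settings.avg_bg_decrease_below_mgdl:
        rationale.append(f"avg<{settings.avg_bg_decrease_below_mgdl:.0f}->decrease")
        action = AdjustmentAction.DECREASE_CATEGORY
    else:
        rationale.append("avg_in_goal_band->maintain")
        action = AdjustmentAction.MAINTAIN

    return AdjustmentRecommendation(
        action=action, average_bg=avg, window=window, rationale=tuple(rationale)
    )


def bedtime_supplement(
    bedtime_bg: float,
    nutritional_status: NutritionalStatus,
    settings: Settings = DEFAULT_SETTINGS,
) -> int:
    """Bedtime supplemental bolus dose for eating patients, in units.

    2 units for BG 250-350 mg/dL (band edges inclusive), 4 units above
    350 mg/dL, nothing below 250 mg/dL.
    """
    if nutritional_status is not NutritionalStatus.EATING:
        raise BedtimeRuleError("rule applies to eating patients")
    if bedtime_bg <= 0:
        raise ValueError(f"BG must be positive, got {bedtime_bg!r}")
    if bedtime_bg > settings.bedtime_supplement_high_mgdl:
        return 4
    if bedtime_bg >= settings.bedtime_supplement_low_mgdl:
        return 2
    return 0


def apply_adjustment(
    prescription: Prescription,
    recommendation: AdjustmentRecommendation,
    at: datetime | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> Prescription:
    """Regenerate the prescription doses for a titration recommendation.

    INCREASE/DECREASE move the dose category one step (clamped) and
    recompute TDDI, dose split and correction scale.  ADD_BASAL converts a
    step-wise regimen to full basal-bolus at the current category.
    MAINTAIN and CONSULT_SPECIALIST leave doses frozen.  The recommendation
    is always appended to the prescription's ``followup`` record.
    """
    profile = prescription.profile
    record = {
        "action": recommendation.action.value,
        "average_bg": round(recommendation.average_bg, 1),
        "window_hours": recommendation.window,
        "rationale": list(recommendation.rationale),
    }
    followup = prescription.followup + (record,)

    action = recommendation.action
    if action in (AdjustmentAction.MAINTAIN, AdjustmentAction.CONSULT_SPECIALIST):
        return replace(prescription, followup=followup)

    category = prescription.category
    regimen = prescription.regimen
    if action is AdjustmentAction.INCREASE_CATEGORY:
        category = category.shifted(+1, settings)
    elif action is AdjustmentAction.DECREASE_CATEGORY:
        category = category.shifted(-1, settings)
    elif action is AdjustmentAction.ADD_BASAL:
        regimen = RegimenType.BASAL_BOLUS

    tddi = category_to_tddi(category, profile.weight)
    sf = sensitivity_factor(tddi, profile.bolus_product.action_class, settings)
    split = split_doses(
        tddi, regimen, profile.basal_product, profile.nutritional_status, settings
    )
    scale = build_correction_scale(sf, settings=settings)
    audit = prescription.audit + (
        f"adjustment:{action.value}",
        f"category:{category.category}({category.coefficient:.2f}u/kg)",
        f"regimen:{regimen.value}",
    )
    return replace(
        prescription,
        regimen=regimen,
        category=category,
        dose_split=split,
        correction_scale=scale,
        audit=audit,
        followup=followup,
        created_at=at or prescription.created_at,
    )
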