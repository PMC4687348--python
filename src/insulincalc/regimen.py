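"""Initial regimen selection and prescription assembly.

Implements the admission decision tree: nutritional support, outpatient
diabetes treatment and the initial BG decide among three scheduled regimens
(basal-bolus, basal-plus, step-wise), and the corresponding bedside
monitoring schedule.  ``build_prescription`` composes the tree with the dose
engine into a complete prescription, recording every fired rule in an audit
trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone

from .config import DEFAULT_SETTINGS, Settings
from .dosing import (
    CorrectionScale,
    DoseCategory,
    DoseSplit,
    RegimenType,
    build_correction_scale,
    category_to_tddi,
    compute_category,
    sensitivity_factor,
    split_doses,
)
from .patient import (
    MeasurementContext,
    NutritionalStatus,
    OutpatientTreatment,
    PatientProfile,
    is_elderly,
    validate_profile,
)

__all__ = [
    "RegimenType",
    "Prescription",
    "select_initial_regimen",
    "monitoring_schedule",
    "build_prescription",
]

EATING_MONITORING = (
    MeasurementContext.PRE_BREAKFAST,
    MeasurementContext.PRE_LUNCH,
    MeasurementContext.PRE_DINNER,
    MeasurementContext.BEDTIME,
)
Q6H_MONITORING = (MeasurementContext.Q6H,) * 4


def _qualifies_low_dose(profile: PatientProfile, settings: Settings) -> bool:
    """Insulin exposure arm of the step-wise predicate.

    Insulin-naive and oral-agent-only patients qualify outright; patients on
    outpatient insulin qualify only when their home total daily dose is
    below 0.2 IU/kg.
    """
    if profile.outpatient_treatment is not OutpatientTreatment.INSULIN:
        return True
    tdd = profile.outpatient_insulin_tdd or 0.0
    return tdd / profile.weight < settings.stepwise_low_dose_iu_per_kg


def select_initial_regimen(
    profile: PatientProfile,
    initial_bg: float,
    settings: Settings = DEFAULT_SETTINGS,
) -> RegimenType:
    """Choose the admission insulin regimen.

    Patients not eating (NPO or enteral feeding) receive basal-plus.  Eating
    patients who are insulin-naive (or on < 0.2 IU/kg outpatient insulin)
    with initial BG below 250 mg/dL start step-wise; everyone else starts on
    the full basal-bolus regimen.
    """
    if initial_bg <= 0:
        raise ValueError(f"initial BG must be positive, got {initial_bg!r}")
    if profile.nutritional_status in (NutritionalStatus.NPO, NutritionalStatus.ENTERAL):
        return RegimenType.BASAL_PLUS
    if (
        _qualifies_low_dose(profile, settings)
        and initial_bg < settings.stepwise_initial_bg_cutoff_mgdl
    ):
        return RegimenType.STEP_WISE
    return RegimenType.BASAL_BOLUS


def monitoring_schedule(
    nutritional_status: NutritionalStatus,
) -> tuple[MeasurementContext, ...]:
    """BG testing times: before meals and at bedtime when eating, else q6h."""
    if nutritional_status is NutritionalStatus.EATING:
        return EATING_MONITORING
    return Q6H_MONITORING


@dataclass(frozen=True)
class Prescription:
    """A complete subcutaneous insulin prescription.

    Carries the regimen, dose category, scheduled doses, correction scale
    and monitoring plan, plus the profile it was derived from, the audit
    trail of fired rules, and any follow-up recommendations appended by the
    titration engine.
    """

    regimen: RegimenType
    category: DoseCategory
    dose_split: DoseSplit
    correction_scale: CorrectionScale
    monitoring: tuple[MeasurementContext, ...]
    created_at: datetime
    profile: PatientProfile
    initial_bg: float
    audit: tuple[str, ...] = ()
    followup: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.regimen is RegimenType.STEP_WISE and self.dose_split.basal_total != 0:
            raise ValueError("step-wise prescriptions must not schedule basal insulin")
        if self.regimen is RegimenType.BASAL_PLUS and self.dose_split.prandial_total != 0:
            raise ValueError("basal-plus prescriptions must not schedule prandial insulin")
        if self.monitoring != monitoring_schedule(self.profile.nutritional_status):
            raise ValueError("monitoring schedule inconsistent with nutritional status")


def build_prescription(
    profile: PatientProfile,
    initial_bg: float,
    at: datetime | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> Prescription:
    """Compose category, regimen, dose split and correction scale.

    Every decision the rules make is recorded as a short identifier in the
    prescription's audit trail so a reviewer can see which rules fired.
    """
    profile = validate_profile(profile, settings)
    audit: list[str] = []

    category = compute_category(profile, settings)
    for flag, name in (
        (is_elderly(profile, settings), "modifier:elderly(-1)"),
        (profile.renal_impairment, "modifier:renal_impairment(-1)"),
        (profile.hepatic_impairment, "modifier:hepatic_impairment(-1)"),
        (profile.obesity, "modifier:obesity(+1)"),
        (profile.high_dose_corticosteroids, "modifier:high_dose_corticosteroids(+1)"),
    ):
        if flag:
            audit.append(name)
    audit.append(f"category:{category.category}({category.coefficient:.2f}u/kg)")

    tddi = category_to_tddi(category, profile.weight)
    audit.append(f"tddi:{tddi:.1f}u/day")

    regimen = select_initial_regimen(profile, initial_bg, settings)
    audit.append(f"regimen:{regimen.value}")

    sf = sensitivity_factor(tddi, profile.bolus_product.action_class, settings)
    rule = (
        settings.rapid_rule_constant
        if profile.bolus_product.action_class.value == "RAPID"
        else settings.short_rule_constant
    )
    audit.append(f"sensitivity_factor:{sf:.1f}mg/dL/u({rule:.0f}-rule)")

    scale = build_correction_scale(sf, settings=settings)
    split = split_doses(
        tddi, regimen, profile.basal_product, profile.nutritional_status, settings
    )
    monitoring = monitoring_schedule(profile.nutritional_status)
    audit.append(
        "monitoring:pre-meals+bedtime"
        if profile.nutritional_status is NutritionalStatus.EATING
        else "monitoring:q6h"
    )

    return Prescription(
        regimen=regimen,
        category=category,
        dose_split=split,
        correction_scale=scale,
        monitoring=monitoring,
        created_at=at or datetime.now(timezone.utc),
        profile=profile,
        initial_bg=initial_bg,
        audit=tuple(audit),
    )
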