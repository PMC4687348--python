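"""Dose arithmetic: category system, TDDI, sensitivity factor, dose split.

The protocol indexes the total daily dose of insulin (TDDI) by an integer
*dose category*: category 8 is the standard 0.4 units/kg and each category
step moves the coefficient by 0.05 units/kg.  Clinical modifier flags shift
the category down (hypoglycemia risk: elderly, renal or hepatic impairment)
or up (insulin resistance: obesity, high-dose corticosteroids), one step
each, combined additively.

The sensitivity factor (expected BG drop in mg/dL per unit of bolus insulin)
follows the 1800 Rule for rapid-acting and the 1500 Rule for short-acting
(regular) insulin: SF = constant / TDDI.

All doses are carried at full precision; rounding (half-up, to whole units,
because pens and syringes deliver whole units) happens only when a dose is
placed on the administration schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .config import DEFAULT_SETTINGS, Settings
from .patient import (
    ActionClass,
    InsulinProduct,
    NutritionalStatus,
    PatientProfile,
    is_elderly,
)

__all__ = [
    "DoseCategory",
    "CorrectionScale",
    "DoseSplit",
    "RegimenType",
    "compute_category",
    "category_to_tddi",
    "sensitivity_factor",
    "build_correction_scale",
    "split_doses",
    "round_half_up",
    "DoseComputationError",
    "STANDARD_CATEGORY",
    "STANDARD_COEFFICIENT",
    "COEFFICIENT_STEP",
]

STANDARD_CATEGORY = 8
STANDARD_COEFFICIENT = 0.4  # units/kg at category 8
COEFFICIENT_STEP = 0.05  # units/kg per category step

MEALS = ("breakfast", "lunch", "dinner")


class DoseComputationError(ValueError):
    """A dose computation was asked for out-of-domain inputs."""


class RegimenType(str, Enum):
    """Scheduled insulin regimen composition.

    BASAL_BOLUS: basal + prandial + correction (eating patients).
    BASAL_PLUS: basal + correction only; prandial withdrawn (NPO/enteral).
    STEP_WISE: prandial + correction without basal (insulin-naive or
    low-dose patients with modest hyperglycemia); basal added later if
    average BG stays high.
    """

    BASAL_BOLUS = "BASAL_BOLUS"
    BASAL_PLUS = "BASAL_PLUS"
    STEP_WISE = "STEP_WISE"


def round_half_up(x: float) -> int:
    """Round to the nearest whole unit, ties away from zero toward +inf.

    Python's built-in ``round`` is banker's rounding; insulin scheduling
    uses conventional half-up (5.5 -> 6).
    """
    if x < 0:
        raise DoseComputationError(f"cannot schedule a negative dose: {x}")
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class DoseCategory:
    """Integer dose category; the per-kg coefficient is derived from it."""

    category: int

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise DoseComputationError(
                f"category {self.category} implies a non-positive coefficient"
            )

    @property
    def coefficient(self) -> float:
        """units/kg: 0.4 + 0.05 x (category - 8)."""
        return STANDARD_COEFFICIENT + COEFFICIENT_STEP * (
            self.category - STANDARD_CATEGORY
        )

    def shifted(self, steps: int, settings: Settings = DEFAULT_SETTINGS) -> "DoseCategory":
        """Move by ``steps`` categories, clamped to the configured bounds."""
        new = min(settings.category_max, max(settings.category_min, self.category + steps))
        return DoseCategory(new)


def compute_category(
    profile: PatientProfile, settings: Settings = DEFAULT_SETTINGS
) -> DoseCategory:
    """Derive the dose category from the profile's modifier flags.

    Starts at the standard category 8 and applies one step per flag:
    -1 each for elderly age, renal impairment, hepatic impairment;
    +1 each for obesity and high-dose corticosteroids.  The result is
    clamped to ``[settings.category_min, settings.category_max]``.
    """
    offset = 0
    if is_elderly(profile, settings):
        offset -= 1
    if profile.renal_impairment:
        offset -= 1
    if profile.hepatic_impairment:
        offset -= 1
    if profile.obesity:
        offset += 1
    if profile.high_dose_corticosteroids:
        offset += 1
    raw = STANDARD_CATEGORY + offset
    clamped = min(settings.category_max, max(settings.category_min, raw))
    return DoseCategory(clamped)


def category_to_tddi(category: DoseCategory, weight: float) -> float:
    """TDDI in units/day = coefficient x body weight, unrounded."""
    if not (math.isfinite(weight) and weight > 0):
        raise DoseComputationError("weight must be positive")
    return category.coefficient * weight


def sensitivity_factor(
    tddi: float,
    bolus_class: ActionClass,
    settings: Settings = DEFAULT_SETTINGS,
) -> float:
    """Sensitivity (correction) factor in mg/dL per unit.

    1800/TDDI for rapid-acting bolus insulin, 1500/TDDI for short-acting
    (regular).  Basal action classes are rejected: the correction factor is
    defined only for bolus insulin.
    """
    if not (math.isfinite(tddi) and tddi > 0):
        raise DoseComputationError(f"TDDI must be positive, got {tddi!r}")
    if bolus_class is ActionClass.RAPID:
        return settings.rapid_rule_constant / tddi
    if bolus_class is ActionClass.SHORT:
        return settings.short_rule_constant / tddi
    raise DoseComputationError(
        f"sensitivity factor is defined for RAPID or SHORT bolus insulin, "
        f"got {bolus_class.value}"
    )


@dataclass(frozen=True)
class CorrectionScale:
    """Correction (supplemental) insulin as a function of measured BG.

    ``entries`` tabulate contiguous BG bands and the whole-unit correction
    dose in each, exactly consistent with the half-up rounded formula
    ``max(0, round((BG - target)/SF))``; the top band is capped and carries
    escalation advice.
    """

    sensitivity_factor: float  # mg/dL per unit
    correction_target: float  # mg/dL
    cap_units: int
    entries: tuple[tuple[float, float, int], ...]  # (bg_lower, bg_upper, units)

    def correction_units(self, bg: float) -> int:
        """Correction dose for a measured BG, capped at ``cap_units``."""
        if not math.isfinite(bg) or bg <= 0:
            raise DoseComputationError(f"BG must be positive, got {bg!r}")
        raw = (bg - self.correction_target) / self.sensitivity_factor
        return min(self.cap_units, max(0, round_half_up(max(0.0, raw))))

    def requires_escalation(self, bg: float) -> bool:
        """True when the uncapped formula exceeds the cap."""
        raw = (bg - self.correction_target) / self.sensitivity_factor
        return raw > self.cap_units + 0.5


def build_correction_scale(
    sf: float,
    correction_target: float | None = None,
    settings: Settings = DEFAULT_SETTINGS,
) -> CorrectionScale:
    """Tabulate the correction scale for a given sensitivity factor.

    The 0-unit band runs from the target to target + SF/2 (below which the
    half-up formula still rounds to zero); each subsequent band has width SF
    and one more unit, up to the configured cap.
    """
    target = settings.correction_target_mgdl if correction_target is None else correction_target
    if not (math.isfinite(sf) and sf > 0):
        raise DoseComputationError(f"sensitivity factor must be positive, got {sf!r}")
    if not 100.0 <= target <= 180.0:
        raise DoseComputationError(
            f"correction target must lie in [100, 180] mg/dL, got {target}"
        )
    cap = settings.correction_cap_units
    entries: list[tuple[float, float, int]] = [(target, target + sf / 2.0, 0)]
    for units in range(1, cap):
        lower = target + (units - 0.5) * sf
        entries.append((lower, lower + sf, units))
    entries.append((target + (cap - 0.5) * sf, math.inf, cap))
    return CorrectionScale(
        sensitivity_factor=sf,
        correction_target=target,
        cap_units=cap,
        entries=tuple(entries),
    )


@dataclass(frozen=True)
class DoseSplit:
    """Scheduled basal and prandial doses derived from the TDDI.

    ``basal_total`` and ``prandial_total`` are the pre-rounding component
    totals (each TDDI/2 when present); the schedules carry the whole-unit
    doses actually administered.
    """

    tddi: float  # units/day, unrounded
    basal_total: float  # units/day before rounding
    prandial_total: float  # units/day before rounding
    basal_schedule: tuple[tuple[str, int], ...]  # (time-of-day, units)
    prandial_per_meal: int  # rounded units per major meal
    prandial_schedule: tuple[tuple[str, int], ...]

    @property
    def scheduled_total(self) -> int:
        return sum(u for _, u in self.basal_schedule) + sum(
            u for _, u in self.prandial_schedule
        )


def _basal_schedule(
    basal_total: float, product: InsulinProduct, settings: Settings
) -> tuple[tuple[str, int], ...]:
    if basal_total <= 0:
        return ()
    if product.name == "NPH":
        if settings.nph_doses_per_day == 3:
            per = basal_total / 3.0
            return (
                ("morning", round_half_up(per)),
                ("afternoon", round_half_up(per)),
                ("evening", round_half_up(per)),
            )
        # twice daily: 2/3 morning + 1/3 evening
        return (
            ("morning", round_half_up(basal_total * 2.0 / 3.0)),
            ("evening", round_half_up(basal_total / 3.0)),
        )
    # long-acting analogues (glargine, detemir): once daily in full
    return (("morning", round_half_up(basal_total)),)


def split_doses(
    tddi: float,
    regimen: RegimenType,
    basal_product: InsulinProduct,
    nutritional_status: NutritionalStatus,
    settings: Settings = DEFAULT_SETTINGS,
) -> DoseSplit:
    """Split the TDDI into scheduled basal and prandial components.

    BASAL_BOLUS: 50 % basal + 50 % prandial divided over the three major
    meals.  BASAL_PLUS: 50 % basal, prandial withdrawn (patient not eating).
    STEP_WISE: basal withheld, the 50 % prandial share divided over meals.
    The remaining TDDI share is covered by correction dosing, not scheduled
    here.
    """
    if not (math.isfinite(tddi) and tddi > 0):
        raise DoseComputationError(f"TDDI must be positive, got {tddi!r}")
    half = tddi / 2.0
    basal_total = 0.0 if regimen is RegimenType.STEP_WISE else half
    prandial_total = 0.0 if regimen is RegimenType.BASAL_PLUS else half

    basal_sched = _basal_schedule(basal_total, basal_product, settings)
    if prandial_total > 0:
        per_meal = round_half_up(prandial_total / len(MEALS))
        prandial_sched = tuple((meal, per_meal) for meal in MEALS)
    else:
        per_meal = 0
        prandial_sched = ()
    return DoseSplit(
        tddi=tddi,
        basal_total=basal_total,
        prandial_total=prandial_total,
        basal_schedule=basal_sched,
        prandial_per_meal=per_meal,
        prandial_schedule=prandial_sched,
    )
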