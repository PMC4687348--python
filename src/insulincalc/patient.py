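"""Domain types shared by every rule module.

Patients are described by a :class:`PatientProfile` (the clinical flags that
drive dose category and regimen choice), insulin products by a fixed
seven-item formulary, and bedside glucose readings by timestamped
:class:`GlucoseMeasurement` records in mg/dL (the canonical internal unit;
mmol/L appears only in rendered output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum

from .config import DEFAULT_SETTINGS, Settings

__all__ = [
    "NutritionalStatus",
    "OutpatientTreatment",
    "InsulinRole",
    "ActionClass",
    "InsulinProduct",
    "MeasurementContext",
    "GlucoseMeasurement",
    "PatientProfile",
    "classify_insulin",
    "validate_profile",
    "is_elderly",
    "mgdl_to_mmol",
    "ProfileValidationError",
    "UnknownInsulinError",
    "UnitConversionError",
]

MGDL_PER_MMOL = 18.0


class ProfileValidationError(ValueError):
    """A patient profile violates an invariant; message names the field."""


class UnknownInsulinError(KeyError):
    """Insulin name outside the seven-product formulary."""


class UnitConversionError(ValueError):
    """Glucose unit conversion asked for a physically impossible value."""


class NutritionalStatus(str, Enum):
    EATING = "EATING"
    NPO = "NPO"  # nil per os: taking nothing by mouth
    ENTERAL = "ENTERAL"  # continuous enteral feeding


class OutpatientTreatment(str, Enum):
    INSULIN_NAIVE = "INSULIN_NAIVE"
    ORAL_AGENTS = "ORAL_AGENTS"
    INSULIN = "INSULIN"


class InsulinRole(str, Enum):
    BASAL = "BASAL"
    BOLUS = "BOLUS"


class ActionClass(str, Enum):
    INTERMEDIATE = "INTERMEDIATE"
    LONG = "LONG"
    SHORT = "SHORT"
    RAPID = "RAPID"


# The complete inpatient formulary: human insulins (NPH, regular) and the
# analogues.  Role and action class are fixed per product name.
_FORMULARY: dict[str, tuple[InsulinRole, ActionClass]] = {
    "NPH": (InsulinRole.BASAL, ActionClass.INTERMEDIATE),
    "GLARGINE": (InsulinRole.BASAL, ActionClass.LONG),
    "DETEMIR": (InsulinRole.BASAL, ActionClass.LONG),
    "REGULAR": (InsulinRole.BOLUS, ActionClass.SHORT),
    "LISPRO": (InsulinRole.BOLUS, ActionClass.RAPID),
    "ASPART": (InsulinRole.BOLUS, ActionClass.RAPID),
    "GLULISINE": (InsulinRole.BOLUS, ActionClass.RAPID),
}


@dataclass(frozen=True)
class InsulinProduct:
    """One formulary product; only formulary-consistent triples construct."""

    name: str
    role: InsulinRole
    action_class: ActionClass

    def __post_init__(self) -> None:
        expected = _FORMULARY.get(self.name)
        if expected is None:
            raise UnknownInsulinError(f"unknown insulin product: {self.name!r}")
        if (self.role, self.action_class) != expected:
            raise ProfileValidationError(
                f"{self.name} must have role {expected[0].value} and action "
                f"class {expected[1].value}, got ({self.role.value}, "
                f"{self.action_class.value})"
            )


def classify_insulin(name: str) -> InsulinProduct:
    """Map a formulary name to its product with fixed role and action class.

    >>> classify_insulin("REGULAR").action_class
    <ActionClass.SHORT: 'SHORT'>
    """
    key = str(name).strip().upper()
    if key not in _FORMULARY:
        raise UnknownInsulinError(
            f"unknown insulin product: {name!r}; expected one of "
            f"{sorted(_FORMULARY)}"
        )
    role, action = _FORMULARY[key]
    return InsulinProduct(key, role, action)


class MeasurementContext(str, Enum):
    PRE_BREAKFAST = "PRE_BREAKFAST"
    PRE_LUNCH = "PRE_LUNCH"
    PRE_DINNER = "PRE_DINNER"
    BEDTIME = "BEDTIME"
    Q6H = "Q6H"


@dataclass(frozen=True)
class GlucoseMeasurement:
    """One bedside capillary glucose reading, value in mg/dL."""

    timestamp: datetime
    value: float
    context: MeasurementContext = MeasurementContext.Q6H

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value <= 0:
            raise ProfileValidationError(
                f"glucose value must be a positive finite mg/dL number, "
                f"got {self.value!r}"
            )


def _default_basal() -> InsulinProduct:
    return classify_insulin("NPH")


def _default_bolus() -> InsulinProduct:
    return classify_insulin("REGULAR")


@dataclass(frozen=True)
class PatientProfile:
    """Clinical flags and choices that drive dosing and regimen selection.

    The impairment/obesity/corticosteroid fields are clinician-supplied
    booleans; the protocol names these modifier factors without numeric
    eGFR/BMI/dose thresholds, so no calculator second-guesses the clinician.
    """

    weight: float  # kg
    age: float  # years
    renal_impairment: bool = False
    hepatic_impairment: bool = False
    high_dose_corticosteroids: bool = False
    obesity: bool = False
    nutritional_status: NutritionalStatus = NutritionalStatus.EATING
    outpatient_treatment: OutpatientTreatment = OutpatientTreatment.INSULIN_NAIVE
    outpatient_insulin_tdd: float | None = None  # units/day, only if on insulin
    basal_product: InsulinProduct = field(default_factory=_default_basal)
    bolus_product: InsulinProduct = field(default_factory=_default_bolus)


def validate_profile(
    profile: PatientProfile, settings: Settings = DEFAULT_SETTINGS
) -> PatientProfile:
    """Check every profile invariant; return the (normalized) profile.

    Raises :class:`ProfileValidationError` naming the offending field.  A
    stray ``outpatient_insulin_tdd`` on a non-insulin-treated patient is
    normalized away rather than rejected.
    """
    if not (math.isfinite(profile.weight) and profile.weight > 0):
        raise ProfileValidationError("weight must be positive")
    if not (math.isfinite(profile.age) and profile.age >= 0):
        raise ProfileValidationError("age must be non-negative")
    if profile.outpatient_treatment is OutpatientTreatment.INSULIN:
        tdd = profile.outpatient_insulin_tdd
        if tdd is None:
            raise ProfileValidationError(
                "outpatient_insulin_tdd is required when outpatient_treatment "
                "is INSULIN"
            )
        if not (math.isfinite(tdd) and tdd >= 0):
            raise ProfileValidationError(
                "outpatient_insulin_tdd must be non-negative"
            )
    elif profile.outpatient_insulin_tdd is not None:
        profile = replace(profile, outpatient_insulin_tdd=None)
    if profile.basal_product.role is not InsulinRole.BASAL:
        raise ProfileValidationError(
            f"basal_product must have role BASAL, got "
            f"{profile.basal_product.name} ({profile.basal_product.role.value})"
        )
    if profile.bolus_product.role is not InsulinRole.BOLUS:
        raise ProfileValidationError(
            f"bolus_product must have role BOLUS, got "
            f"{profile.bolus_product.name} ({profile.bolus_product.role.value})"
        )
    return profile


def is_elderly(profile: PatientProfile, settings: Settings = DEFAULT_SETTINGS) -> bool:
    return profile.age >= settings.elderly_age_years


def mgdl_to_mmol(value: float, ndigits: int = 1) -> float:
    """Convert a glucose concentration from mg/dL to mmol/L.

    Uses the fixed factor 18.0 mg/dL per mmol/L and rounds to ``ndigits``
    (one decimal for display): 180 -> 10.0, 140 -> 7.8.
    """
    if not math.isfinite(value) or value < 0:
        raise UnitConversionError(
            f"glucose concentration must be non-negative, got {value!r}"
        )
    return round(value / MGDL_PER_MMOL, ndigits)
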