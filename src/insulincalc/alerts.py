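"""Per-measurement safety alerts and the hypoglycemia order set.

Two emergencies are screened on every single reading: BG above 250 mg/dL
raises a diabetic-ketoacidosis rule-out message, and BG below 70 mg/dL
raises a hypoglycemia alert carrying a treatment order set.  The order set
is a three-way decision table on consciousness and intravenous access;
intramuscular glucagon appears only when the patient is not alert and has
no peripheral IV line.  Alert evaluation is stateless: the same measurement
always yields the same alerts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DEFAULT_SETTINGS, Settings
from .patient import GlucoseMeasurement

__all__ = [
    "AlertKind",
    "Alert",
    "PatientState",
    "evaluate_alerts",
    "hypoglycemia_orders",
]

from enum import Enum


class AlertKind(str, Enum):
    DKA_RULE_OUT = "DKA_RULE_OUT"
    HYPOGLYCEMIA = "HYPOGLYCEMIA"
    VARIABILITY_CONSULT = "VARIABILITY_CONSULT"


@dataclass(frozen=True)
class PatientState:
    """Bedside state consulted by the hypoglycemia order set."""

    conscious: bool = True
    iv_line: bool = False


@dataclass(frozen=True)
class Alert:
    kind: AlertKind
    triggering_bg: float  # mg/dL
    message: str
    orders: tuple[str, ...] = ()


# Template order text: the protocol fixes only the glucagon condition; the
# carbohydrate/dextrose amounts and the 15-minute recheck follow standard
# hospital hypoglycemia order sets and are configurable downstream.
_RECHECK = "Recheck capillary BG in 15 minutes; repeat treatment until BG >= 100 mg/dL"
_ORAL = "Give 15-20 g fast-acting oral carbohydrate (e.g. glucose tablets or juice)"
_IV_DEXTROSE = "Give 25 mL 50% dextrose (D50W) IV push"
_GLUCAGON = "Give glucagon 1 mg intramuscularly; obtain IV access"


def hypoglycemia_orders(conscious: bool, iv_line: bool) -> tuple[str, ...]:
    """Treatment orders for a hypoglycemia episode.

    Conscious patients take oral carbohydrate; unconscious patients with IV
    access get IV dextrose; glucagon IM is reserved for the patient who is
    not alert and has no peripheral IV line.
    """
    if conscious:
        return (_ORAL, _RECHECK)
    if iv_line:
        return (_IV_DEXTROSE, _RECHECK)
    return (_GLUCAGON, _RECHECK)


def evaluate_alerts(
    measurement: GlucoseMeasurement,
    alert_state: PatientState = PatientState(),
    settings: Settings = DEFAULT_SETTINGS,
) -> list[Alert]:
    """Screen one glucose measurement for emergency conditions.

    BG > 250 mg/dL -> DKA rule-out message; BG < 70 mg/dL -> hypoglycemia
    alert with the order set (annotated severe below 40 mg/dL); in-range
    values raise nothing.  The two conditions are mutually exclusive.
    """
    bg = measurement.value
    alerts: list[Alert] = []
    if bg > settings.dka_rule_out_above_mgdl:
        alerts.append(
            Alert(
                kind=AlertKind.DKA_RULE_OUT,
                triggering_bg=bg,
                message=(
                    f"BG {bg:.0f} mg/dL exceeds "
                    f"{settings.dka_rule_out_above_mgdl:.0f} mg/dL: rule out "
                    "diabetic ketoacidosis"
                ),
            )
        )
    elif bg < settings.hypoglycemia_alert_mgdl:
        severe = bg < settings.severe_hypoglycemia_mgdl
        label = "SEVERE hypoglycemia" if severe else "Hypoglycemia"
        alerts.append(
            Alert(
                kind=AlertKind.HYPOGLYCEMIA,
                triggering_bg=bg,
                message=f"{label}: BG {bg:.0f} mg/dL "
                f"(< {settings.hypoglycemia_alert_mgdl:.0f} mg/dL)",
                orders=hypoglycemia_orders(alert_state.conscious, alert_state.iv_line),
            )
        )
    return alerts
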