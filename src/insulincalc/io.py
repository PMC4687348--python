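"""File formats and the two end-to-end workflows.

Patient profiles travel as JSON documents (field names exactly as in
:class:`~insulincalc.patient.PatientProfile`), bedside glucose series as CSV
with header ``timestamp,value_mgdl,context`` and ISO-8601 timezone-aware
timestamps.  Prescriptions serialize to JSON plus a human-readable order
sheet.  ``run_init`` and ``run_followup`` are the library counterparts of
the two CLI subcommands: admission prescription and 24-48 h titration.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from datetime import datetime
from pathlib import Path
from typing import Any

import pandas as pd

from .adjustment import apply_adjustment, recommend_adjustment
from .alerts import Alert, PatientState, evaluate_alerts
from .config import DEFAULT_SETTINGS, Settings
from .dosing import CorrectionScale, DoseCategory, DoseSplit, RegimenType
from .patient import (
    GlucoseMeasurement,
    MeasurementContext,
    NutritionalStatus,
    OutpatientTreatment,
    PatientProfile,
    ProfileValidationError,
    classify_insulin,
    mgdl_to_mmol,
    validate_profile,
)
from .regimen import Prescription, build_prescription

__all__ = [
    "PROFILE_SCHEMA",
    "SchemaError",
    "profile_from_dict",
    "profile_to_dict",
    "load_profile",
    "load_bg_series",
    "prescription_to_dict",
    "prescription_from_dict",
    "write_prescription",
    "read_prescription",
    "render_order_sheet",
    "run_init",
    "run_followup",
]


class SchemaError(ValueError):
    """An input document does not match its published schema."""


# Published JSON schema for the patient-profile document (draft-07 dialect).
PROFILE_SCHEMA: dict[str, Any] = {
    "$schema": "http://json-schema.org/draft-07/schema#",
    "title": "PatientProfile",
    "type": "object",
    "required": ["weight", "age"],
    "additionalProperties": False,
    "properties": {
        "weight": {"type": "number", "exclusiveMinimum": 0, "description": "kg"},
        "age": {"type": "number", "minimum": 0, "description": "years"},
        "renal_impairment": {"type": "boolean", "default": False},
        "hepatic_impairment": {"type": "boolean", "default": False},
        "high_dose_corticosteroids": {"type": "boolean", "default": False},
        "obesity": {"type": "boolean", "default": False},
        "nutritional_status": {
            "type": "string",
            "enum": [s.value for s in NutritionalStatus],
            "default": "EATING",
        },
        "outpatient_treatment": {
            "type": "string",
            "enum": [t.value for t in OutpatientTreatment],
            "default": "INSULIN_NAIVE",
        },
        "outpatient_insulin_tdd": {
            "type": ["number", "null"],
            "minimum": 0,
            "description": "units/day; required when outpatient_treatment is INSULIN",
        },
        "basal_product": {
            "type": "string",
            "enum": ["NPH", "GLARGINE", "DETEMIR"],
            "default": "NPH",
        },
        "bolus_product": {
            "type": "string",
            "enum": ["REGULAR", "LISPRO", "ASPART", "GLULISINE"],
            "default": "REGULAR",
        },
    },
}

_BOOL_FIELDS = (
    "renal_impairment",
    "hepatic_impairment",
    "high_dose_corticosteroids",
    "obesity",
)


def profile_from_dict(
    data: dict[str, Any], settings: Settings = DEFAULT_SETTINGS
) -> PatientProfile:
    """Build and validate a profile from its JSON document.

    Raises :class:`SchemaError` with a field-level message for any
    violation, so CLI callers can report exactly what to fix.
    """
    if not isinstance(data, dict):
        raise SchemaError("profile document must be a JSON object")
    allowed = set(PROFILE_SCHEMA["properties"])
    unknown = set(data) - allowed
    if unknown:
        raise SchemaError(f"unknown profile field(s): {sorted(unknown)}")
    for req in PROFILE_SCHEMA["required"]:
        if req not in data:
            raise SchemaError(f"missing required profile field: {req!r}")
    for name in ("weight", "age", "outpatient_insulin_tdd"):
        v = data.get(name)
        if v is not None and not isinstance(v, (int, float)):
            raise SchemaError(f"profile field {name!r} must be a number, got {v!r}")
    for name in _BOOL_FIELDS:
        v = data.get(name, False)
        if not isinstance(v, bool):
            raise SchemaError(f"profile field {name!r} must be a boolean, got {v!r}")
    try:
        profile = PatientProfile(
            weight=float(data["weight"]),
            age=float(data["age"]),
            renal_impairment=data.get("renal_impairment", False),
            hepatic_impairment=data.get("hepatic_impairment", False),
            high_dose_corticosteroids=data.get("high_dose_corticosteroids", False),
            obesity=data.get("obesity", False),
            nutritional_status=NutritionalStatus(data.get("nutritional_status", "EATING")),
            outpatient_treatment=OutpatientTreatment(
                data.get("outpatient_treatment", "INSULIN_NAIVE")
            ),
            outpatient_insulin_tdd=(
                None
                if data.get("outpatient_insulin_tdd") is None
                else float(data["outpatient_insulin_tdd"])
            ),
            basal_product=classify_insulin(data.get("basal_product", "NPH")),
            bolus_product=classify_insulin(data.get("bolus_product", "REGULAR")),
        )
        return validate_profile(profile, settings)
    except (ValueError, KeyError) as exc:
        raise SchemaError(str(exc.args[0] if exc.args else exc)) from exc


def profile_to_dict(profile: PatientProfile) -> dict[str, Any]:
    return {
        "weight": profile.weight,
        "age": profile.age,
        "renal_impairment": profile.renal_impairment,
        "hepatic_impairment": profile.hepatic_impairment,
        "high_dose_corticosteroids": profile.high_dose_corticosteroids,
        "obesity": profile.obesity,
        "nutritional_status": profile.nutritional_status.value,
        "outpatient_treatment": profile.outpatient_treatment.value,
        "outpatient_insulin_tdd": profile.outpatient_insulin_tdd,
        "basal_product": profile.basal_product.name,
        "bolus_product": profile.bolus_product.name,
    }


def load_profile(path: str | Path, settings: Settings = DEFAULT_SETTINGS) -> PatientProfile:
    """Read and validate a patient-profile JSON document."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"profile file {path} is not valid JSON: {exc}") from exc
    return profile_from_dict(data, settings)


def _parse_timestamp(raw: str) -> datetime:
    try:
        ts = datetime.fromisoformat(str(raw).replace("Z", "+00:00"))
    except ValueError as exc:
        raise SchemaError(f"timestamp {raw!r} is not ISO-8601") from exc
    if ts.tzinfo is None:
        raise SchemaError(f"timestamp {raw!r} must carry a timezone offset")
    return ts


def load_bg_series(path: str | Path) -> list[GlucoseMeasurement]:
    """Read a bedside glucose series CSV.

    Expects header ``timestamp,value_mgdl,context``; timestamps must be
    ISO-8601 with timezone, contexts one of the monitoring contexts.
    Returns measurements sorted by timestamp.
    """
    frame = pd.read_csv(path, dtype=str)
    expected = ["timestamp", "value_mgdl", "context"]
    if list(frame.columns) != expected:
        raise SchemaError(
            f"BG series {path} must have header {','.join(expected)}, "
            f"got {','.join(frame.columns)}"
        )
    out: list[GlucoseMeasurement] = []
    for row in frame.itertuples(index=False):
        ts = _parse_timestamp(row.timestamp)
        try:
            value = float(row.value_mgdl)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"value_mgdl {row.value_mgdl!r} is not a number") from exc
        if not math.isfinite(value) or value <= 0:
            raise SchemaError(f"value_mgdl must be positive, got {value}")
        try:
            ctx = MeasurementContext(str(row.context).strip().upper())
        except ValueError as exc:
            raise SchemaError(f"unknown measurement context {row.context!r}") from exc
        out.append(GlucoseMeasurement(timestamp=ts, value=value, context=ctx))
    return sorted(out, key=lambda m: m.timestamp)


def _alert_to_dict(alert: Alert) -> dict[str, Any]:
    return {
        "kind": alert.kind.value,
        "triggering_bg": alert.triggering_bg,
        "message": alert.message,
        "orders": list(alert.orders),
    }


def prescription_to_dict(
    prescription: Prescription, alerts: list[Alert] | tuple[Alert, ...] = ()
) -> dict[str, Any]:
    """Serialize a prescription (plus any active alerts) to plain JSON types."""
    scale = prescription.correction_scale
    return {
        "regimen": prescription.regimen.value,
        "category": {
            "category": prescription.category.category,
            "coefficient_u_per_kg": round(prescription.category.coefficient, 2),
        },
        "dose_split": {
            "tddi": prescription.dose_split.tddi,
            "basal_total": prescription.dose_split.basal_total,
            "prandial_total": prescription.dose_split.prandial_total,
            "basal_schedule": [list(x) for x in prescription.dose_split.basal_schedule],
            "prandial_per_meal": prescription.dose_split.prandial_per_meal,
            "prandial_schedule": [
                list(x) for x in prescription.dose_split.prandial_schedule
            ],
        },
        "correction_scale": {
            "sensitivity_factor": scale.sensitivity_factor,
            "correction_target": scale.correction_target,
            "cap_units": scale.cap_units,
            "entries": [
                [lo, None if math.isinf(hi) else hi, units]
                for lo, hi, units in scale.entries
            ],
        },
        "monitoring": [m.value for m in prescription.monitoring],
        "created_at": prescription.created_at.isoformat(),
        "initial_bg": prescription.initial_bg,
        "profile": profile_to_dict(prescription.profile),
        "audit": list(prescription.audit),
        "followup": [dict(f) for f in prescription.followup],
        "alerts": [_alert_to_dict(a) for a in alerts],
    }


def prescription_from_dict(data: dict[str, Any]) -> Prescription:
    """Rebuild a prescription object from its JSON document."""
    try:
        profile = profile_from_dict(data["profile"])
        split = data["dose_split"]
        scale = data["correction_scale"]
        return Prescription(
            regimen=RegimenType(data["regimen"]),
            category=DoseCategory(int(data["category"]["category"])),
            dose_split=DoseSplit(
                tddi=float(split["tddi"]),
                basal_total=float(split["basal_total"]),
                prandial_total=float(split["prandial_total"]),
                basal_schedule=tuple(
                    (str(t), int(u)) for t, u in split["basal_schedule"]
                ),
                prandial_per_meal=int(split["prandial_per_meal"]),
                prandial_schedule=tuple(
                    (str(t), int(u)) for t, u in split["prandial_schedule"]
                ),
            ),
            correction_scale=CorrectionScale(
                sensitivity_factor=float(scale["sensitivity_factor"]),
                correction_target=float(scale["correction_target"]),
                cap_units=int(scale["cap_units"]),
                entries=tuple(
                    (float(lo), math.inf if hi is None else float(hi), int(units))
                    for lo, hi, units in scale["entries"]
                ),
            ),
            monitoring=tuple(MeasurementContext(m) for m in data["monitoring"]),
            created_at=_parse_timestamp(data["created_at"]),
            initial_bg=float(data["initial_bg"]),
            profile=profile,
            audit=tuple(data.get("audit", ())),
            followup=tuple(data.get("followup", ())),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed prescription document: {exc}") from exc


def write_prescription(
    prescription: Prescription,
    out_dir: str | Path,
    alerts: list[Alert] | tuple[Alert, ...] = (),
) -> tuple[Path, Path]:
    """Write ``prescription.json`` and ``order_sheet.txt``; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "prescription.json"
    sheet_path = out / "order_sheet.txt"
    doc = prescription_to_dict(prescription, alerts)
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
    sheet_path.write_text(render_order_sheet(prescription, alerts), encoding="utf-8")
    return json_path, sheet_path


def read_prescription(path: str | Path) -> Prescription:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"prescription file {path} is not valid JSON: {exc}") from exc
    return prescription_from_dict(data)


_MONITORING_LABEL = {
    MeasurementContext.PRE_BREAKFAST: "before breakfast",
    MeasurementContext.PRE_LUNCH: "before lunch",
    MeasurementContext.PRE_DINNER: "before dinner",
    MeasurementContext.BEDTIME: "at bedtime",
    MeasurementContext.Q6H: "every 6 hours",
}


def render_order_sheet(
    prescription: Prescription, alerts: list[Alert] | tuple[Alert, ...] = ()
) -> str:
    """Render the prescription as a human-readable order sheet."""
    p = prescription
    prof = p.profile
    lines: list[str] = []
    lines.append("SUBCUTANEOUS INSULIN ORDERS")
    lines.append("=" * 60)
    lines.append(f"Created: {p.created_at.isoformat()}")
    lines.append(
        f"Patient: {prof.weight:.0f} kg, {prof.age:.0f} y, "
        f"{prof.nutritional_status.value}, home treatment "
        f"{prof.outpatient_treatment.value}"
    )
    lines.append(
        f"Initial BG: {p.initial_bg:.0f} mg/dL "
        f"({mgdl_to_mmol(p.initial_bg)} mmol/L)"
    )
    lines.append("")
    lines.append(
        f"Regimen: {p.regimen.value}   dose category {p.category.category} "
        f"({p.category.coefficient:.2f} u/kg)   TDDI {p.dose_split.tddi:.1f} u/day"
    )
    lines.append("")
    lines.append(f"BASAL insulin ({prof.basal_product.name}):")
    if p.dose_split.basal_schedule:
        for when, units in p.dose_split.basal_schedule:
            lines.append(f"  {units:>3d} units  {when}")
    else:
        lines.append("  none (withheld under this regimen)")
    lines.append("")
    lines.append(f"PRANDIAL insulin ({prof.bolus_product.name}):")
    if p.dose_split.prandial_schedule:
        for meal, units in p.dose_split.prandial_schedule:
            lines.append(f"  {units:>3d} units  with {meal}")
    else:
        lines.append("  none (withheld under this regimen)")
    lines.append("")
    scale = p.correction_scale
    lines.append(
        f"CORRECTION insulin ({prof.bolus_product.name}), sensitivity "
        f"{scale.sensitivity_factor:.0f} mg/dL per unit, "
        f"target {scale.correction_target:.0f} mg/dL:"
    )
    for lo, hi, units in scale.entries:
        if units == 0:
            continue
        if math.isinf(hi):
            lines.append(
                f"  BG > {lo:>5.0f} mg/dL          add {units} units "
                "and CALL PHYSICIAN"
            )
        else:
            lines.append(f"  BG {lo:>5.0f}-{hi:>5.0f} mg/dL      add {units} units")
    lines.append("")
    lines.append("MONITORING (capillary BG):")
    for ctx in p.monitoring:
        lines.append(f"  {_MONITORING_LABEL[ctx]}")
    if p.followup:
        lines.append("")
        lines.append("FOLLOW-UP:")
        for rec in p.followup:
            lines.append(
                f"  {rec['action']}  (average BG {rec['average_bg']} mg/dL "
                f"over {rec['window_hours']:.0f} h)"
            )
    if alerts:
        lines.append("")
        lines.append("!!! SAFETY ALERTS !!!")
        for alert in alerts:
            lines.append(f"  * {alert.message}")
            for order in alert.orders:
                lines.append(f"      - {order}")
    lines.append("")
    lines.append("Audit trail: " + "; ".join(p.audit))
    return "\n".join(lines) + "\n"


def run_init(
    profile_path: str | Path,
    bg: float,
    out_dir: str | Path,
    settings: Settings = DEFAULT_SETTINGS,
    formulary: str | None = None,
    at: datetime | None = None,
) -> Prescription:
    """Admission workflow: profile file + initial BG -> prescription files.

    Validates everything before writing anything, so a malformed input
    leaves no partial output behind.  ``formulary`` of ``"human"`` or
    ``"analogue"`` overrides the profile's insulin products.
    """
    profile = load_profile(profile_path, settings)
    if formulary is not None:
        if formulary == "human":
            basal, bolus = classify_insulin("NPH"), classify_insulin("REGULAR")
        elif formulary == "analogue":
            basal, bolus = classify_insulin("GLARGINE"), classify_insulin("LISPRO")
        else:
            raise SchemaError(f"formulary must be 'human' or 'analogue', got {formulary!r}")
        from dataclasses import replace

        profile = replace(profile, basal_product=basal, bolus_product=bolus)
    if not (isinstance(bg, (int, float)) and math.isfinite(bg) and bg > 0):
        raise SchemaError(f"initial BG must be a positive mg/dL value, got {bg!r}")
    prescription = build_prescription(profile, float(bg), at=at, settings=settings)
    initial_alerts = evaluate_alerts(
        GlucoseMeasurement(
            timestamp=prescription.created_at, value=float(bg)
        ),
        settings=settings,
    )
    write_prescription(prescription, out_dir, initial_alerts)
    return prescription


def run_followup(
    prescription_path: str | Path,
    bg_series_path: str | Path,
    window: float,
    out_dir: str | Path,
    settings: Settings = DEFAULT_SETTINGS,
    patient_state: PatientState = PatientState(),
) -> Prescription:
    """Titration workflow: prior prescription + BG series -> updated files.

    Computes the window-average recommendation, regenerates doses for any
    category change or basal addition, evaluates per-measurement safety
    alerts, and writes the updated prescription and order sheet.
    """
    prescription = read_prescription(prescription_path)
    series = load_bg_series(bg_series_path)
    recommendation = recommend_adjustment(
        prescription, series, window=window, settings=settings
    )
    updated = apply_adjustment(prescription, recommendation, settings=settings)
    now = max(m.timestamp for m in series)
    alerts = [
        alert
        for m in series
        if (now - m.timestamp).total_seconds() <= window * 3600
        for alert in evaluate_alerts(m, patient_state, settings)
    ]
    write_prescription(updated, out_dir, alerts)
    return updated
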