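"""Reassess a step-wise prescription after a day of high glucose readings.

One day of pre-meal/bedtime readings averaging above 180 mg/dL on the
step-wise approach triggers the add-basal rule: the regimen converts to
full basal-bolus, with 50 % of the TDDI now scheduled as basal insulin.
"""

from datetime import datetime, timedelta, timezone

from insulincalc import (
    GlucoseMeasurement,
    MeasurementContext,
    PatientProfile,
    apply_adjustment,
    build_prescription,
    recommend_adjustment,
)

profile = PatientProfile(weight=80.0, age=50.0)
prescription = build_prescription(profile, initial_bg=200.0)

day = datetime(2024, 3, 2, tzinfo=timezone.utc)
contexts = [
    (7, MeasurementContext.PRE_BREAKFAST),
    (12, MeasurementContext.PRE_LUNCH),
    (18, MeasurementContext.PRE_DINNER),
    (22, MeasurementContext.BEDTIME),
]
values = [195.0, 210.0, 188.0, 202.0]
series = [
    GlucoseMeasurement(day + timedelta(hours=h), v, ctx)
    for (h, ctx), v in zip(contexts, values)
]

recommendation = recommend_adjustment(prescription, series, window=24.0)
print("Average BG:", round(recommendation.average_bg, 1), "mg/dL")
print("Action:", recommendation.action.value)
print("Rationale:", "; ".join(recommendation.rationale))

updated = apply_adjustment(prescription, recommendation)
print(
    "\nRegimen after adjustment:", updated.regimen.value,
    "- basal", [u for _, u in updated.dose_split.basal_schedule], "units,",
    "prandial", updated.dose_split.prandial_per_meal, "units/meal.",
)
print(
    "The average exceeded 180 mg/dL on the step-wise approach, so basal\n"
    "insulin (half the TDDI) was added and the regimen is now basal-bolus."
)
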