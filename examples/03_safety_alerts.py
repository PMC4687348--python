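"""Screen single glucose measurements for emergencies.

A reading above 250 mg/dL raises the diabetic-ketoacidosis rule-out
message; a reading below 70 mg/dL raises a hypoglycemia alert whose order
set depends on consciousness and IV access (glucagon IM only when the
patient is not alert and has no line).  The eating patient's bedtime
supplement rule is shown alongside.
"""

from datetime import datetime, timezone

from insulincalc import (
    GlucoseMeasurement,
    NutritionalStatus,
    PatientState,
    bedtime_supplement,
    evaluate_alerts,
)

ts = datetime(2024, 3, 1, 22, 0, tzinfo=timezone.utc)

for bg, state in [
    (300.0, PatientState()),
    (55.0, PatientState(conscious=True)),
    (55.0, PatientState(conscious=False, iv_line=False)),
    (150.0, PatientState()),
]:
    alerts = evaluate_alerts(GlucoseMeasurement(ts, bg), state)
    label = f"BG {bg:.0f} mg/dL (conscious={state.conscious}, iv={state.iv_line}):"
    if not alerts:
        print(label, "no alert")
    for alert in alerts:
        print(label, alert.message)
        for order in alert.orders:
            print("    -", order)

print("\nBedtime supplement for an eating patient:")
for bg in (180.0, 300.0, 400.0):
    units = bedtime_supplement(bg, NutritionalStatus.EATING)
    print(f"  bedtime BG {bg:.0f} mg/dL -> {units} extra units of bolus insulin")
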