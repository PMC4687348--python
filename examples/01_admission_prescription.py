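"""Build an admission insulin prescription for an eating, insulin-naive patient.

An 80 kg, 50-year-old with no dose modifiers and an admission BG of
200 mg/dL qualifies for the step-wise approach: prandial + correction
insulin, basal withheld.  The printed order sheet shows the full
prescription including the correction table (1500 Rule, regular insulin).
"""

from insulincalc import PatientProfile, build_prescription, render_order_sheet

profile = PatientProfile(weight=80.0, age=50.0)
prescription = build_prescription(profile, initial_bg=200.0)

print(render_order_sheet(prescription))
print(
    "The patient starts on", prescription.regimen.value,
    "at dose category", prescription.category.category,
    f"({prescription.category.coefficient:.2f} u/kg -> "
    f"TDDI {prescription.dose_split.tddi:.0f} u/day);",
    f"{prescription.dose_split.prandial_per_meal} units with each meal,",
    "no basal yet, plus correction per the table above.",
)
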