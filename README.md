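# insulincalc

An inpatient subcutaneous insulin dose calculator for non-critically ill
hospitalized patients with hyperglycemia. It turns a patient profile
(weight, age, renal/hepatic status, corticosteroid use, obesity, nutrition,
home diabetes treatment) and bedside glucose measurements into a complete
insulin prescription — basal, prandial and correction components — plus a
monitoring schedule, 24–48 h titration recommendations and safety alerts.
It is written for clinical-informatics and decision-support developers, and
works with both human insulins (NPH, regular) and analogues (glargine,
detemir, lispro, aspart, glulisine).

## The rules at the core

- **Category dosing.** The total daily dose of insulin (TDDI) is indexed by
  an integer category: category 8 is the standard 0.4 units/kg, and each
  category step is ±0.05 units/kg. Modifier factors shift the category one
  step each: −1 for elderly age, renal impairment or hepatic impairment
  (hypoglycemia risk), +1 for obesity or high-dose corticosteroids (insulin
  resistance). TDDI = coefficient × body weight.
- **Regimen selection.** Patients not eating (NPO or enteral feeding) get
  *basal-plus* (basal + correction, prandial withheld). Eating patients who
  are insulin-naïve — or on outpatient insulin below 0.2 IU/kg — with
  initial BG below 250 mg/dL start on the *step-wise* approach (prandial +
  correction, no basal). Everyone else gets full *basal-bolus*: 50 % of the
  TDDI as basal, 50 % as prandial divided over the three major meals.
- **Correction scale.** The sensitivity factor SF (mg/dL drop per unit of
  bolus insulin) follows the 1800 Rule for rapid-acting and the 1500 Rule
  for short-acting insulin: SF = 1800/TDDI or 1500/TDDI. Correction units
  for a measured BG are max(0, round((BG − 140)/SF)), capped at 8 units
  with escalation advice.
- **Titration.** Reassessment every 24–48 h against the 100–140 mg/dL
  average-BG goal: variability (hypo *and* hyperglycemia in one window) →
  specialist consult; step-wise with average > 180 mg/dL → add basal;
  average > 140 → category +1; average < 100 → category −1; else maintain.
- **Safety.** Any BG > 250 mg/dL → DKA rule-out message; BG < 70 mg/dL →
  hypoglycemia order set (glucagon IM only when the patient is not alert
  and has no IV line). Eating patients with bedtime hyperglycemia get 2
  supplemental units for BG 250–350 mg/dL, 4 units above 350.

## Worked example

```python
from insulincalc import PatientProfile, build_prescription

profile = PatientProfile(weight=80.0, age=50.0)      # eating, insulin-naive
rx = build_prescription(profile, initial_bg=200.0)
print(rx.regimen.value, rx.category.category, rx.dose_split.tddi,
      rx.dose_split.prandial_per_meal,
      round(rx.correction_scale.sensitivity_factor, 1))
```

prints

```
STEP_WISE 8 32.0 5 46.9
```

meaning: no modifier flags keeps the standard category 8 (0.4 u/kg × 80 kg
= 32 units/day TDDI); an eating, insulin-naïve patient at 200 mg/dL enters
the step-wise approach, so no basal is scheduled and the 16-unit prandial
share is split as 5 units with each meal; regular (short-acting) insulin
gives a sensitivity factor of 1500/32 ≈ 46.9 mg/dL per unit for the
correction table. The `examples/` scripts walk through admission
prescriptions, follow-up titration and safety alerts in the same style, and
the CLI mirrors the two clinical steps:

```sh
insulincalc init --patient profile.json --bg 200 --out orders/
insulincalc followup --prescription orders/prescription.json \
    --bg bg_series.csv --window 24 --out orders_day2/
```

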