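# Methods

## Model and scope

`insulincalc` implements a rule-based protocol for subcutaneous insulin
therapy in non-critically ill hospitalized adults. It is a deterministic
decision system, not a pharmacokinetic model: no insulin-on-board,
carbohydrate counting, or glucose dynamics are simulated. The unit of work
is a *prescription* — regimen, dose category, scheduled doses, correction
table, monitoring plan — derived from a patient profile and an admission
glucose value, then revised against the bedside glucose record every
24–48 h. Glucose is carried internally in mg/dL; mmol/L appears only in
rendered output, converted at the fixed factor 18.0 mg/dL per mmol/L
(which reproduces the conventional printed pairs 180 → 10.0 and
140 → 7.8).

## Parameters and defaults

All thresholds live in `insulincalc.config.Settings` and can be overridden
from a YAML file (`--config`). The defaults are the protocol's own values;
changing them produces a different protocol.

| parameter | default | meaning |
|---|---|---|
| standard category / coefficient | 8 / 0.4 u/kg | TDDI anchor; ±0.05 u/kg per category step |
| category bounds | [2, 14] | keeps the coefficient in 0.1–0.7 u/kg; the protocol states no bounds, so these clamp pathological flag combinations to a clinically plausible range |
| elderly age | ≥ 70 y | the protocol names "elderly" without a cutoff; 70 is the common geriatric convention |
| sensitivity rules | 1800 (rapid), 1500 (short) | SF = constant / TDDI |
| correction target | 140 mg/dL | upper edge of the 100–140 goal band, biased against hypoglycemia |
| correction cap | 8 units | single-dose ceiling with escalate-to-physician advice; the protocol states no cap |
| step-wise entry | BG < 250 mg/dL and home insulin < 0.2 IU/kg | eating patients only |
| titration band | (100, 140) mg/dL average | strict inequalities, exactly as worded ("more than 140", "less than 100") |
| add-basal threshold | average > 180 mg/dL | step-wise regimens only |
| variability | < 70 and > 180 mg/dL in one window | the protocol defines variability qualitatively; 70 is the standard hypoglycemia alert level and 180 the guideline random-BG ceiling |
| hypoglycemia alert / severe | < 70 / < 40 mg/dL | severity is an annotation, not a different order set |
| DKA rule-out | BG > 250 mg/dL | message only; no ketone/anion-gap workup |
| bedtime supplement | 2 u for 250–350, 4 u above 350 | eating patients; band edges inclusive in the 2-unit band |
| NPH schedule | twice daily, 2/3 + 1/3 | thrice-daily equal thirds behind `nph_doses_per_day: 3` |
| review window | 24 h (24–48 allowed) | half-open interval (now − w, now], `now` defaulting to the latest measurement |

## Numerical choices

- **Rounding.** Doses are carried at full precision and rounded once, at
  scheduling, half-up to whole units (pens and syringes deliver whole
  units; late rounding minimizes drift). Python's built-in banker's
  rounding is deliberately not used.
- **Correction table tabulation.** The dose formula is
  `max(0, round_half_up((BG − target)/SF))`, capped. A naïve tabulation in
  bands of width SF anchored at the target would disagree with that formula
  at half-band points, so the printed table is derived from the formula
  instead: the 0-unit band spans [target, target + SF/2), and each
  subsequent band of width SF adds one unit. Table and formula therefore
  agree everywhere (tested exhaustively on an integer grid).
- **Modifier combination.** The protocol says modifier factors act
  independently and combine; the arithmetic used is additive ±1 category
  per flag, the simplest rule consistent with "one category could be
  increased or decreased", verified against brute-force offset summation
  over all 32 flag combinations.
- **Step-wise prandial magnitude.** The protocol never states the
  step-wise dose explicitly; this package retains the 50 % prandial share
  and withholds basal, so escalation to basal-bolus adds the basal half
  without disturbing meal doses.
- **Titration step size.** Category moves by exactly 1 per review cycle,
  bounding the daily change to 0.05 u/kg; repeated moves are clamped at
  the category bounds (fixed-point behaviour under sustained
  recommendations).
- **Degenerate inputs.** Non-positive weights, glucose values, and TDDI
  are rejected with named errors; an empty review window raises
  "insufficient measurements" rather than returning a default; a stray
  home-insulin dose on a non-insulin-treated patient is normalized away
  rather than rejected.

## Design choices where the design was open

- Oral-agent-only patients are grouped with the insulin-naïve for the
  step-wise predicate: the decision keys on insulin exposure, and treating
  low-exposure patients conservatively (less insulin up front) matches the
  protocol's stated caution about hypoglycemia.
- Home insulin doses are never carried into the inpatient prescription;
  the category system always re-derives the TDDI from weight and flags.
- Renal/hepatic impairment, obesity and high-dose corticosteroids are
  clinician-supplied booleans; no eGFR/BMI/dose calculators second-guess
  them.
- The hypoglycemia order set beyond the glucagon condition (15–20 g oral
  carbohydrate, IV dextrose, 15-minute recheck) is template text following
  standard hospital protocols, exposed as data so sites can adapt it.

## Synthetic scenarios

`generate_fixtures(seed, n)` emits self-validating patient scenarios:
each bundles a random profile constructed to select a chosen regimen, one
day of bedside readings drawn from uniform BG bands chosen so the windowed
average lands unambiguously in one titration region (105–135 mg/dL for
maintain, 160–240 for increase, 75–95 for decrease, 190–260 for add-basal,
and a hypo + hyper pair for the consult case; the step-wise increase band
is 145–175 so the add-basal rule cannot fire first), and the expected
regimen and action. Twelve templates cover all three regimens, all three
nutritional statuses and all five titration actions; timestamps are
anchored to a fixed reference day so a seed fully determines the output.

What the fixtures emulate is the *logic path*, not physiology: values are
i.i.d. within bands, with none of the meal-to-meal autocorrelation,
measurement error, missed checks or mixed-band days of real bedside
records. Passing the end-to-end suite shows the rules compose and the file
interfaces round-trip — it says nothing about clinical outcomes, which the
underlying protocol itself does not quantify.

The test suite and acceptance script are exhaustive where the domain is
small (32 modifier combinations; integer BG grids of a few hundred points
for every breakpoint sweep; 1,000 randomized profiles for dose
conservation; 100 scenarios end-to-end through the CLI) — problem sizes
chosen because they cover the rule space completely in seconds.

## Known limitations

- No intravenous insulin, discharge/transition dosing, carbohydrate
  counting (500 Rule), CGM ingestion or drug-interaction logic.
- The DKA alert is a rule-out prompt only.
- Enteral-fed patients are handled like NPO (basal + correction, q6h
  checks); continuous-feed prandial strategies are out of scope.
- The protocol is mg/dL-first; mmol/L support is display-only.
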