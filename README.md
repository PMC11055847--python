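# saltscore

Predicting habitual 24-h urinary sodium excretion and the urinary
sodium-to-potassium molar ratio from a handful of short questionnaire
items, using empirical regression weights — with a synthetic-cohort
generator that makes every stage of the method testable against known
ground truth.

## Why

Sodium intake is notoriously hard to measure with food-frequency
questionnaires (FFQs): in populations where most salt comes from
discretionary seasoning (soy sauce, miso soup, pickled vegetables, noodle
broth), multiplying food frequencies by a composition table misses the
dominant sources. An alternative is the *empirical-weights* approach:
regress a recovery biomarker — repeated 24-h urinary excretion — on a
small set of salt-related behavior items, and use the fitted coefficients
as a prediction score. `saltscore` implements that workflow end to end:

1. **Urine processing** — daily excretion from aliquot measurements
   (`Na mg/day = [Na] mEq/L x aliquot mL x 50/1000 x 23`, potassium with
   39), completeness rules (a day with ≥2 missed voids is incomplete;
   ≥3 incomplete days exclude the person; a single-miss day is replaced
   by the person's complete-day mean), and per-person means.
2. **Questionnaire coding** — ordinal coding of behavior items
   (taste preference, soy-sauce use, noodle soup, pickled vegetables,
   miso-soup bowls, ...) from labels or weekly frequencies via a
   versioned YAML coding map; cohort-wide quartiles for food groups; the
   questionnaire Na/K molar ratio
   `(Na/23) / ((K/1.3)/39)` (the 1.3 converts potassium intake to its
   urinary-excretion equivalent); residual-method energy adjustment.
3. **Modeling** — per-item trend regressions adjusted for sex, age, BMI,
   alcohol, smoking and antihypertensive medication; selection of items
   significant in *both* FFQ administrations; stepwise screening of 17
   food groups for the Na/K model; a final simultaneous fit that yields
   the prediction equation (intercept + coefficient per coded item,
   optionally including sex/age/BMI/medication).
4. **Validation** — a development/validation split balanced on sex, top
   questionnaire-sodium quartile and taste preference; Spearman
   correlations between score and measured excretion, deattenuated by
   `adjusted CC = observed CC x sqrt(1 + lambda_x / n)` where `lambda_x`
   is the within/between-person variance ratio estimated by one-way
   ANOVA method of moments; Bland–Altman agreement with a
   proportional-bias slope; comparison against the food-composition
   estimator.
5. **Synthetic cohort** — a generator whose latent habitual excretion is
   an exact linear score of true behavior codes, with lognormal
   day-to-day noise of configurable within/between ratio, 3–5
   collections per person, missed voids, two noisy FFQ administrations
   and an error-prone food-composition estimator. Its ground truth is
   the oracle for every downstream test.

## Worked example

```python
from saltscore import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(cohort=CohortConfig(seed=1))
manifest = run_pipeline(config, "out")
print(manifest["selected_items"]["sodium_mg"])
```

With the default study-like conditions (244 participants, 5 collection
days, within/between ratio 2, item coding noise 0.2) and seed 1 this
prints the items whose trend was significant in both administrations:

```
['taste_preference', 'soy_sauce', 'noodle_soup', 'spices',
 'processed_meat', 'pickled_vegetables', 'noodles', 'miso_soup_bowls']
```

The development-group sodium equation (`out/table3_weights.json`) then
reads, in mg/day per ordinal step:

```
intercept 2367;  taste_preference 42;  soy_sauce 219;  noodle_soup 160;
spices 57;  processed_meat 34;  pickled_vegetables 105;  noodles -11;
miso_soup_bowls 146
```

The five truly weighted items (generator truth 47/187/199/101/161,
intercept 2523) are recovered within sampling error; spuriously selected
items get near-zero weights. Scoring the held-out half
(`out/table4_report.json`) gives, for sodium, a crude Spearman
correlation of 0.77 against the measured 5-day mean (deattenuated 0.93
with the estimated `lambda_x = 2.14`), versus 0.08 for the noisy
food-composition comparator — the qualitative pattern the method is
designed to produce. A score applied to data it was not fitted on shrinks
toward the mean, which the Bland–Altman proportional-bias slope (here
about −0.2) makes visible as over-estimation at low and under-estimation
at high intake.

A CLI wraps the same stages:

```bash
saltscore run --seed 1 --out out/          # full pipeline
saltscore generate --seed 1 --out data/    # cohort tables only
saltscore process --urine-days data/urine_days.csv --out out/
```

## Layout

```
src/saltscore/
  config.py      # CohortConfig / PipelineConfig, YAML I/O
  synthetic.py   # ground-truth cohort generator
  urine.py       # excretion formulas, completeness rules
  ffq.py         # ordinal coding, quartiles, ratio & energy adjustment
  modeling.py    # OLS engine, trends, selection, stepwise, weights
  validation.py  # split, scoring, deattenuation, Bland–Altman
  pipeline.py    # staged orchestration with manifest
  cli.py         # click CLI
docs/methods.md  # model, assumptions, parameter choices, limitations
```
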