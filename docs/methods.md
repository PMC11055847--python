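# Methods

This note documents the statistical model behind `saltscore`, the
assumptions it makes, the defaults it ships with, and what the synthetic
validation does and does not demonstrate.

## The measurement problem

A person's habitual sodium intake is best measured by repeated 24-h
urinary collections, since nearly all ingested sodium is excreted in
urine (potassium only at ~77%, which is why the questionnaire
sodium-to-potassium molar ratio divides potassium intake by 1.3 before
the molar conversion: `(Na mg / 23) / ((K mg / 1.3) / 39)`). Collections
are burdensome, so cohort studies need a questionnaire proxy. Where
discretionary seasoning dominates intake, a short battery of behavior
items (taste preference, soy-sauce use at the table, noodle-soup
consumption, pickled-vegetable frequency, miso-soup bowls per day) can
carry more signal than a full food-composition calculation. The
empirical-weights method regresses the biomarker on the coded items and
uses the fitted equation as a score.

## Urine processing

Daily excretion is reconstructed from the 1/50-aliquot device:
`excretion (mg/day) = concentration (mEq/L) x aliquot (mL) x 50/1000 x M`
with molar masses 23 (Na) and 39 (K). The daily Na/K molar ratio is the
concentration ratio (volume cancels). Completeness rules: a day with two
or more missed voids is incomplete; three or more incomplete days exclude
the person; a day with exactly one missed void is replaced by the
person's complete-day mean (an algebraic consequence is that the summary
mean equals the complete-day mean — the rule is retained explicitly
because it defines day-level data for variance estimation). The daily
ratio is averaged across days rather than computed from mean excretions,
matching the per-sample concentration formula; total volumes of 10 L/day
or more raise a flag but never exclude.

## Modeling and selection

Per-item *trend* models enter one ordinal item at a time, adjusted for
sex, age, BMI, alcohol frequency (dummy-coded, reference "none"),
current smoking and antihypertensive medication. Ordinal codes are used
as 1..k integers. An item is retained only if its trend is significant
(default α = 0.05) in **both** questionnaire administrations — a cheap
replication filter against winner's-curse selection. Candidate
potassium-source food groups for the ratio model are screened by
bidirectional p-value stepwise regression over 17 quartile-coded groups
(entry/stay default 0.05/0.05; the defaults are exposed because no
canonical value exists). The final prediction equation fits all selected
items *simultaneously*; optionally sex, age, BMI and medication use are
added (alcohol and smoking remain trend adjusters only and never enter
the equation). The OLS engine is a thin QR/least-squares fit with
classical homoskedastic standard errors and two-sided t-tests; it is
cross-checked in the tests against an independent normal-equations
solve.

## Validation

Participants are split into development and validation halves by
stratified alternation within (sex × top questionnaire-sodium quartile ×
taste-preference) cells after a seeded shuffle, so every stratum differs
by at most one member. Development-half equations are scored on the
validation half. Observed Spearman correlations against the k-day mean
biomarker are attenuated by day-to-day noise; the correction

    adjusted CC = observed CC x sqrt(1 + lambda_x / n)

uses the within/between-person variance ratio `lambda_x`, estimated per
outcome and stratum by the one-way random-effects ANOVA method of
moments on daily values of complete days (unbalanced n0 coefficient; a
nonpositive between-person component is clamped to a small floor with a
warning). `n` defaults to the mean number of complete collections per
person; a fixed-n option exists. The correction is exact for Pearson
correlations under additive noise and is applied to Spearman values as a
deliberate replication of field practice; a Pearson switch
(`use_pearson`) is provided, and the test-suite checks the k-invariance
of the adjusted correlation on the Pearson scale, where the formula is
exact. Values pushed past |1| are reported as computed, with a warning.
Agreement is summarized by Bland–Altman statistics (mean difference,
±1.96 SD limits) plus the slope of the difference on the pairwise mean:
any score applied out-of-sample shrinks toward the mean, which shows up
as a negative proportional-bias slope. The food-composition comparator
is energy-adjusted (residual method; density available) before its
sodium correlation, never for the ratio.

## Synthetic cohort: what it emulates

The generator is the package's oracle. Its key choices:

* **Latent truth is an exact linear score.** Habitual sodium excretion
  and Na/K ratio are deterministic linear combinations of the true
  ordinal codes (and optionally characteristics) under configured
  weights; latent potassium follows as `39 x (Na/23) / ratio`. This
  makes weight derivation a parameter-recovery problem with a known
  answer, exact at zero noise.
* **Default weights** are the behavior-only equation scale a field study
  of this design reports: sodium intercept 2523 mg/day with 47/187/199/
  101/161 mg per step for taste preference, soy sauce, noodle soup,
  pickled vegetables and miso soup; ratio intercept 2.89 with +0.18
  (taste), +0.32 (soy sauce) and −0.18/−0.18/−0.13 for vegetable, fruit
  and dairy quartiles.
* **Day-to-day noise is lognormal and mean-one**, with within-person
  log-variance `lambda_x` times the between-person variance of the log
  latent score (default `lambda_x = 2`; the distributional form is a
  package choice — excretion must stay positive — since no canonical
  form exists). Mean-one noise keeps day values unbiased for the latent
  mean; a mild consequence is heteroskedasticity (noise SD proportional
  to the latent level), so ±2-SE coverage of homoskedastic OLS intervals
  runs a little below nominal.
* **Collection completeness**: 86/11/2% of persons provide 5/4/3
  complete days (renormalized; the printed shares sum to 99% through
  rounding); ~2% (5/253) fail on three or more days and are excluded
  downstream; complete days additionally suffer a single missed void
  with probability 0.05. Missingness is independent of excretion (MCAR)
  — no dependence structure is asserted.
* **Behavior items** are drawn by ordered probit with marginal category
  frequencies matching a 244-person field survey (e.g. "always" soy-sauce
  use is rare, nobody reports "very strong" taste preference), sharing a
  latent salt-liking factor (loading 0.35) so items inter-correlate and
  marginal trends exceed partial weights, as in real cohorts; vegetable,
  fruit and dairy intakes load negatively on the same factor.
* **Questionnaire error**: each administration independently perturbs
  each ordinal code by ±1 with probability 0.2; food-group intakes carry
  lognormal error (SD 0.25) and are re-quartiled per administration; the
  food-composition estimates are the latent values times lognormal error
  (SD 0.45, potassium scaled by 1.3 to the intake scale); energy intake
  is generated higher for men and increasing in BMI.

### What it does not emulate

The latent score contains **no questionnaire-orthogonal variation**:
everything that drives habitual excretion is, by construction, visible
to the questionnaire. Real behavior items explain only a modest fraction
of between-person variance, so validation correlations here (crude ~0.7)
are substantially higher than a field study would obtain (~0.3–0.5), and
deattenuated values can exceed 1 (flagged, not truncated). Passing tests
therefore demonstrate *correctness of the machinery* — formulas,
selection logic, recovery, calibration, agreement — not the field
performance of any particular equation. Seasonality, portion-size
algebra, the full 172-item instrument and area heterogeneity are out of
scope.

## Numerical choices and degenerate inputs

* Quartile codes are rank-based with stable (participant-order) tie
  breaking, giving n/4 ± 1 per quartile; an all-equal vector yields all
  code 1 with a warning.
* Frequency category boundaries are closed on the left, open on the
  right (a value equal to a bound falls in the upper category).
* Rank-deficient designs raise an error naming the collinear columns
  (incremental-rank scan); a constant outcome returns slope 0 with a
  degenerate-variance warning rather than dividing by zero.
* Probabilities for the completeness mix are validated to sum to 1
  within 0.05 and renormalized.
* All randomness flows from named seeds (cohort seed; split seed
  defaults to cohort seed + 1) through per-stage spawned generators; a
  rerun with identical config is bit-identical, which the manifest's
  checksums make verifiable.

## Problem sizes used in the test-suite

Monte-Carlo checks use the cohort sizes the method targets: n = 244 with
5 collections for recovery-under-noise (100 replicates), n = 500 for
trend recovery and stepwise power, n = 200–400 for variance-component
and attenuation checks (40 replicates over k ∈ {1, 3, 5} days), 400
null replicates for the type-I-error calibration. These sizes keep each
Monte-Carlo standard error small relative to the asserted tolerance.

## Known limitations

* The deattenuation formula applied to Spearman correlations is an
  approximation; at k = 1 collection it under-corrects by ~1–2% under
  the default noise model.
* Single-miss correction replaces the whole day by the complete-day
  mean; rescaling the partial collection is an alternative the package
  does not implement.
* The ANOVA `lambda_x` estimator is moment-based; with few persons or
  days it is noisy and can clamp at the between-variance floor.
* Ordinal trend tests treat codes as equally spaced; category-mean
  contrasts are not offered.
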