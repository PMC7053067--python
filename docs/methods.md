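# Methods

## Scope and flow

`pdqmap` turns PDQ-39 questionnaire data from a two-arm longitudinal trial
into EQ-5D-3L utilities and trial statistics in four stages:

1. **Scoring** — 39 items → eight 0–100 subscale indices → summary index.
2. **Response mapping** — subscale profile (+ age/gender for the
   multinomial family) → per-dimension level probabilities → argmax level.
3. **Tariff valuation** — predicted 5-level state → utility via an additive
   country value set.
4. **Trial statistics** — complete-case filtering, change-from-baseline
   t-tests within and between arms, mixed repeated-measures ANOVA,
   Bonferroni adjustment, responsiveness indices, H&Y-stratified boxplot
   summaries.

A synthetic trial generator provides ground-truth data for all of it.

## Scoring

Each subscale index is `100 · Σ(answered values) / (4 · n_answered)`,
equivalently 25 × the mean answered item value (the identity the property
tests exploit). A subscale is scorable when at least half of its items are
answered — the published instrument convention; the half-rule is the only
imputation performed. The summary index is the mean of the eight subscale
indices and is defined only when all eight are present. Item-to-subscale
assignment follows the published ordering (items 1–10 mobility, 11–16 ADL,
17–22 emotional well-being, 23–26 stigma, 27–29 social support, 30–33
cognitions, 34–36 communication, 37–39 bodily discomfort) and is
configurable for non-standard exports. Datasets may instead supply
precomputed subscale indices (`granularity: subscales`), bypassing this
stage; item-level and subscale-level inputs are mutually exclusive per
dataset.

## Mapping families

Both families are *consumed* as coefficient files; estimation is out of
scope by design. The ordinal family uses the cumulative inverse-Cauchy
(Cauchit) link: with η = β′X, `p1 = 0.5 − atan(−α₁ + η)/π`, cumulative
`c2 = 0.5 − atan(−α₂ + η)/π`, `p2 = c2 − p1`, `p3 = 1 − c2`. The constraint
α₁ < α₂ (checked at load, never at predict time) guarantees p2 ≥ 0. The
multinomial family pivots on level 1 (score fixed at 0) and computes
softmax probabilities with max-subtraction so extreme linear scores cannot
overflow. Levels are assigned by argmax; exact ties (measure-zero with real
coefficients) break toward the less severe level — deterministic and
conservative. A record missing any required covariate is left unmapped in
all five dimensions; no partial states are emitted. Predicted probabilities
are retained alongside levels to support expected-utility variants later
(not computed here).

Coefficient files declare the gender coding (default: female = 1) and an
optional age-centering constant, so transcribed published sets can override
both; a data/model coding mismatch is a load-time error. The schema admits
plain linear terms only — interaction or transformed covariates are a known
limitation. The shipped demonstration sets are synthetic round numbers with
severity-increasing slopes whose level-switch points are spread across the
0–100 summary-index range, so the mapped utility responds smoothly to
severity; they exercise the machinery but carry no empirical content. When
transcribing a published ordinal model, confirm the sign convention of β′X
against the source parameterization.

## Tariffs

Value sets use the standard additive form: utility = 1 − any-dysfunction
constant (once, if any level > 1) − per-dimension level-2/3 decrements − an
extreme-level constant (once, if any level 3). Sets lacking a term set it
to zero. Load-time validation enforces full-health = 1.0, non-negative
decrements, and level-3 ≥ level-2 per dimension, which makes the tariff
monotone over the 243-state lattice (property-tested exhaustively).
Utilities are kept at full floating precision; rounding is a rendering
concern. Two synthetic demonstration sets ship (UK-like structure with an
extreme-level term; French-like structure without); real analyses should
transcribe published tariffs into the template.

## Trial statistics

* **Complete cases.** A "case" is a subject: anyone without an observation
  at every scheduled visit is excluded at all visits (a per-visit
  alternative would be straightforward but the subject-level reading
  matches per-arm case-count reporting conventions). Reported exclusion
  percentages are rounded to the nearest integer.
* **Within-group tests** are one-sample t-tests of mean change against
  zero — algebraically the paired t of visit vs baseline. Between-group
  tests are classical pooled-variance Student's t on change scores
  (estimate = arm A − arm B), with a Welch switch. Zero-variance samples
  return an exact verdict (p = 1 if the mean is 0, else p = 0) flagged
  `degenerate`, with spread judged at floating precision relative to the
  data scale rather than by exact equality.
* **Multiplicity.** Bonferroni over the k follow-up visits: threshold
  α/k (0.05/3 ≈ 0.017), adjusted p = min(1, k·p); confidence intervals are
  reported at the adjusted level.
* **Repeated measures.** Two-way mixed ANOVA (between: arm; within: visit,
  baseline included as a visit) via `pingouin.mixed_anova`; the
  Greenhouse–Geisser correction is reported alongside but not substituted,
  since no sphericity policy is imposed.
* **Responsiveness.** ES = mean change / SD(baseline), SRM = mean change /
  SD(change), both with n−1 denominators; a zero SD leaves the statistic
  undefined (None) rather than infinite.
* **Severity strata.** Tukey boxplot statistics per H&Y stage over all
  subject-visit observations: quartiles by linear interpolation (fixed and
  documented because boxplot statistics depend on the convention), whiskers
  at the most extreme point within 1.5·IQR, outliers listed. Stages with
  fewer than 10 observations (configurable) are flagged low-reliability;
  empty stages are omitted.

## Synthetic trial generator

The generator's defaults describe an early-PD device-vs-medication trial:
124/127 subjects, visits at 0/5/12/24 months, mean age 52 (SD 6), 35%
female, baseline H&Y ≤ 2.5 (mass on stages 1–2.5, stages ≥ 3 permitted but
zero-weighted by default), a between-arm summary-index effect of 8 PDQ-39
points, and a ~3.6% subject-level incomplete rate. Baseline summary-index
mean 32 (SD 12) and an 8-point per-subscale spread are plausible values for
an early-PD cohort with motor complications; no subscale-level calibration
data were available, so subscales are exchangeable perturbations of one
latent index (SD 10) with no per-subscale effect profile.

The latent trajectory is a subject random intercept plus visit-specific arm
means with Gaussian noise; the within-subject correlation (0.7) is realized
as the random-intercept share of the latent variance. The full treatment
effect applies from the first follow-up visit onward (arm A's latent index
drops by `arm_effect_si`; the A−B difference in change is therefore
negative on the PDQ-39 scale and positive after mapping to utilities).
Subscales are clipped to [0, 100] rather than resampled; clipping is a
small bias source (≈0.3 points at the default design, computed in closed
form from the Gaussian clipped mean), and designs where it would absorb
more than half the intended effect are rejected at construction. H&Y stage
is sampled at baseline, held fixed, and independent of severity — so
severity-gradient checks construct their own stage-linked profiles.
Missingness withholds one random follow-up visit's subscales per affected
subject, matching complete-case semantics. A single integer seed drives one
named generator; no global state.

What the generator does **not** emulate: item-level response processes,
dropout over time, surgical-complication shocks, subscale-specific
treatment profiles, and any H&Y–severity coupling. Passing end-to-end tests
therefore demonstrates the pipeline's statistical machinery and direction
recovery under a clean Gaussian world, not the empirical performance of any
published coefficient set on real patients.

## Problem sizes and numerical choices

Replicate counts used by the validation suites — 1000 null-calibration
replicates, 200 direction-recovery replicates per family, 10,000-draw
normalization and argmax sweeps, 100-dataset t-test parity at 1e-10 — are
the package's chosen balance of Monte-Carlo error against runtime; the
whole suite runs in under a minute on one CPU. The null-calibration check
pools rejections over the three follow-up visits (3000 tests), which
estimates the type-I rate with smaller Monte-Carlo error than any single
visit. Probability triples are validated to sum to 1 within 1e-12; softmax
uses max-subtraction; the Cauchit link needs no guard (arctan is bounded).

## Command-line interface

`pdqmap` exposes `simulate`, `score`, `map`, `value`, `analyse` and `run`
sub-commands; each stage consumes the previous stage's tab-delimited output,
so intermediate artifacts stay auditable. `run` computes every
(family × value set) bundle before writing anything, so a failed run emits
no partial result tables. Logs go to console and a run-stamped file;
low-n strata warnings never abort.
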