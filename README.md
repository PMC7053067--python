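# pdqmap

Map PDQ-39 scores onto EQ-5D-3L utilities and analyse two-arm longitudinal
trials on the mapped utilities.

## The problem

Cost-utility analyses need health-state **utilities** — preference weights
anchored at 1.0 (full health) and 0.0 (death) — but many Parkinson's disease
trials collect only the disease-specific **PDQ-39** questionnaire (39 items,
eight subscales each scored 0–100, higher = worse) and never administer a
generic utility instrument such as the **EQ-5D-3L** (five dimensions —
mobility, self-care, usual activities, pain/discomfort, anxiety/depression —
each at level 1 "no problems", 2 "some problems" or 3 "extreme problems").
Response mapping (crosswalking) fills this gap: pre-estimated regression
models predict the level of each EQ-5D-3L dimension from the PDQ-39 subscale
profile, and a country value set (tariff) then converts the predicted state
into a utility.

`pdqmap` implements this pipeline end to end for people doing health-economic
modelling of PD interventions: scoring, two mapping families, tariff
valuation, and the longitudinal change-from-baseline trial statistics, plus a
synthetic trial generator so every stage is testable without patient data.

## The models

**Ordinal (Cauchit link).** Per dimension, with cut-points α₁ < α₂, slope
vector β over a declared subset of the eight subscale indices and linear
predictor η = β′X:

    ϑ₁ = 0.5 − arctan(−α₁ + η)/π
    ϑ₂ = [0.5 − arctan(−α₂ + η)/π] − ϑ₁
    ϑ₃ = 1 − ϑ₁ − ϑ₂

**Multinomial logit.** Per dimension, level 1 is the pivot (score 0) and
levels 2 and 3 carry linear scores over the eight subscales, age and a
gender indicator: P(level i) = exp(sᵢ) / Σⱼ exp(sⱼ).

Either way the predicted level is the argmax of (ϑ₁, ϑ₂, ϑ₃), ties broken
toward the less severe level, and the tariff applies the standard additive
form u = 1 − c·[any level > 1] − Σ decrement(dim, level) − e·[any level 3].

Coefficients are **consumed, never re-fit**: the package ships synthetic
round-number demonstration sets (used by all tests) and annotated templates
for transcribing published estimates.

## Worked example

```sh
pdqmap simulate --seed 4 --out trial.tsv
# wrote 1004 records (251 subjects x 4 visits, arms 124/127,
#        effect 8.0 SI points, seed 4) to trial.tsv
pdqmap run --data trial.tsv --family both --outdir out --seed 1
```

`out/ordinal_UK-demo_between.tsv` then holds the between-arm comparison of
utility change from baseline (pooled-variance Student's t, Bonferroni
threshold 0.05/3 ≈ 0.017):

```
 visit  estimate      se     t  df         p  ci_low  ci_high
     5    0.2064 0.04559 4.526 237 9.508e-06 0.09643   0.3163
    12    0.2198 0.04056 5.419 237 1.474e-07   0.122   0.3175
    24    0.2487 0.04491 5.537 237 8.137e-08  0.1404    0.357
```

The simulated 8-point PDQ-39 treatment effect maps to a positive utility
difference of ≈0.21–0.25 favouring arm A at every follow-up visit, all
significant at the adjusted threshold. The mixed repeated-measures ANOVA
agrees (arm main effect F(1, 237) = 10.2, p = 0.0016), and the
responsiveness table shows the treated arm's larger standardized response
mean at 24 months (SRM 0.587 vs −0.101). The confidence intervals are at
the Bonferroni-adjusted level.

Each stage also runs standalone (`pdqmap score | map | value | analyse`) on
the previous stage's output, and everything is available as a library:

```python
import pdqmap as pm
df = pm.generate_trial(pm.TrialDesign(seed=4))
mapped = pm.predict_table(pm.demo_coefficients("ordinal"), df)
```

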