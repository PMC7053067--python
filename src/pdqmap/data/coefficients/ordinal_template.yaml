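# Template for a transcribed ordinal (Cauchit-link) coefficient set.
# Fill in the published cut-points (alpha1 < alpha2) and subscale slopes
# from the source PDQ-39 -> EQ-5D-3L cumulative-link mapping study before
# use; the source restricted the predictors per dimension, so list only the
# subscales that study's equations include.  Confirm the sign convention of
# the linear predictor beta'X against the source parameterization.
label: ordinal-transcribed
family: ordinal
dimensions:
  mobility:
    alpha1: null   # <- transcribe
    alpha2: null   # <- transcribe
    beta: {}       # e.g. {mobility: ..., activities_of_daily_living: ...}
  self_care:
    alpha1: null
    alpha2: null
    beta: {}
  usual_activities:
    alpha1: null
    alpha2: null
    beta: {}
  pain_discomfort:
    alpha1: null
    alpha2: null
    beta: {}
  anxiety_depression:
    alpha1: null
    alpha2: null
    beta: {}
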