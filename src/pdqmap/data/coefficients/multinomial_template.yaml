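# Template for a transcribed multinomial-logit coefficient set (response
# mapping with age and gender as covariates; level 1 is the pivot outcome).
# Fill in the published intercepts and coefficients for levels 2 and 3 of
# each dimension from the source mapping study.  Declare the source's
# gender coding and any age centering below; a mismatch with the data
# coding is a load-time error.
label: multinomial-transcribed
family: multinomial
gender_coding: {female: 1, male: 0}
age_centering: 0.0
dimensions:
  mobility:
    level2: {intercept: null}   # add subscale/age/gender coefficients
    level3: {intercept: null}
  self_care:
    level2: {intercept: null}
    level3: {intercept: null}
  usual_activities:
    level2: {intercept: null}
    level3: {intercept: null}
  pain_discomfort:
    level2: {intercept: null}
    level3: {intercept: null}
  anxiety_depression:
    level2: {intercept: null}
    level3: {intercept: null}
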