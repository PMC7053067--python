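# Synthetic demonstration coefficient set for the ordinal (Cauchit-link)
# mapping family.  These are NOT published regression estimates: they are
# round-number placeholders with severity-increasing slopes (higher PDQ-39
# subscale scores push probability mass toward more severe EQ-5D levels),
# chosen so that level switches are spread across the plausible 0-100
# summary-index range.  Replace with transcribed published coefficients for
# real analyses (see ordinal_template.yaml).
label: ordinal-demo
family: ordinal
dimensions:
  mobility:
    alpha1: 0.9
    alpha2: 2.5
    beta:
      mobility: 0.025
      activities_of_daily_living: 0.015
  self_care:
    alpha1: 1.5
    alpha2: 3.1
    beta:
      activities_of_daily_living: 0.03
      mobility: 0.01
  usual_activities:
    alpha1: 1.2
    alpha2: 2.8
    beta:
      activities_of_daily_living: 0.02
      mobility: 0.01
      social_support: 0.01
  pain_discomfort:
    alpha1: 0.6
    alpha2: 2.2
    beta:
      bodily_discomfort: 0.03
      mobility: 0.01
  anxiety_depression:
    alpha1: 0.8
    alpha2: 2.4
    beta:
      emotional_wellbeing: 0.03
      stigma: 0.01
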