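# Synthetic demonstration coefficient set for the multinomial-logit mapping
# family (level 1 "no problems" is the pivot; levels 2 and 3 carry linear
# scores over the eight PDQ-39 subscale indices, age in years and a gender
# indicator).  These are NOT published regression estimates: round-number
# placeholders with severity-increasing slopes.  Replace with transcribed
# published coefficients for real analyses (see multinomial_template.yaml).
label: multinomial-demo
family: multinomial
gender_coding: {female: 1, male: 0}
age_centering: 0.0
dimensions:
  mobility:
    level2:
      intercept: -1.8
      mobility: 0.00625
      activities_of_daily_living: 0.00625
      emotional_wellbeing: 0.00625
      stigma: 0.00625
      social_support: 0.00625
      cognitions: 0.00625
      communication: 0.00625
      bodily_discomfort: 0.00625
      age: 0.01
      gender: 0.1
    level3:
      intercept: -3.9
      mobility: 0.0075
      activities_of_daily_living: 0.0075
      emotional_wellbeing: 0.0075
      stigma: 0.0075
      social_support: 0.0075
      cognitions: 0.0075
      communication: 0.0075
      bodily_discomfort: 0.0075
      age: 0.012
      gender: 0.1
  self_care:
    level2:
      intercept: -2.6
      mobility: 0.00625
      activities_of_daily_living: 0.00625
      emotional_wellbeing: 0.00625
      stigma: 0.00625
      social_support: 0.00625
      cognitions: 0.00625
      communication: 0.00625
      bodily_discomfort: 0.00625
      age: 0.01
      gender: 0.1
    level3:
      intercept: -4.9
      mobility: 0.0075
      activities_of_daily_living: 0.0075
      emotional_wellbeing: 0.0075
      stigma: 0.0075
      social_support: 0.0075
      cognitions: 0.0075
      communication: 0.0075
      bodily_discomfort: 0.0075
      age: 0.012
      gender: 0.1
  usual_activities:
    level2:
      intercept: -2.1
      mobility: 0.00625
      activities_of_daily_living: 0.00625
      emotional_wellbeing: 0.00625
      stigma: 0.00625
      social_support: 0.00625
      cognitions: 0.00625
      communication: 0.00625
      bodily_discomfort: 0.00625
      age: 0.01
      gender: 0.1
    level3:
      intercept: -4.6
      mobility: 0.0075
      activities_of_daily_living: 0.0075
      emotional_wellbeing: 0.0075
      stigma: 0.0075
      social_support: 0.0075
      cognitions: 0.0075
      communication: 0.0075
      bodily_discomfort: 0.0075
      age: 0.012
      gender: 0.1
  pain_discomfort:
    level2:
      intercept: -1.6
      mobility: 0.00625
      activities_of_daily_living: 0.00625
      emotional_wellbeing: 0.00625
      stigma: 0.00625
      social_support: 0.00625
      cognitions: 0.00625
      communication: 0.00625
      bodily_discomfort: 0.00625
      age: 0.01
      gender: 0.1
    level3:
      intercept: -3.7
      mobility: 0.0075
      activities_of_daily_living: 0.0075
      emotional_wellbeing: 0.0075
      stigma: 0.0075
      social_support: 0.0075
      cognitions: 0.0075
      communication: 0.0075
      bodily_discomfort: 0.0075
      age: 0.012
      gender: 0.1
  anxiety_depression:
    level2:
      intercept: -1.8
      mobility: 0.00625
      activities_of_daily_living: 0.00625
      emotional_wellbeing: 0.00625
      stigma: 0.00625
      social_support: 0.00625
      cognitions: 0.00625
      communication: 0.00625
      bodily_discomfort: 0.00625
      age: 0.01
      gender: 0.1
    level3:
      intercept: -3.9
      mobility: 0.0075
      activities_of_daily_living: 0.0075
      emotional_wellbeing: 0.0075
      stigma: 0.0075
      social_support: 0.0075
      cognitions: 0.0075
      communication: 0.0075
      bodily_discomfort: 0.0075
      age: 0.012
      gender: 0.1
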