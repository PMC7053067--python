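# Synthetic demonstration value set with UK-like structure and magnitudes:
# an any-dysfunction constant, per-dimension level-2/level-3 decrements and
# a single extreme-level (any level 3) constant, in the standard additive
# time-trade-off tariff form.  Not a transcription of a published tariff —
# transcribe the published UK TTO value set into valueset_template.yaml for
# real analyses.
country: UK-demo
full_health: 1.0
any_dysfunction: 0.081
extreme: 0.269
decrements:
  mobility: {level2: 0.069, level3: 0.314}
  self_care: {level2: 0.104, level3: 0.214}
  usual_activities: {level2: 0.036, level3: 0.094}
  pain_discomfort: {level2: 0.123, level3: 0.386}
  anxiety_depression: {level2: 0.071, level3: 0.236}
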