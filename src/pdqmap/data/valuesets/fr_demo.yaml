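# Synthetic demonstration value set with French-like structure (no separate
# extreme-level constant) and round-number decrements.  Not a transcription
# of a published tariff — transcribe the published French value set into
# valueset_template.yaml for real analyses.
country: FR-demo
full_health: 1.0
any_dysfunction: 0.05
extreme: 0.0
decrements:
  mobility: {level2: 0.06, level3: 0.25}
  self_care: {level2: 0.06, level3: 0.20}
  usual_activities: {level2: 0.04, level3: 0.15}
  pain_discomfort: {level2: 0.10, level3: 0.30}
  anxiety_depression: {level2: 0.07, level3: 0.25}
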