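# Template for a transcribed country value set (additive EQ-5D-3L tariff).
# Constraints checked at load: full_health = 1.0; all decrements >= 0;
# level-3 decrement >= level-2 decrement per dimension.  A value set
# without an any-dysfunction or extreme-level term sets that constant to 0.
country: null
full_health: 1.0
any_dysfunction: null
extreme: null
decrements:
  mobility: {level2: null, level3: null}
  self_care: {level2: null, level3: null}
  usual_activities: {level2: null, level3: null}
  pain_discomfort: {level2: null, level3: null}
  anxiety_depression: {level2: null, level3: null}
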