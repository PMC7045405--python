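# UK MVH time-trade-off value set for the 3-level EQ-5D (Dolan, 1997).
# Additive tariff: index = 1 − constant_any_problem·1{any level > 1}
#                        − Σ_dimension decrement[level]
#                        − any_level3_term·1{any level = 3}
# Worst state (3,3,3,3,3) scores −0.594.
name: uk_tto_3l
levels_per_dimension: 3
full_health_value: 1.0
constant_any_problem: 0.081
any_level3_term: 0.269
decrements:
  mobility: {2: 0.069, 3: 0.314}
  self_care: {2: 0.104, 3: 0.214}
  usual_activities: {2: 0.036, 3: 0.094}
  pain_discomfort: {2: 0.123, 3: 0.386}
  anxiety_depression: {2: 0.071, 3: 0.236}
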