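# Scheme definitions for the four needs-based segmentation schemes.
#
# Cascade schemes list segments in evaluation order, highest to lowest
# healthcare need; a subject enters the FIRST segment whose `when` predicate
# it satisfies, so the final catch-all makes assignment total.  Predicates
# reference only features derivable from the survey record plus the
# condition map:
#   {age_ge: N} {age_lt: N}            age thresholds (years)
#   {flag: name}                        a boolean survey flag is true
#   {mental_health_is: mild|severe}     exact severity
#   {mental_health_ge: mild|severe}     at least this severity
#   {chronic_count_ge: N}               chronic-condition count
#   {class_present: name}               condition-map class (cancer,
#                                       early_stage, organ_failure,
#                                       progressive_decline)
#   {all_of: [...]} {any_of: [...]} {negate: {...}} {always: true}
#
# Segments under `placeholders` are inert: defined by the source scheme but
# not evaluable from this survey instrument (no record can enter them).
version: 1
schemes:
  singapore:
    kind: grid   # 6 Global Impression x 3 Risk-and-Actionability, id = 3*(GI-1)+RA
    gi_labels:
      1: Healthy
      2: Asymptomatic Chronic Condition
      3: Symptomatic Chronic Condition
      4: Long Course of Decline
      5: Limited Reserve with Serious Exacerbations
      6: End of Life
    ra_labels:
      1: Low RA
      2: Moderate RA
      3: High RA
    not_evaluable: [16, 17, 18]   # End of Life: survey carries no such item

  delaware:
    kind: cascade
    segments:
      - id: 10
        label: "Elderly & have severe mental health conditions (includes those with chronic illness)"
        when: {all_of: [{age_ge: 75}, {mental_health_is: severe}]}
      - id: 9
        label: "Elderly & have mild mental health conditions (includes those with chronic illness)"
        when: {all_of: [{age_ge: 75}, {mental_health_is: mild}]}
      - id: 8
        label: "Elderly & 2+ chronic condition"
        when: {all_of: [{age_ge: 75}, {chronic_count_ge: 2}]}
      - id: 7
        label: "Elderly & 1 chronic condition"
        when: {all_of: [{age_ge: 75}, {chronic_count_ge: 1}]}
      - id: 6
        label: "Elderly & no chronic conditions"
        when: {age_ge: 75}
      - id: 5
        label: "Adult & have severe mental health conditions (includes those with chronic illness)"
        when: {mental_health_is: severe}
      - id: 4
        label: "Adult & have mild mental health conditions (includes those with chronic illness)"
        when: {mental_health_is: mild}
      - id: 3
        label: "Adult & 2+ chronic condition"
        when: {chronic_count_ge: 2}
      - id: 2
        label: "Adult & 1 chronic condition"
        when: {chronic_count_ge: 1}
      - id: 1
        label: "Adult & no chronic conditions"
        when: {always: true}
    placeholders:
      - {id: 11, label: "Maternity and pediatrics", reason: "survey enrols ages 60+ only"}
      - {id: 12, label: "Special needs populations", reason: "not captured by this instrument"}

  lombardy:
    kind: cascade
    segments:
      - id: 6
        label: "Elderly: 85 years or more"
        when: {age_ge: 85}
      - id: 5
        label: "People affected by more than 1 chronic disease"
        when: {chronic_count_ge: 2}
      - id: 4
        label: "People affected by only 1 chronic disease"
        when: {chronic_count_ge: 1}
      - id: 3
        label: "People possibly affected by chronic disease or at early stage"
        when: {class_present: early_stage}
      - id: 2
        label: "People suffering from an acute event"
        when: {flag: acute_event_recent}
      - id: 1
        label: "Healthy people"
        when: {always: true}
    placeholders:
      - {id: 7, label: "High 3-year utilization variants", reason: "3-year utilization history unavailable from a one-off survey"}

  nwlondon:
    kind: cascade
    segments:
      - id: 8
        label: "Adults and elderly people with severe physical disabilities"
        when: {flag: adl_deficit}
      - id: 7
        label: "Adults and elderly people with cancer"
        when: {class_present: cancer}
      - id: 6
        label: "Adults and elderly people with SEMI"
        when: {mental_health_is: severe}
      - id: 5
        label: "Elderly > 74 with 1 or more LTCs"
        when: {all_of: [{age_ge: 75}, {chronic_count_ge: 1}]}
      - id: 4
        label: "Adults < 75 with 1 or more LTCs"
        when: {chronic_count_ge: 1}
      - id: 2
        label: "Mostly health adults > 74"
        when: {age_ge: 75}
      - id: 1
        label: "Mostly healthy adults < 75"
        when: {always: true}
    placeholders:
      - {id: 3, label: "Children and adolescents", reason: "survey enrols ages 60+ only"}
      - {id: 9, label: "Alcohol or drug dependency", reason: "not captured by this instrument"}
      - {id: 10, label: "Learning difficulties", reason: "not captured by this instrument"}
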