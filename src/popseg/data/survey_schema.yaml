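# Column dictionary for the survey and outcomes tables.
# Delimited text (comma default, tab accepted), UTF-8, one header row;
# booleans encoded 0/1, missing values as empty cells.
version: 1
survey:
  subject_id: {type: string, required: true, doc: opaque unique identifier}
  age: {type: integer, required: true, doc: age in years; study eligibility is 60+}
  sex: {type: enum, values: [male, female], required: true}
  proxy_respondent: {type: boolean, doc: a proxy answered the survey}
  chronic_conditions: {type: string, doc: semicolon-separated condition codes from the condition map}
  mental_health: {type: enum, values: [none, mild, severe], doc: mental-health condition severity}
  any_symptomatic_condition: {type: boolean, doc: at least one chronic condition is symptomatic}
  cancer: {type: boolean, doc: any form or stage of cancer}
  acute_event_recent: {type: boolean, doc: recent acute event (e.g. fracture)}
  organ_failure_condition: {type: boolean, doc: limited-reserve class condition (CHF/COPD-type)}
  progressive_decline_condition: {type: boolean, doc: long-course-of-decline class condition}
  end_of_life: {type: boolean, doc: carried in the model; never set by this survey}
  adl_deficit: {type: boolean, doc: any activity-of-daily-living deficit}
  skilled_nursing_need: {type: boolean, doc: any skilled nursing task need}
  iadl_deficit: {type: boolean, doc: instrumental ADL deficit}
  social_support_deficit: {type: boolean}
  activation_deficit: {type: boolean}
  disruptive_behaviour: {type: boolean}
  eq5d_mobility: {type: ordinal, doc: EQ-5D level, 1 = no problems; empty = missing}
  eq5d_self_care: {type: ordinal}
  eq5d_usual_activities: {type: ordinal}
  eq5d_pain_discomfort: {type: ordinal}
  eq5d_anxiety_depression: {type: ordinal}
  difficulty_meeting_expenses: {type: boolean, doc: perceived difficulty meeting expenses; may be missing}
outcomes:
  subject_id: {type: string, required: true, doc: joins to exactly one survey row}
  died_180d: {type: boolean, doc: died within 180 days of baseline}
  n_admissions_180d: {type: count, doc: hospital admissions within 180 days}
  n_ed_visits_180d: {type: count, doc: emergency department visits within 180 days}
  n_soc_visits_180d: {type: count, doc: specialist outpatient clinic visits within 180 days}
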