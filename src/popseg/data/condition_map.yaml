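# Default condition vocabulary for the survey's chronic-condition checklist.
#
# Every code a subject can report is mapped to the classes the segmentation
# schemes consume; scheme rules never see raw codes.  Classes:
#   chronic             counts toward chronic-condition totals
#   organ_failure       limited-reserve class (CHF/COPD-type conditions)
#   progressive_decline long-course-of-decline class (dementia/stroke-type)
#   cancer              any form or stage of cancer
#   mental_health       none | mild | severe
#   early_stage         suspected / not-yet-established disease (Lombardy
#                       "possibly affected"); EMPTY by default — add codes
#                       here to make that segment reachable, e.g.
#                       prediabetes: {early_stage: true}
version: 1
conditions:
  hypertension: {chronic: true}
  hyperlipidemia: {chronic: true}
  diabetes: {chronic: true}
  osteoarthritis: {chronic: true}
  gastritis: {chronic: true}
  chf: {chronic: true, organ_failure: true}
  copd: {chronic: true, organ_failure: true}
  esrd: {chronic: true, organ_failure: true}
  stroke: {chronic: true, progressive_decline: true}
  dementia: {chronic: true, progressive_decline: true}
  parkinsons: {chronic: true, progressive_decline: true}
  cancer: {chronic: true, cancer: true}
  depression: {chronic: true, mental_health: mild}
  schizophrenia: {chronic: true, mental_health: severe}
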