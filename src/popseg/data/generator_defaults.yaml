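# Calibrated default generator parameters — produced by
# scripts/calibrate_generator.py; edit the structure there, not here.
age:
  gamma_scale: 6.0
  gamma_shape: 2.0
  max_age: 100
  offset: 60
  severity_coef: 2.0
conditions:
  cancer:
    p0: 0.045
    slope: 0.5
  chf:
    p0: 0.006
    slope: 0.8
  copd:
    p0: 0.007
    slope: 0.8
  dementia:
    p0: 0.08
    slope: 0.9
  depression:
    p0: 0.16
    slope: 0.7
  diabetes:
    p0: 0.3
    slope: 0.4
  esrd:
    p0: 0.003
    slope: 0.8
  gastritis:
    p0: 0.1
    slope: 0.2
  hyperlipidemia:
    p0: 0.4
    slope: 0.2
  hypertension:
    p0: 0.5
    slope: 0.3
  osteoarthritis:
    p0: 0.22
    slope: 0.4
  parkinsons:
    p0: 0.01
    slope: 0.6
  schizophrenia:
    p0: 0.05
    slope: 0.6
  stroke:
    p0: 0.08
    slope: 0.7
difficulty_meeting_expenses:
  p0: 0.33
  slope: 0.3
eq5d:
  dimensions:
    anxiety_depression:
      alpha1: -1.743133
      alpha2: -4.369287
    mobility:
      alpha1: -1.324764
      alpha2: -4.369287
    pain_discomfort:
      alpha1: -0.882932
      alpha2: -3.953565
    self_care:
      alpha1: -2.674691
      alpha2: -5.072586
    usual_activities:
      alpha1: -1.993814
      alpha2: -4.662058
  missing_p: 0.05
  slope: 0.9
factors:
  activation_deficit:
    p0: 0.3
    slope: 0.5
  acute_event_recent:
    p0: 0.02
    slope: 0.3
  adl_deficit:
    p0: 0.055
    slope: 1.0
  disruptive_behaviour:
    p0: 0.02
    slope: 0.5
  iadl_deficit:
    p0: 0.3
    slope: 0.8
  skilled_nursing_need:
    p0: 0.02
    slope: 1.0
  social_support_deficit:
    p0: 0.35
    slope: 0.3
n: 928
outcomes:
  admissions:
    intercept: -2.871407
    slope: 1.552674
  death:
    intercept: -4.55742
    slope: 1.2
  ed:
    intercept: -2.13116
    slope: 1.227057
  soc:
    intercept: -1.578079
    slope: 1.744425
proxy_p: 0.051
sex_male_p: 0.55
symptomatic_given_chronic:
  p0: 0.25
  slope: 0.8
version: 1
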