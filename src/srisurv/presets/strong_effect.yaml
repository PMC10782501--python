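# High-power preset for quick experiments: a large SRI effect and an
# inflated event rate so modest cohorts produce enough deaths to fit
# cause-specific models.
pattern_mixture:
- weight: 0.13
  params:
    mean_onset: 23.0
    onset_sd: 0.3
    mean_duration: 7.4
    duration_sd: 0.45
    duration_between_sd: 0.9
    nap_probability: 0.03
    awakening_rate: 0.6
    awakening_duration: 0.25
- weight: 0.33
  params:
    mean_onset: 23.0
    onset_sd: 0.45
    mean_duration: 7.25
    duration_sd: 0.5
    duration_between_sd: 0.9
    nap_probability: 0.05
    awakening_rate: 1.0
    awakening_duration: 0.25
- weight: 0.34
  params:
    mean_onset: 23.0
    onset_sd: 0.7
    mean_duration: 7.1
    duration_sd: 0.8
    duration_between_sd: 0.9
    nap_probability: 0.1
    awakening_rate: 1.4
    awakening_duration: 0.3
- weight: 0.12
  params:
    mean_onset: 23.0
    onset_sd: 1.1
    mean_duration: 6.95
    duration_sd: 0.9
    duration_between_sd: 0.9
    nap_probability: 0.15
    awakening_rate: 2.0
    awakening_duration: 0.3
- weight: 0.08
  params:
    mean_onset: 23.0
    onset_sd: 1.8
    mean_duration: 6.8
    duration_sd: 1.3
    duration_between_sd: 0.9
    nap_probability: 0.3
    awakening_rate: 2.7
    awakening_duration: 0.4
survival:
  n_participants: 1000
  follow_up_mean: 6.3
  follow_up_sd: 0.83
  censor_horizon: 7.8
  baseline_hazards:
    cardiometabolic: 0.008
    cancer: 0.015
    other: 0.008
  sri_log_hrs:
    cardiometabolic:
    - 0.0
    - -0.35
    - -0.65
    - -0.9
    - -1.1
    cancer:
    - 0.0
    - -0.35
    - -0.65
    - -0.9
    - -1.1
    other:
    - 0.0
    - -0.35
    - -0.65
    - -0.9
    - -1.1
  duration_log_hrs: {}
  covariate_log_hrs:
    age: 0.08
    sex_male: 0.45
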