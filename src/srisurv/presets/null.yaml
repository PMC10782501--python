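# Null preset: same sleep mixture as ukb_like but no sleep or covariate
# effects on mortality; baseline hazards give an expected 4.84 deaths
# per 1000 person-years (split across causes by their observed shares).
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
    cardiometabolic: 0.00098156
    cancer: 0.0028431
    other: 0.0010154
  sri_log_hrs: {}
  duration_log_hrs: {}
  covariate_log_hrs: {}
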