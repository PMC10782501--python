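# srisurv

Sleep-regularity metrics and quintile-based mortality models for
actigraphy cohorts.

Epidemiological work on sleep and mortality has focused on sleep
*duration*; day-to-day *regularity* of sleep–wake timing is an
alternative exposure that more directly tracks circadian disruption.
`srisurv` implements the full analysis pipeline needed to compare the
two on epoch-level sleep–wake data:

1. **Sleep Regularity Index (SRI)** and companion sleep metrics from
   epoch-level sleep/wake/missing series (or from interval-format sleep
   episode and non-wear tables, which are rendered onto an epoch grid);
2. **quintile survival models** — Cox proportional hazards for
   all-cause mortality and Fine–Gray proportional sub-distribution
   hazards for cause-specific mortality — with "minimal" (age, sex,
   ethnicity) and "full" (plus sociodemographic/lifestyle/medication)
   adjustment sets;
3. **model comparisons**: AIC relative likelihood for the non-nested
   SRI-only vs duration-only models, likelihood-ratio tests for the
   nested SRI vs SRI+duration models, and a polynomial (linear /
   quadratic / cubic) regression of SRI on sleep duration;
4. a **synthetic-cohort generator** producing epoch-level recordings
   with tunable regularity and linked cause-specific survival outcomes,
   so the whole pipeline is testable without access-controlled cohort
   data.

## The statistic

For an epoch series $s_1, \dots, s_N$ (epoch length $\delta$ dividing
24 h, states sleep/wake/missing), every epoch is paired with the epoch
exactly 24 h later ($\ell = 86400/\delta$ indices ahead). A pair is
*valid* when neither member is missing, and *concordant* when both share
the same state. The SRI is

$$\mathrm{SRI} = 200 \cdot \frac{\#\{\text{concordant pairs}\}}{\#\{\text{valid pairs}\}} - 100,$$

so 100 is a perfectly repeating pattern, 0 the chance level for
independent random states, and −100 perfect day-to-day alternation. A
score is valid only with ≥ 120 h (5 days) of valid pairs.

Survival models split SRI and mean sleep duration into quintiles
(Q1 = least regular / shortest sleep, the hypothesised highest-risk
reference) and estimate hazard ratios for Q2–Q5 vs Q1 on the
time-since-recording scale. Cause-specific sub-hazards use the
Fine–Gray construction: participants dying of competing causes remain
in the risk set with inverse-probability-of-censoring weights from a
Kaplan–Meier estimate of the censoring distribution.

## Worked example

Simulate a 5 000-participant cohort from the default preset and run the
whole pipeline:

```bash
srisurv run-all --preset ukb_like --n 5000 --seed 7 --out example_out
```

The default preset draws each participant's sleep archetype from a
five-component mixture calibrated to give a negatively skewed SRI
distribution (this run: median 81.6, IQR 73.8–86.6) and attaches
survival outcomes whose hazards fall with SRI quintile. The model-1
(SRI-only, minimally adjusted) hazard ratios from `models.csv`:

| quintile | HR   | 95% CI        |
|----------|------|---------------|
| Q1       | 1.00 | (reference)   |
| Q2       | 0.81 | 0.53–1.23     |
| Q3       | 0.53 | 0.33–0.84     |
| Q4       | 0.55 | 0.35–0.88     |
| Q5       | 0.38 | 0.23–0.65     |

(163 deaths among 5 000 participants, 5.3 per 1000 person-years.)
`comparisons.csv` reports ΔAIC = 17.4 between the SRI-only and
duration-only models — a relative likelihood of 1.6 × 10⁻⁴ that the
duration model minimises information loss — and a likelihood-ratio test
of Χ²(4) = 1.15, p = 0.89 for adding duration quintiles on top of SRI:
with this preset's SRI-driven truth, duration adds nothing once SRI is
in the model, while SRI clearly beats duration head-to-head.

The same stages are available as library calls (`summarize_participant`,
`fit_cox`, `fit_fine_gray`, `compare_aic`, `lrt_nested`,
`fit_sri_duration_polynomials`) and as sklearn-style estimators
(`SleepSummaryTransformer`, `QuintileCoxPH`, `FineGraySubdistribution`,
`SleepDurationSRIRegression`) that compose with sklearn tooling.

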