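# Methods

## Epoch representation

A recording is a fixed grid of epochs (default 30 s; any divisor of
86 400 s is accepted so that "the same epoch 24 h later" is an exact
index shift), each in one of three states: WAKE, SLEEP, MISSING.
Interval-format inputs (sleep episodes, non-wear intervals) are rendered
onto the grid by the midpoint rule: an epoch is SLEEP if its midpoint
lies inside a sleep interval, MISSING if inside a non-wear interval
(non-wear wins over sleep), else WAKE. Overlapping sleep episodes for
one participant are rejected; overlapping non-wear intervals are merged.

## Sleep Regularity Index

SRI = 200 · (concordant pairs / valid pairs) − 100 over all epoch pairs
separated by exactly 24 h. A pair is valid when neither member is
MISSING. Every epoch that has a partner 24 h later is paired — there is
no day-level bookkeeping — and the valid-pair count is reported
explicitly (`valid_pairs`, `valid_pair_hours`). A score is *valid* only
when valid-pair time reaches the threshold (default 120 h = 5 days);
below it the result carries `sri = None` rather than raising, since
short recordings are an expected, countable exclusion. The raw ratio is
still exposed (`sri_raw`) for diagnostics.

## Daily records and participant summaries

Days are half-open 24-h windows anchored at a configurable boundary
(noon by default, so a typical night is never split — the analysis
choice, not a property of the data). Each window's *main sleep period*
is the longest episode whose onset falls in the window, ties broken by
earlier onset; shorter episodes in the window are naps and never
contribute to daily duration. Daily sleep duration is the summed
SLEEP-epoch time between the main period's onset and offset: intra-night
awakenings (WAKE epochs inside the period) are excluded, and MISSING
time inside the period is not counted as sleep. A day is invalid when
the window holds no episode or when MISSING time exceeds 20%
(configurable) of the main period — a stand-in for upstream
quality-flag exclusions, also exposed as a pluggable day-validity
predicate.

Participant summaries average duration and mid-sleep (the clock time
halfway between onset and offset) over valid days. Onset/offset
variability is the standard deviation of daily onset/offset clock
times after unwrapping: each time is shifted by a multiple of 24 h to
the representative nearest the participant's median (a circular-mean
first pass makes the median itself wrap-safe), so 23:30 and 00:30 are
one hour apart. SDs use the population convention (ddof = 0) and are
reported only with ≥ 2 valid days. A summary is absent entirely when
the SRI is invalid.

## Survival models

Exposures enter as quintile factors. Cut points are the 20/40/60/80
empirical percentiles (linear-interpolation definition) computed on all
rows with the exposure observed — before any covariate-driven row drop —
and boundary ties go to the lower quintile. Constant input is rejected.

*All-cause mortality*: Cox proportional hazards on the
time-since-recording scale, Efron tie handling, maximised by lifelines
with a tightened Newton tolerance (1e-10) so that independent fitting
paths agree to ~1e-6. *Cause-specific mortality*: Fine–Gray
proportional sub-distribution hazards. The IPCW counting-process
dataset is built in-package: subjects failing from competing causes stay
in the risk set after their failure time, carrying weight
G(t−)/G(T_i−) at each later target-cause event time t, where G is the
Kaplan–Meier estimate of the censoring survival function (cohort-wide,
not covariate-adjusted). The weighted partial likelihood is then
maximised by a start–stop Cox fitter. With no competing events the
dataset collapses to the plain Cox layout and estimates agree with the
cause-specific Cox fit to ~1e-8; on competing-risks data the
coefficients agree with the R `cmprsk::crr` reference to ~1e-6 (checked
in the test suite). All non-target deaths compete jointly against the
target cause.

Adjustment sets: minimal = age, sex, ethnicity; full adds physical
activity, employment, income, deprivation, social activities, social
visits, smoking, urbanicity, shift work and cholesterol/hypertension
medication. Categorical covariates use fixed level orders (first level
reference) for deterministic dummy coding; income and social visits are
treated as numeric scales. Missing covariate values are handled
complete-case per model with the dropped count logged — no imputation —
which is also how the generator reproduces the minimal-vs-full
analysed-N gap. Wald 95% CIs on the log-HR scale; AIC = 2k − 2ℓ with ℓ
the (pseudo-)partial log-likelihood. Scaled Schoenfeld residuals are
available as an optional diagnostic and never gate a fit.

## Model comparisons

Non-nested SRI-only vs duration-only models on identical rows (enforced
via a row-index hash) are compared by AIC; the reported quantity is the
worse model's relative likelihood exp((AIC_min − AIC_other)/2) ∈ (0, 1],
a probability-like weight that it minimises information loss. Nested
models use the likelihood-ratio test 2(ℓ_full − ℓ_reduced) on a
chi-square with df = added coefficients (4 when adding one quintile
factor); a negative statistic beyond numerical tolerance raises rather
than being silently clamped.

The SRI ~ duration association is summarised by OLS with duration
entered as raw polynomials of degree 1–3. Nested F-tests share the
cubic model's residual mean square as denominator (the ANOVA
convention, so the two tests against the cubic have a common
denominator df). The cubic's turning point is the derivative root with
negative second derivative inside the observed duration range, absent
otherwise. Near-constant duration is rejected as a degenerate design.

## Synthetic cohorts

The generator emulates the structure the SRI is sensitive to —
variable onset/offset timing, intra-night awakenings, afternoon naps,
device non-wear — not raw accelerometry. Per day: onset ~
Normal(mean_onset, onset_sd), duration ~ Normal(habitual, duration_sd)
truncated at ≥ 1 h, where the participant's habitual duration is itself
drawn once from Normal(mean_duration, duration_between_sd); awakening
bouts (Poisson count per night) are carved out of the night; naps occur
with a daily probability in the early afternoon; non-wear intervals are
placed uniformly. A night is one logical sleep episode for
daily-record bookkeeping while its awakenings appear only in the epoch
states, matching how duration is defined. Everything is reproducible
from a single `numpy` Generator.

The default "ukb_like" preset mixes five archetypes (very regular →
irregular; weights 0.13/0.33/0.34/0.12/0.08) calibrated so the
population SRI distribution has median ≈ 81 with IQR ≈ 74–86 and
negative skew, habitual duration ≈ 6.8 ± 1.0 h, and an SRI–duration
cross-R² ≈ 0.1 induced by a mild duration gradient across archetypes.

Survival outcomes: cause-specific exponential event times with hazard
λ_c · exp(βᶜ_SRI[q] + βᶜ_dur[q] + covariate effects) — a step function
of quintile membership, matching the analysis structure; the earliest
cause wins and follow-up is censored at min(Normal(6.30, 0.83) draw,
7.8 y horizon). Baseline rates split a 4.84-per-1000-person-year total
across causes by their observed shares (20.3% cardiometabolic, 58.7%
cancer, 21.0% other); in presets with protective effects the baselines
are pre-scaled by the mean quintile multiplier and the covariate
lognormal factor so the marginal rate stays near that total. Covariates
(age, sex, ethnicity, physical activity, employment, income,
deprivation, social measures, smoking, urbanicity, shift work,
medication) are drawn independently with marginals typical of an older
UK accelerometer cohort; default hazard effects are age
(log-HR 0.08/y), male sex (0.45) and current smoking (0.70). The
"ukb_like" preset also blanks income MCAR in 23.1% of rows so
full-adjustment complete-case models analyse a smaller N than minimal
ones.

What the generator does **not** emulate: weekday/weekend structure,
seasonal timing, correlated covariates, informative censoring, a
U-shaped duration–SRI association (the coupling is linear, so the
fitted cubic's turning point is typically absent on synthetic cohorts —
the cubic machinery is validated on data generated from a known cubic),
or any claim of distributional equivalence to a real cohort. Passing
tests therefore demonstrate correctness of the computations and
recoverability of known truths, not realism of any particular dataset.

## Problem sizes and numerical conventions

- Parameter-recovery checks run 20 replicates of 5 000-participant
  cohorts (~150 deaths each), pooling replicate-level means with a
  t-based 95% interval; calibration checks (LRT type-I error, F-test
  size) use 200 replicates at n = 400–700 with inflated event rates so
  the asymptotics are informative at test scale.
- Quintile boundary ties go down; categorical dummy order is fixed;
  row sets are hashed so cross-model comparisons cannot silently mix
  populations.
- Pipeline outputs contain no timestamps and use fixed float formatting,
  so identical configuration + seed ⇒ byte-identical bundles; the
  output directory is excluded from the recorded configuration hash.
- Degenerate inputs fail loudly (constant exposure, empty event set,
  non-positive follow-up, malformed intervals) except where absence is
  an expected data state (invalid SRI, invalid days, all-censored null
  cohorts), which is reported in results and manifests instead.

## Known limitations

- Fine–Gray standard errors come from the weighted partial likelihood
  without the IPCW sandwich correction; CIs for sub-HRs are mildly
  anti-conservative in heavy-competition settings.
- The censoring-weight estimator is cohort-wide Kaplan–Meier; covariate-
  dependent censoring would bias sub-hazard estimates.
- Follow-up is drawn from a truncated normal; real administrative
  censoring is determined by calendar enrolment patterns.
- The quintile step-function hazard is the analysis model's own
  structure; continuous-exposure misspecification is out of scope.
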