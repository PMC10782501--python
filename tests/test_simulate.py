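import dataclasses

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

from srisurv import (
    SleepPatternParams,
    SurvivalGenConfig,
    assign_quintiles,
    compute_sri,
    generate_cohort,
    generate_sleep_pattern,
    load_preset,
    simulate_survival,
)

from conftest import survival_layer_cohort


def mean_sri(params, n, seed):
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n):
        _, _, series = generate_sleep_pattern(params, rng, "x")
        vals.append(compute_sri(series, 0.0).sri_raw)
    return float(np.mean(vals))


class TestSleepPatternGenerator:
    def test_zero_variability_gives_sri_100(self):
        params = SleepPatternParams(onset_sd=0, duration_sd=0,
                                    duration_between_sd=0, nap_probability=0,
                                    awakening_rate=0, nonwear_rate=0)
        _, _, series = generate_sleep_pattern(params, 0, "p")
        assert compute_sri(series).sri == 100.0

    def test_identical_seed_reproduces_bytes(self):
        params = SleepPatternParams()
        eps1, nw1, s1 = generate_sleep_pattern(params, 123, "p")
        eps2, nw2, s2 = generate_sleep_pattern(params, 123, "p")
        assert eps1 == eps2 and nw1 == nw2
        assert np.array_equal(s1.states, s2.states)

    def test_mean_sri_strictly_decreasing_in_onset_sd(self):
        means = [mean_sri(SleepPatternParams(onset_sd=sd, nap_probability=0,
                                             awakening_rate=0, nonwear_rate=0),
                          120, seed=5)
                 for sd in (0.0, 1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_naps_and_awakenings_lower_mean_sri(self):
        base = dict(onset_sd=0.3, nonwear_rate=0)
        quiet = mean_sri(SleepPatternParams(**base, nap_probability=0,
                                            awakening_rate=0), 120, 7)
        napping = mean_sri(SleepPatternParams(**base, nap_probability=0.6,
                                              awakening_rate=0), 120, 7)
        fragmented = mean_sri(SleepPatternParams(**base, nap_probability=0,
                                                 awakening_rate=4.0), 120, 7)
        assert napping < quiet
        assert fragmented < quiet

    def test_infeasible_duration_rejected(self):
        with pytest.raises(ValueError, match="fit within a day"):
            SleepPatternParams(mean_duration=23.0).validate()


class TestSurvivalLayer:
    def test_null_event_rate_matches_target(self):
        # all log-HRs zero; baseline tuned for 4.84 deaths / 1000 py
        rng = np.random.default_rng(20)
        n = 8000
        summaries = pd.DataFrame({
            "participant_id": [f"S{i}" for i in range(n)],
            "sri": rng.normal(80, 10, n),
            "sleep_duration": rng.normal(6.9, 1.0, n),
        })
        config = SurvivalGenConfig(
            n_participants=n,
            baseline_hazards={"cardiometabolic": 9.8156e-4, "cancer": 2.8431e-3,
                              "other": 1.0154e-3},
            covariate_log_hrs={},
        )
        cohort = simulate_survival(summaries, config, rng)
        person_years = cohort["follow_up_time"].sum()
        rate = 1000 * cohort["event"].sum() / person_years
        se = 1000 * np.sqrt(cohort["event"].sum()) / person_years
        assert abs(rate - 4.84) < 3 * se

    def test_zero_baseline_hazard_produces_no_deaths_of_that_cause(self):
        rng = np.random.default_rng(6)
        summaries = pd.DataFrame({
            "participant_id": [f"S{i}" for i in range(500)],
            "sri": rng.normal(80, 10, 500),
            "sleep_duration": rng.normal(7, 1, 500),
        })
        config = SurvivalGenConfig(
            n_participants=500,
            baseline_hazards={"cancer": 0.0, "other": 0.02},
            covariate_log_hrs={},
        )
        cohort = simulate_survival(summaries, config, rng)
        assert (cohort["cause"] != "cancer").all()

    def test_all_zero_hazards_warn_and_censor_everyone(self):
        rng = np.random.default_rng(6)
        summaries = pd.DataFrame({
            "participant_id": ["a", "b", "c", "d", "e", "f"],
            "sri": [60.0, 70, 75, 80, 85, 90],
            "sleep_duration": [6.0, 6.5, 7, 7.2, 7.4, 8],
        })
        config = SurvivalGenConfig(n_participants=6,
                                   baseline_hazards={"all": 0.0},
                                   covariate_log_hrs={})
        with pytest.warns(UserWarning, match="all-censored"):
            cohort = simulate_survival(summaries, config, rng)
        assert (cohort["event"] == 0).all()

    def test_censoring_fraction_monotone_in_horizon(self):
        fracs = []
        for horizon in (1.0, 3.0, 6.0, 7.8):
            rng = np.random.default_rng(14)
            summaries = pd.DataFrame({
                "participant_id": [f"S{i}" for i in range(2000)],
                "sri": rng.normal(80, 10, 2000),
                "sleep_duration": rng.normal(7, 1, 2000),
            })
            config = SurvivalGenConfig(
                n_participants=2000, baseline_hazards={"all": 0.05},
                covariate_log_hrs={}, censor_horizon=horizon,
                follow_up_mean=horizon * 0.85, follow_up_sd=0.4,
            )
            cohort = simulate_survival(summaries, config, rng)
            fracs.append(1.0 - cohort["event"].mean())
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_null_configuration_passes_logrank_across_quintiles(self):
        rng = np.random.default_rng(23)
        cohort = survival_layer_cohort(3000, rng, rate=0.05)
        q = assign_quintiles(cohort["sri"], "sri").labels
        res = multivariate_logrank_test(cohort["follow_up_time"], q,
                                        cohort["event"])
        assert res.p_value > 0.01

    def test_q1_reference_validation(self):
        cfg = SurvivalGenConfig(sri_log_hrs={"all": [0.1, 0, 0, 0, 0]},
                                baseline_hazards={"all": 0.01})
        with pytest.raises(ValueError, match="Q1 must be 0"):
            cfg.validate()


class TestGenerateCohort:
    def test_deterministic_for_identical_seed(self):
        mix, surv = load_preset("strong_effect")
        surv = dataclasses.replace(surv, n_participants=120)
        c1, e1 = generate_cohort(mix, surv, np.random.default_rng(77))
        c2, e2 = generate_cohort(mix, surv, np.random.default_rng(77))
        pd.testing.assert_frame_equal(c1, c2)
        assert e1 == e2

    def test_weights_must_sum_to_one(self):
        mix, surv = load_preset("null")
        bad = [(w * 0.5, p) for w, p in mix]
        with pytest.raises(ValueError, match="sum to 1"):
            generate_cohort(bad, surv, 1)

    def test_default_preset_sri_distribution_matches_calibration_target(self):
        mix, surv = load_preset("ukb_like")
        surv = dataclasses.replace(surv, n_participants=1200)
        cohort, _ = generate_cohort(mix, surv, np.random.default_rng(2))
        q25, med, q75 = np.percentile(cohort["sri"], [25, 50, 75])
        # population targets: median ~81, IQR ~74-86 (generous MC slack)
        assert med == pytest.approx(81.0, abs=2.0)
        assert q25 == pytest.approx(73.8, abs=2.5)
        assert q75 == pytest.approx(86.3, abs=2.5)
        # negative skew and realistic duration spread
        from scipy import stats
        assert stats.skew(cohort["sri"]) < -0.5
        assert cohort["sleep_duration"].std() == pytest.approx(1.0, abs=0.25)

    def test_full_model_missingness_shrinks_complete_cases(self):
        mix, surv = load_preset("ukb_like")
        surv = dataclasses.replace(surv, n_participants=400)
        cohort, _ = generate_cohort(mix, surv, np.random.default_rng(3))
        frac = cohort["income"].isna().mean()
        assert 0.15 < frac < 0.31  # mirrors the minimal-vs-full N shrinkage
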