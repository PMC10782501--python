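import subprocess

import numpy as np
import pandas as pd
import pytest

from srisurv import fit_cox, fit_fine_gray
from srisurv.survival import build_fine_gray_dataset, fine_gray_from_arrays

from conftest import survival_layer_cohort
from oracles import km_censoring_survival, weighted_startstop_loglik_and_score


def competing_cohort(n, rng, cancer_log_hrs, cardio_log_hrs):
    """Survival-layer cohort with two competing causes."""
    from srisurv.simulate import SurvivalGenConfig, simulate_survival

    sri = np.clip(rng.normal(80, 10, n), 5, 99)
    dur = np.clip(rng.normal(6.9, 1.0, n), 1, 13)
    summaries = pd.DataFrame({
        "participant_id": [f"S{i:05d}" for i in range(n)],
        "sri": sri, "sleep_duration": dur,
    })
    config = SurvivalGenConfig(
        n_participants=n,
        baseline_hazards={"cancer": 0.03, "cardiometabolic": 0.02},
        sri_log_hrs={"cancer": cancer_log_hrs, "cardiometabolic": cardio_log_hrs},
        covariate_log_hrs={},
    )
    return simulate_survival(summaries, config, rng)


class TestDegeneracy:
    def test_no_competing_events_reduces_to_cause_specific_cox(self):
        rng = np.random.default_rng(21)
        cohort = survival_layer_cohort(1500, rng, rate=0.04)
        cohort["cause"] = np.where(cohort["event"] == 1, "cancer", None)
        fg = fit_fine_gray(cohort, "cancer", ("sri",), "minimal")
        cx = fit_cox(cohort, ("sri",), "minimal", outcome="cancer")
        hr_fg = fg.hazard_ratios.query("quintile != 'Q1'")["hr"].to_numpy()
        hr_cx = cx.hazard_ratios.query("quintile != 'Q1'")["hr"].to_numpy()
        np.testing.assert_allclose(hr_fg, hr_cx, rtol=1e-6)
        assert fg.log_likelihood == pytest.approx(cx.log_likelihood, abs=1e-6)


class TestIpcwConstruction:
    def test_toy_dataset_weights_match_hand_km(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        target = np.array([1, 0, 0, 1, 0, 0, 1, 0], dtype=bool)
        competing = np.array([0, 1, 0, 0, 1, 0, 0, 0], dtype=bool)
        cov = pd.DataFrame({"x": [0.5, -1, 0, 1, 2, -0.5, 0.3, 0.8]})
        long_df = build_fine_gray_dataset(times, target, competing, cov)

        g = km_censoring_survival(times, ~target & ~competing)
        # competing subject at t=2 stays at risk for target events at 4 and 7
        rows = long_df[(long_df["id"] == 1) & (long_df["start"] > 0)]
        assert list(rows["stop"]) == [4.0, 7.0]
        expected_w = g(np.array([4.0, 7.0])) / g(np.array([2.0]))[0]
        np.testing.assert_allclose(rows["w"].to_numpy(), expected_w)
        # everyone contributes their own base interval with weight 1
        base = long_df[long_df["start"] == 0]
        assert len(base) == 8 and (base["w"] == 1).all()

    def test_estimating_equation_zero_at_fitted_beta(self):
        rng = np.random.default_rng(4)
        n = 120
        x = rng.normal(size=n)
        t1 = rng.exponential(1 / (0.2 * np.exp(0.7 * x)))
        t2 = rng.exponential(1 / 0.15, size=n)
        c = rng.uniform(1, 8, n)
        t = np.minimum(np.minimum(t1, t2), c)
        target = t1 <= np.minimum(t2, c)
        competing = ~target & (t2 <= c)
        cov = pd.DataFrame({"x": x})

        ctv = fine_gray_from_arrays(t, target, competing, cov)
        long_df = build_fine_gray_dataset(t, target, competing, cov)
        ll, score = weighted_startstop_loglik_and_score(
            ctv.params_.to_numpy(), long_df, ["x"]
        )
        assert abs(score[0]) < 1e-6  # weighted score vanishes at the optimum
        assert ll == pytest.approx(ctv.log_likelihood_, abs=1e-8)


class TestRecovery:
    def test_known_subdistribution_effect_recovered(self):
        """Binary-group data drawn from an exact Fine-Gray law."""
        rng = np.random.default_rng(17)
        beta, p = 0.8, 0.35
        reps = 12
        errs = []
        for _ in range(reps):
            n = 800
            x = (rng.random(n) < 0.5).astype(float)
            e = np.exp(beta * x)
            p_cause1 = 1 - (1 - p) ** e
            is1 = rng.random(n) < p_cause1
            u = rng.random(n)
            # invert F1(t|x)/F1(inf|x) for cause-1 subjects
            t = np.where(
                is1,
                -np.log(1 - (1 - (1 - u * p_cause1) ** (1 / e)) / p),
                rng.exponential(0.8, n),
            )
            c = rng.uniform(0.5, 6.0, n)
            obs = np.minimum(t, c)
            target = is1 & (t <= c)
            competing = ~is1 & (t <= c)
            ctv = fine_gray_from_arrays(obs, target, competing,
                                        pd.DataFrame({"x": x}))
            errs.append(ctv.params_.iloc[0] - beta)
        errs = np.asarray(errs)
        ci = errs.mean() + np.array([-1, 1]) * 2.2 * errs.std(ddof=1) / np.sqrt(reps)
        assert ci[0] <= 0.0 <= ci[1]  # replicate CI of the bias covers zero

    def test_moderate_competition_shrinks_subhazard_vs_cause_specific(self):
        # with a protective competing-cause effect absent, sub-HRs for the
        # target cause sit between the cause-specific HR and 1
        rng = np.random.default_rng(9)
        cohort = competing_cohort(
            4000, rng,
            cancer_log_hrs=[0.0, -0.4, -0.6, -0.8, -1.0],
            cardio_log_hrs=[0.0, 0.0, 0.0, 0.0, 0.0],
        )
        fg = fit_fine_gray(cohort, "cancer", ("sri",), adjustment="none")
        cx = fit_cox(cohort, ("sri",), adjustment="none", outcome="cancer")
        b_fg = fg.coefficients["coef"].to_numpy()
        b_cx = cx.coefficients["coef"].to_numpy()
        # same ordering and comparable magnitude; competition attenuates
        assert np.all(np.sign(b_fg) == np.sign(b_cx))
        assert np.all(np.abs(b_fg) <= np.abs(b_cx) + 0.08)


def test_matches_reference_crr_implementation(tmp_path):
    """Coefficients agree with the cmprsk::crr reference on one dataset."""
    rng = np.random.default_rng(5)
    n = 300
    x1 = rng.normal(size=n)
    x2 = (rng.random(n) < 0.5).astype(float)
    t1 = rng.exponential(1 / (0.15 * np.exp(0.6 * x1 - 0.4 * x2)))
    t2 = rng.exponential(1 / (0.10 * np.exp(-0.3 * x1)))
    c = rng.uniform(2, 10, n)
    t = np.minimum(np.minimum(t1, t2), c)
    status = np.where(t1 <= np.minimum(t2, c), 1, np.where(t2 <= c, 2, 0))
    df = pd.DataFrame({"t": t, "status": status, "x1": x1, "x2": x2})

    ctv = fine_gray_from_arrays(t, status == 1, status == 2, df[["x1", "x2"]])

    csv = tmp_path / "fg.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fg.R"
    script.write_text(
        'suppressMessages(library(cmprsk))\n'
        f'd <- read.csv("{csv}")\n'
        'fit <- crr(d$t, d$status, cov1=cbind(d$x1, d$x2), failcode=1, cencode=0)\n'
        'cat(sprintf("%.10f %.10f\\n", fit$coef[1], fit$coef[2]))\n'
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         timeout=120)
    assert out.returncode == 0, out.stderr
    ref = np.array([float(v) for v in out.stdout.split()])
    np.testing.assert_allclose(ctv.params_.to_numpy(), ref, atol=1e-6)
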