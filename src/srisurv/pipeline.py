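"""End-to-end orchestration: data -> metrics -> models -> comparisons.

A run either generates a synthetic cohort from a named preset or loads
interval CSVs plus an outcome table, computes participant sleep
summaries, fits the requested quintile mortality models, runs the AIC
and likelihood-ratio comparisons and the SRI~duration polynomial
regression, and writes a reproducible bundle:

    cohort.csv        analysed cohort table (summaries + covariates + outcome)
    models.csv        tidy per-quintile hazard-ratio table (all fitted models)
    comparisons.csv   AIC / LRT / polynomial comparison rows
    curves.csv        Kaplan-Meier survival-curve coordinates per SRI quintile
    manifest.json     config hash, seed, and row-count accounting per stage

No wall-clock information is written, so identical configurations and
seeds produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .compare import compare_aic, fit_sri_duration_polynomials, lrt_nested
from .epochs import read_episode_csv, read_interval_csv
from .metrics import summarize_cohort
from .quintiles import assign_quintiles
from .simulate import SurvivalGenConfig, generate_cohort, load_preset
from .survival import CAUSES, ModelFit, fit_cox, fit_fine_gray

log = logging.getLogger("srisurv")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "srisurv_out"
    seed: int = 0
    # data source: either a generator preset ...
    preset: str | None = "ukb_like"
    n_participants: int | None = None
    # ... or interval + outcome CSVs
    episodes_csv: str | None = None
    nonwear_csv: str | None = None
    outcomes_csv: str | None = None
    # metric settings
    epoch_length: int = 30
    validity_hours: float = 120.0
    # model grid
    models: tuple[int, ...] = (1, 2, 3)
    adjustments: tuple[str, ...] = ("minimal",)
    outcomes: tuple[str, ...] = ("all_cause",)

    def to_dict(self) -> dict:
        """Scientific configuration only: the output location is excluded so
        reruns into different directories stay byte-identical."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


MODEL_PREDICTORS = {
    1: ("sri",),
    2: ("sleep_duration",),
    3: ("sri", "sleep_duration"),
}


def _load_cohort_from_files(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    episodes = read_episode_csv(config.episodes_csv)
    nonwear = (
        read_interval_csv(config.nonwear_csv) if config.nonwear_csv else {}
    )
    n_input = len(episodes)
    summaries, excluded = summarize_cohort(
        episodes,
        nonwear,
        epoch_length=config.epoch_length,
        validity_threshold_hours=config.validity_hours,
    )
    summaries = summaries.rename(columns={"mean_sleep_duration_h": "sleep_duration"})
    outcomes = pd.read_csv(config.outcomes_csv, dtype={"participant_id": str})
    bad = outcomes["follow_up_time"] <= 0
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("skipping %d malformed outcome rows (non-positive time)", n_bad)
        if n_bad > 0.5 * len(outcomes):
            raise ValueError(
                f"{n_bad}/{len(outcomes)} outcome rows malformed; aborting"
            )
        outcomes = outcomes[~bad]
    cohort = summaries.merge(outcomes, on="participant_id", how="inner")
    counts = {
        "n_input_participants": n_input,
        "excluded": excluded,
        "n_summarized": len(summaries),
        "n_with_outcome": len(cohort),
        "malformed_outcome_rows": n_bad,
    }
    return cohort, counts


def _km_curves(cohort: pd.DataFrame) -> pd.DataFrame:
    """Survival-curve coordinates per SRI quintile (all-cause)."""
    qa = assign_quintiles(cohort["sri"], "sri")
    kmf = KaplanMeierFitter()
    frames = []
    for q in ["Q1", "Q2", "Q3", "Q4", "Q5"]:
        sel = qa.labels == q
        if sel.sum() == 0:
            continue
        kmf.fit(cohort.loc[sel, "follow_up_time"], cohort.loc[sel, "event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf.insert(0, "sri_quintile", q)
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns the manifest dictionary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if config.preset is not None:
        mixture, surv = load_preset(config.preset)
        if config.n_participants is not None:
            surv = dataclasses.replace(surv, n_participants=config.n_participants)
        cohort, excluded = generate_cohort(
            mixture, surv, rng, validity_threshold_hours=config.validity_hours
        )
        counts: dict = {
            "n_input_participants": surv.n_participants,
            "excluded": excluded,
            "n_summarized": len(cohort),
            "n_with_outcome": len(cohort),
        }
    elif config.episodes_csv and config.outcomes_csv:
        cohort, counts = _load_cohort_from_files(config)
    else:
        raise ValueError("config must name a preset or provide episodes+outcomes CSVs")
    log.info("cohort assembled: %d participants, %d events",
             len(cohort), int(cohort["event"].sum()))

    cohort_path = out_dir / "cohort.csv"
    cohort.to_csv(cohort_path, index=False, float_format="%.10g")

    fits: dict[tuple[int, str, str], ModelFit] = {}
    tidy_frames = []
    model_counts = []
    for model_id in config.models:
        predictors = MODEL_PREDICTORS[model_id]
        for adj in config.adjustments:
            for outcome in config.outcomes:
                if outcome == "all_cause":
                    fit = fit_cox(cohort, predictors, adj, outcome="all_cause")
                else:
                    if outcome not in CAUSES:
                        raise ValueError(f"unknown outcome {outcome!r}")
                    fit = fit_fine_gray(cohort, outcome, predictors, adj)
                fits[(model_id, adj, outcome)] = fit
                tidy_frames.append(fit.to_tidy())
                model_counts.append({
                    "model": model_id, "adjustment": adj, "outcome": outcome,
                    "n_analyzed": fit.n, "n_dropped_missing": fit.n_dropped,
                    "n_events": fit.n_events,
                })
                log.info("fitted model %d (%s, %s): n=%d, events=%d",
                         model_id, adj, outcome, fit.n, fit.n_events)

    models_df = pd.concat(tidy_frames, ignore_index=True)
    models_df.to_csv(out_dir / "models.csv", index=False, float_format="%.10g")

    comparisons = []
    for adj in config.adjustments:
        for outcome in config.outcomes:
            k1, k2, k3 = [(m, adj, outcome) for m in (1, 2, 3)]
            if k1 in fits and k2 in fits:
                res = compare_aic(fits[k1], fits[k2])
                comparisons.append({
                    "kind": res.kind, "adjustment": adj, "outcome": outcome,
                    "statistic": res.statistic, "df": "",
                    "value": res.p_or_relative_likelihood,
                    "detail": f"worse={res.worse}",
                })
            if k1 in fits and k3 in fits:
                res = lrt_nested(fits[k1], fits[k3])
                comparisons.append({
                    "kind": res.kind, "adjustment": adj, "outcome": outcome,
                    "statistic": res.statistic, "df": res.df,
                    "value": res.p_or_relative_likelihood,
                    "detail": "model 1 vs model 3",
                })

    poly = fit_sri_duration_polynomials(cohort)
    for (red, full), (f, d1, d2, p) in sorted(poly.f_tests.items()):
        comparisons.append({
            "kind": "polynomial_f_test", "adjustment": "", "outcome": "sri~duration",
            "statistic": f, "df": f"{d1},{d2}", "value": p,
            "detail": f"degree {red} vs {full}",
        })
    comparisons.append({
        "kind": "cubic_turning_point", "adjustment": "", "outcome": "sri~duration",
        "statistic": poly.turning_point if poly.turning_point is not None else "",
        "df": "", "value": poly.sri_at_turning_point
        if poly.sri_at_turning_point is not None else "",
        "detail": "duration (h) at local maximum of fitted cubic; value = fitted SRI",
    })
    pd.DataFrame(comparisons).to_csv(
        out_dir / "comparisons.csv", index=False, float_format="%.10g"
    )

    _km_curves(cohort).to_csv(out_dir / "curves.csv", index=False,
                              float_format="%.10g")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "models": model_counts,
        "outputs": ["cohort.csv", "models.csv", "comparisons.csv", "curves.csv"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
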