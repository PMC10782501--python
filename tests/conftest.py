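from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from srisurv import SleepEpisode, episodes_to_epoch_series
from srisurv.simulate import SurvivalGenConfig, generate_covariates, simulate_survival

START = datetime(2015, 3, 2, 12, 0)  # a Monday noon


def nightly_episodes(n_days=7, onset_h=23.0, duration_h=8.0, pid="p"):
    """Identical nights at the given clock onset for n_days."""
    eps = []
    base = START.replace(hour=0, minute=0, second=0)
    for d in range(n_days):
        onset = base + timedelta(days=d, hours=onset_h)
        eps.append(SleepEpisode(pid, onset, onset + timedelta(hours=duration_h)))
    return eps


def series_for(episodes, n_days=7, epoch_length=30, non_wear=()):
    span = (START, START + timedelta(days=n_days))
    return episodes_to_epoch_series(list(episodes), list(non_wear), epoch_length, span)


@pytest.fixture
def regular_week():
    """7 identical nights 23:00-07:00 rendered at 30-s epochs."""
    eps = nightly_episodes()
    return eps, series_for(eps)


def survival_layer_cohort(
    n: int,
    rng: np.random.Generator,
    sri_log_hrs=None,
    duration_log_hrs=None,
    rate: float = 0.03,
    duration_coupling: float = 0.35,
    covariate_log_hrs=None,
) -> pd.DataFrame:
    """Fast cohort for model tests: summaries drawn parametrically (no
    epoch simulation), survival attached by the package generator."""
    sri = np.clip(rng.normal(80, 10, n), 5, 99)
    dur = np.clip(6.9 + duration_coupling * (sri - 80) / 10 + rng.normal(0, 0.9, n),
                  1, 13)
    summaries = pd.DataFrame({
        "participant_id": [f"S{i:05d}" for i in range(n)],
        "sri": sri,
        "sleep_duration": dur,
    })
    config = SurvivalGenConfig(
        n_participants=n,
        baseline_hazards={"all": rate},
        sri_log_hrs={"all": list(sri_log_hrs)} if sri_log_hrs is not None else {},
        duration_log_hrs={"all": list(duration_log_hrs)}
        if duration_log_hrs is not None else {},
        covariate_log_hrs=covariate_log_hrs or {},
    )
    return simulate_survival(summaries, config, rng)
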