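"""Synthetic sleep recordings and survival cohorts.

Two layers:

1. an epoch-level sleep--wake generator: per day a main night episode
   with Gaussian onset timing and duration, optional intra-night
   awakenings (wake bouts carved out of the night), afternoon naps, and
   device non-wear intervals, rendered to a 30-s epoch grid;
2. a survival layer attaching covariates and cause-specific exponential
   event times whose hazards depend on SRI and duration quintile
   membership (a step function, matching the analysis structure), with
   administrative censoring at the follow-up horizon.

The default ("ukb_like") mixture is calibrated so the generated SRI
distribution has median ~= 81 with IQR ~= 74-86 and the null event rate
is ~= 4.84 deaths per 1000 person-years over a 6.30 +/- 0.83 year
follow-up censored at 7.8 years, emulating the scale of a large
accelerometer cohort of older adults.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import yaml

from .daily import DEFAULT_DAY_BOUNDARY_HOURS
from .epochs import EpochSeries, SleepEpisode, episodes_to_epoch_series, merge_intervals
from .metrics import summarize_participant, summary_to_row
from .quintiles import assign_quintiles
from .regularity import DEFAULT_VALIDITY_HOURS

# arbitrary fixed recording start (a Monday noon); only clock arithmetic matters
RECORDING_START = datetime(2015, 3, 2, 12, 0, 0)

CAUSE_FRACTIONS = {"cardiometabolic": 377 / 1859, "cancer": 1092 / 1859,
                   "other": 390 / 1859}
DEFAULT_EVENT_RATE = 4.84e-3  # deaths per person-year, all causes


@dataclass
class SleepPatternParams:
    """Tunable sleep-pattern generator for one participant archetype.

    Clock times are decimal hours; durations/SDs in hours; rates are per
    day (naps, awakenings) or per week (non-wear).
    """

    mean_onset: float = 23.0
    onset_sd: float = 0.75
    mean_duration: float = 8.0
    duration_sd: float = 0.5
    # between-participant spread of habitual duration: each participant's
    # own mean is drawn once from N(mean_duration, duration_between_sd)
    duration_between_sd: float = 0.0
    nap_probability: float = 0.1
    nap_duration: float = 0.75
    awakening_rate: float = 1.0
    awakening_duration: float = 0.25
    nonwear_rate: float = 0.5
    nonwear_duration: float = 2.0
    n_days: int = 7
    epoch_length: int = 30

    def validate(self) -> None:
        for name in ("onset_sd", "duration_sd", "nap_probability", "nap_duration",
                     "awakening_rate", "awakening_duration", "nonwear_rate",
                     "nonwear_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.nap_probability <= 1):
            raise ValueError("nap_probability must be in [0, 1]")
        if self.mean_duration + 4 * self.duration_sd + self.nap_duration >= 22:
            raise ValueError(
                "mean_duration + perturbations must fit within a day; "
                f"got mean {self.mean_duration} h with sd {self.duration_sd} h"
            )
        if self.n_days < 1:
            raise ValueError("n_days must be positive")


@dataclass
class SurvivalGenConfig:
    """Cause-specific proportional-hazards survival generator settings.

    ``sri_log_hrs`` / ``duration_log_hrs`` map each cause to five
    log-hazard-ratios over quintiles Q1..Q5 with Q1 = 0 (reference).
    ``baseline_hazards`` are per-year exponential rates per cause.
    """

    n_participants: int = 1000
    follow_up_mean: float = 6.30
    follow_up_sd: float = 0.83
    censor_horizon: float = 7.8
    baseline_hazards: dict = field(
        default_factory=lambda: {
            c: DEFAULT_EVENT_RATE * f for c, f in CAUSE_FRACTIONS.items()
        }
    )
    sri_log_hrs: dict = field(default_factory=dict)  # cause -> 5 floats
    duration_log_hrs: dict = field(default_factory=dict)
    covariate_log_hrs: dict = field(
        default_factory=lambda: {"age": 0.08, "sex_male": 0.45,
                                 "smoking_current": 0.70}
    )
    # MCAR missingness applied to the income covariate, so full-adjustment
    # complete-case models analyse a smaller N than minimal ones
    covariate_missingness: float = 0.0

    def validate(self) -> None:
        for c, lam in self.baseline_hazards.items():
            if lam < 0:
                raise ValueError(f"baseline hazard for {c!r} must be >= 0")
        for name, table in (("sri_log_hrs", self.sri_log_hrs),
                            ("duration_log_hrs", self.duration_log_hrs)):
            for cause, vec in table.items():
                if len(vec) != 5:
                    raise ValueError(f"{name}[{cause!r}] must have 5 entries (Q1..Q5)")
                if vec[0] != 0:
                    raise ValueError(f"{name}[{cause!r}] Q1 must be 0 (reference)")


def generate_sleep_pattern(
    params: SleepPatternParams,
    rng: np.random.Generator | int,
    participant_id: str = "sim",
) -> tuple[list[SleepEpisode], list[tuple[datetime, datetime]], EpochSeries]:
    """Simulate one participant's recording.

    Returns (episodes, non_wear, series).  ``episodes`` holds the logical
    sleep periods — one whole night per day plus any naps — which is what
    daily main-sleep selection consumes; intra-night awakenings appear
    only in the epoch series (WAKE carved out of the night), so the
    summed-SLEEP daily duration is shorter than offset − onset.
    """
    params.validate()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_days = params.n_days
    span = (RECORDING_START, RECORDING_START + timedelta(days=n_days))
    span_h = 24.0 * n_days
    onset_base = (params.mean_onset - DEFAULT_DAY_BOUNDARY_HOURS) % 24.0

    habitual = params.mean_duration + (
        rng.normal(0.0, params.duration_between_sd)
        if params.duration_between_sd > 0 else 0.0
    )
    habitual = float(np.clip(habitual, 1.5, 12.0))

    nights: list[tuple[float, float]] = []  # hours after span start
    prev_off = 0.0
    for d in range(n_days):
        onset = d * 24.0 + onset_base + rng.normal(0.0, params.onset_sd)
        dur = max(rng.normal(habitual, params.duration_sd), 1.0)
        onset = max(onset, prev_off + 0.5, 0.0)
        offset = min(onset + dur, span_h)
        if offset - onset >= 1.0:
            nights.append((onset, offset))
            prev_off = offset

    # naps: early-to-mid afternoon, independent of the nights
    naps: list[tuple[float, float]] = []
    for d in range(n_days):
        if rng.random() < params.nap_probability:
            start = d * 24.0 + rng.uniform(1.0, 5.0)  # 13:00-17:00 clock
            end = min(start + params.nap_duration, span_h)
            if end > start and not any(a < end and start < b for a, b in nights):
                naps.append((start, end))

    # awakenings: carve wake bouts out of each night for the epoch render
    render: list[tuple[float, float]] = []
    for a, b in nights:
        cuts: list[tuple[float, float]] = []
        n_awake = rng.poisson(params.awakening_rate)
        margin = 0.25
        for _ in range(n_awake):
            lo, hi = a + margin, b - margin - params.awakening_duration
            if hi <= lo:
                continue
            s = rng.uniform(lo, hi)
            cuts.append((s, s + params.awakening_duration))
        pos = a
        for s, e in sorted(cuts):
            s, e = max(s, pos), max(e, pos)
            if s > pos:
                render.append((pos, s))
            pos = max(pos, e)
        if b > pos:
            render.append((pos, b))
    render.extend(naps)

    nonwear: list[tuple[float, float]] = []
    n_nw = rng.poisson(params.nonwear_rate * n_days / 7.0)
    for _ in range(n_nw):
        s = rng.uniform(0.0, span_h - params.nonwear_duration) \
            if span_h > params.nonwear_duration else 0.0
        nonwear.append((s, min(s + params.nonwear_duration, span_h)))

    def to_dt(h: float) -> datetime:
        return RECORDING_START + timedelta(seconds=round(h * 3600.0))

    episode_objs = [
        SleepEpisode(participant_id, to_dt(a), to_dt(b))
        for a, b in sorted(nights + naps)
    ]
    render_objs = [
        SleepEpisode(participant_id, to_dt(a), to_dt(b))
        for a, b in sorted(render) if to_dt(b) > to_dt(a)
    ]
    nonwear_ivs = merge_intervals([(to_dt(a), to_dt(b)) for a, b in nonwear
                                   if to_dt(b) > to_dt(a)])
    series = episodes_to_epoch_series(
        render_objs, nonwear_ivs, params.epoch_length, span,
        participant_id=participant_id,
    )
    return episode_objs, nonwear_ivs, series


def generate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate table emulating a UK accelerometer cohort of older adults."""
    income = rng.integers(1, 6, size=n)
    smoking = rng.choice(["never", "previous", "current"], size=n,
                         p=[0.573, 0.364, 0.063])
    return pd.DataFrame({
        "age": np.clip(rng.normal(62.8, 7.8, size=n), 43.5, 79.0),
        "sex": rng.choice(["female", "male"], size=n, p=[0.55, 0.45]),
        "ethnicity": rng.choice(["white", "other"], size=n, p=[0.972, 0.028]),
        "physical_activity": np.clip(rng.normal(28.4, 8.1, size=n), 4.0, 70.0),
        "employment": rng.choice(["employed", "not_employed"], size=n,
                                 p=[0.608, 0.392]),
        "income": income.astype(float),
        "deprivation": rng.normal(-1.79, 2.77, size=n),
        "social_visits": rng.integers(1, 8, size=n).astype(float),
        "social_activities": rng.choice(["yes", "no"], size=n, p=[0.729, 0.271]),
        "smoking": smoking,
        "urbanicity": rng.choice(["urban", "rural"], size=n, p=[0.836, 0.164]),
        "shift_work": rng.choice(["yes", "no"], size=n, p=[0.073, 0.927]),
        "meds_chol_htn": rng.choice(["yes", "no"], size=n, p=[0.25, 0.75]),
    })


def _covariate_lp(cov: pd.DataFrame, effects: dict) -> np.ndarray:
    """Linear predictor contribution of the covariates (centred age)."""
    lp = np.zeros(len(cov))
    for key, beta in effects.items():
        if key == "age":
            lp += beta * (cov["age"].to_numpy() - 62.8)
        elif key == "sex_male":
            lp += beta * (cov["sex"] == "male").to_numpy()
        elif key == "smoking_current":
            lp += beta * (cov["smoking"] == "current").to_numpy()
        elif key == "smoking_previous":
            lp += beta * (cov["smoking"] == "previous").to_numpy()
        elif key in cov.columns and cov[key].dtype != object:
            lp += beta * cov[key].to_numpy()
        else:
            raise ValueError(f"unknown covariate effect {key!r}")
    return lp


def simulate_survival(
    summaries: pd.DataFrame,
    config: SurvivalGenConfig,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Attach covariates and cause-specific survival outcomes to summaries.

    Event times are exponential per cause with hazard
    lambda_c * exp(sri_beta[q_sri] + dur_beta[q_dur] + covariate lp);
    the earliest cause wins, censored at min(follow-up draw, horizon).
    With all hazards zero an all-censored cohort is returned (a warning
    is emitted rather than an error).
    """
    config.validate()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(summaries)
    out = summaries.reset_index(drop=True).copy()
    if not {"sri", "sleep_duration"}.issubset(out.columns):
        raise ValueError("summaries must have 'sri' and 'sleep_duration' columns")

    cov = generate_covariates(n, rng)
    q_sri = assign_quintiles(out["sri"], "sri").labels.cat.codes.to_numpy()
    q_dur = assign_quintiles(out["sleep_duration"], "sleep_duration").labels.cat.codes.to_numpy()
    cov_lp = _covariate_lp(cov, config.covariate_log_hrs)
    if config.covariate_missingness > 0:
        # hazards are computed from the complete values; missingness only
        # affects what the analyst sees
        mask = rng.random(n) < config.covariate_missingness
        cov.loc[mask, "income"] = np.nan
    out = pd.concat([out, cov], axis=1)

    causes = sorted(config.baseline_hazards)
    cause_times = np.full((n, len(causes)), np.inf)
    for j, c in enumerate(causes):
        lam = config.baseline_hazards[c]
        if lam <= 0:
            continue
        lp = cov_lp.copy()
        if c in config.sri_log_hrs:
            lp += np.asarray(config.sri_log_hrs[c])[q_sri]
        if c in config.duration_log_hrs:
            lp += np.asarray(config.duration_log_hrs[c])[q_dur]
        cause_times[:, j] = rng.exponential(1.0 / (lam * np.exp(lp)))

    t_event = cause_times.min(axis=1)
    which = cause_times.argmin(axis=1)

    follow_up = rng.normal(config.follow_up_mean, config.follow_up_sd, size=n)
    follow_up = np.clip(follow_up, 0.05, config.censor_horizon)

    observed = t_event <= follow_up
    if not observed.any():
        import warnings as _w

        _w.warn("no events generated (all-censored cohort)", stacklevel=2)
    out["follow_up_time"] = np.where(observed, t_event, follow_up)
    out["event"] = observed.astype(int)
    out["cause"] = pd.Series(
        np.where(observed, np.asarray(causes, dtype=object)[which], None),
        dtype=object,
    )
    return out


def generate_cohort(
    pattern_presets: list[tuple[float, SleepPatternParams]],
    surv: SurvivalGenConfig,
    rng: np.random.Generator | int,
    validity_threshold_hours: float = DEFAULT_VALIDITY_HOURS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """End-to-end synthetic cohort: sleep patterns -> metrics -> survival.

    ``pattern_presets`` is a mixture of (weight, params); each participant
    draws one component, a full recording is simulated and summarised via
    the same epoch/SRI/daily machinery the analysis uses, and survival
    outcomes are attached.  Participants failing the validity rule are
    excluded and counted (they receive no outcome), so the returned table
    is exactly what the models consume.

    Returns (cohort table, exclusion counts).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    weights = np.array([w for w, _ in pattern_presets], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    for _, p in pattern_presets:
        p.validate()

    component = rng.choice(len(pattern_presets), size=surv.n_participants, p=weights)
    rows = []
    excluded = {"below_validity_threshold": 0, "no_valid_days": 0}
    for i in range(surv.n_participants):
        params = pattern_presets[component[i]][1]
        pid = f"P{i:06d}"
        episodes, nonwear, series = generate_sleep_pattern(params, rng, pid)
        summary, reg = summarize_participant(
            episodes, nonwear, series=series,
            validity_threshold_hours=validity_threshold_hours,
        )
        if summary is None:
            key = "below_validity_threshold" if not reg.is_valid else "no_valid_days"
            excluded[key] += 1
            continue
        row = summary_to_row(summary)
        row["sleep_duration"] = row.pop("mean_sleep_duration_h")
        rows.append(row)

    summaries = pd.DataFrame(rows)
    if summaries.empty:
        raise ValueError("no participant passed the validity rule; check parameters")
    cohort = simulate_survival(summaries, surv, rng)
    return cohort, excluded


# ---------------------------------------------------------------------------
# preset library


def _params_from_dict(d: dict) -> SleepPatternParams:
    return SleepPatternParams(**d)


def load_preset(name: str) -> tuple[list[tuple[float, SleepPatternParams]], SurvivalGenConfig]:
    """Load a named preset ("ukb_like", "null", "strong_effect") from the
    packaged YAML library."""
    ref = importlib.resources.files("srisurv") / "presets" / f"{name}.yaml"
    try:
        text = ref.read_text()
    except FileNotFoundError as err:
        raise ValueError(f"unknown preset {name!r}") from err
    raw = yaml.safe_load(text)
    mixture = [
        (float(comp["weight"]), _params_from_dict(comp["params"]))
        for comp in raw["pattern_mixture"]
    ]
    surv = SurvivalGenConfig(**raw["survival"])
    return mixture, surv
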