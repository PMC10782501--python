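"""Cohort-level sleep-metric extraction.

Glues the epoch, regularity and daily-record layers together: takes
interval-format sleep episodes and non-wear intervals for many
participants and produces one summary row per participant (SRI, mean
sleep duration, mean mid-sleep, onset/offset SD, valid-day count).
Participants failing the 120-hour valid-pair rule are excluded and
counted.

``SleepSummaryTransformer`` exposes the same computation as a stateless
scikit-learn transformer over a long-format interval table, so it can sit
at the front of an sklearn pipeline.
"""

from __future__ import annotations

from dataclasses import asdict
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .daily import (
    DEFAULT_DAY_BOUNDARY_HOURS,
    DEFAULT_MAX_MISSING_FRACTION,
    ParticipantSummary,
    daily_sleep_records,
    participant_summary,
)
from .epochs import EpochSeries, SleepEpisode, episodes_to_epoch_series
from .regularity import DEFAULT_VALIDITY_HOURS, RegularityResult, compute_sri

SUMMARY_COLUMNS = [
    "participant_id",
    "sri",
    "valid_pair_hours",
    "mean_sleep_duration_h",
    "mean_mid_sleep",
    "onset_sd_h",
    "offset_sd_h",
    "n_valid_days",
]


def _default_span(
    episodes: list[SleepEpisode],
    non_wear: list[tuple[datetime, datetime]],
    day_boundary: float,
) -> tuple[datetime, datetime]:
    """Smallest whole-day window, anchored at the day boundary, covering all
    intervals."""
    starts = [e.onset for e in episodes] + [a for a, _ in non_wear]
    ends = [e.offset for e in episodes] + [b for _, b in non_wear]
    if not starts:
        raise ValueError("cannot infer a span from empty interval data")
    t0, t1 = min(starts), max(ends)
    base = t0.replace(hour=0, minute=0, second=0, microsecond=0) + timedelta(
        hours=day_boundary
    )
    if base > t0:
        base -= timedelta(days=1)
    n_days = int(np.ceil((t1 - base).total_seconds() / 86400.0))
    return base, base + timedelta(days=n_days)


def summarize_participant(
    episodes: list[SleepEpisode],
    non_wear: list[tuple[datetime, datetime]] | None = None,
    *,
    span: tuple[datetime, datetime] | None = None,
    epoch_length: int = 30,
    validity_threshold_hours: float = DEFAULT_VALIDITY_HOURS,
    day_boundary: float = DEFAULT_DAY_BOUNDARY_HOURS,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
    series: EpochSeries | None = None,
    main_episodes: list[SleepEpisode] | None = None,
) -> tuple[ParticipantSummary | None, RegularityResult]:
    """Full single-participant path: intervals -> epochs -> SRI + summary.

    ``series`` may be supplied directly (pre-binarised epoch input), in
    which case ``episodes`` is only used for daily onset/offset records.
    ``main_episodes`` optionally overrides the episode set used for daily
    main-sleep selection (e.g. whole nights when ``episodes`` carries
    awakening-fragmented intervals).
    """
    non_wear = non_wear or []
    if series is None:
        if span is None:
            span = _default_span(episodes, non_wear, day_boundary)
        series = episodes_to_epoch_series(episodes, non_wear, epoch_length, span)
    reg = compute_sri(series, validity_threshold_hours)
    records = daily_sleep_records(
        main_episodes if main_episodes is not None else episodes,
        series,
        day_boundary=day_boundary,
        max_missing_fraction=max_missing_fraction,
    )
    return participant_summary(records, reg), reg


def summary_to_row(
    summary: ParticipantSummary, day_boundary: float = DEFAULT_DAY_BOUNDARY_HOURS
) -> dict:
    """Flatten a ParticipantSummary to the summary-CSV schema.

    ``mean_mid_sleep`` is reported as decimal hours after the day
    boundary, which is continuous for normal night sleep (e.g. 03:00
    clock time with a noon boundary -> 15.0).
    """
    return {
        "participant_id": summary.participant_id,
        "sri": summary.sri,
        "valid_pair_hours": summary.valid_pair_hours,
        "mean_sleep_duration_h": summary.mean_sleep_duration,
        "mean_mid_sleep": (summary.mean_mid_sleep - day_boundary) % 24.0,
        "onset_sd_h": summary.onset_sd if summary.onset_sd is not None else np.nan,
        "offset_sd_h": summary.offset_sd if summary.offset_sd is not None else np.nan,
        "n_valid_days": summary.n_valid_days,
    }


def summarize_cohort(
    episodes_by_pid: dict[str, list[SleepEpisode]],
    nonwear_by_pid: dict[str, list[tuple[datetime, datetime]]] | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Summarise every participant; returns (summary table, exclusion counts).

    Exclusion counts report participants dropped by the valid-pair-hours
    rule (``below_validity_threshold``) and those with no valid day
    (``no_valid_days``).
    """
    nonwear_by_pid = nonwear_by_pid or {}
    day_boundary = kwargs.get("day_boundary", DEFAULT_DAY_BOUNDARY_HOURS)
    rows = []
    excluded = {"below_validity_threshold": 0, "no_valid_days": 0}
    for pid in sorted(episodes_by_pid):
        summary, reg = summarize_participant(
            episodes_by_pid[pid], nonwear_by_pid.get(pid, []), **kwargs
        )
        if summary is None:
            if not reg.is_valid:
                excluded["below_validity_threshold"] += 1
            else:
                excluded["no_valid_days"] += 1
            continue
        rows.append(summary_to_row(summary, day_boundary))
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return df, excluded


class SleepSummaryTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer: long-format interval table -> summary table.

    Input is a DataFrame with columns ``participant_id``, ``onset``,
    ``offset`` and ``kind`` (``"sleep"`` or ``"nonwear"``); output is one
    row per participant passing the validity rule, with the summary-CSV
    schema.  Exclusion counts from the latest transform are kept in
    ``exclusions_``.
    """

    def __init__(
        self,
        epoch_length: int = 30,
        validity_threshold_hours: float = DEFAULT_VALIDITY_HOURS,
        day_boundary: float = DEFAULT_DAY_BOUNDARY_HOURS,
        max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
    ):
        self.epoch_length = epoch_length
        self.validity_threshold_hours = validity_threshold_hours
        self.day_boundary = day_boundary
        self.max_missing_fraction = max_missing_fraction

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        required = {"participant_id", "onset", "offset", "kind"}
        if not required.issubset(X.columns):
            raise ValueError(f"interval table must have columns {sorted(required)}")
        X = X.copy()
        X["onset"] = pd.to_datetime(X["onset"])
        X["offset"] = pd.to_datetime(X["offset"])
        episodes: dict[str, list[SleepEpisode]] = {}
        nonwear: dict[str, list[tuple[datetime, datetime]]] = {}
        for row in X.itertuples(index=False):
            pid = str(row.participant_id)
            if row.kind == "sleep":
                episodes.setdefault(pid, []).append(
                    SleepEpisode(pid, row.onset.to_pydatetime(), row.offset.to_pydatetime())
                )
            elif row.kind == "nonwear":
                nonwear.setdefault(pid, []).append(
                    (row.onset.to_pydatetime(), row.offset.to_pydatetime())
                )
            else:
                raise ValueError(f"unknown interval kind {row.kind!r}")
        df, self.exclusions_ = summarize_cohort(
            episodes,
            nonwear,
            epoch_length=self.epoch_length,
            validity_threshold_hours=self.validity_threshold_hours,
            day_boundary=self.day_boundary,
            max_missing_fraction=self.max_missing_fraction,
        )
        return df
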