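"""Daily sleep records and participant-level sleep summaries.

The recording is cut into 24-h windows anchored at a configurable day
boundary (noon by default, so a typical night is never split).  Each
window is assigned its *main sleep period* — the longest sleep episode
whose onset falls inside the window — and daily sleep duration is the
summed SLEEP-epoch time between that period's onset and offset, so
mid-sleep awakenings do not count towards duration and in-period
non-wear is not mistaken for sleep.  Naps (shorter episodes in the same
window) are excluded from daily duration.

Participant summaries average duration and mid-sleep over valid days and
report the standard deviation of daily onset and offset clock times;
clock times are unwrapped across midnight before averaging (23:30 and
00:30 are one hour apart, not 23 hours).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Callable, Sequence

import numpy as np

from .epochs import MISSING, SLEEP, EpochSeries, SleepEpisode
from .regularity import RegularityResult

DEFAULT_DAY_BOUNDARY_HOURS = 12.0
DEFAULT_MAX_MISSING_FRACTION = 0.20


@dataclass(frozen=True)
class DailySleepRecord:
    participant_id: str
    day_index: int
    onset: datetime | None
    offset: datetime | None
    sleep_duration: float | None  # hours of actual SLEEP time
    mid_sleep: float | None  # clock time, decimal hours in [0, 24)
    valid: bool


@dataclass(frozen=True)
class ParticipantSummary:
    participant_id: str
    sri: float
    mean_sleep_duration: float  # hours
    mean_mid_sleep: float  # clock time, decimal hours in [0, 24)
    onset_sd: float | None  # hours; None with < 2 valid days
    offset_sd: float | None
    n_valid_days: int
    valid_pair_hours: float


def clock_hours(t: datetime) -> float:
    """Decimal hours since the most recent midnight."""
    return t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9


def _unwrap_to_center(values: np.ndarray, period: float = 24.0) -> np.ndarray:
    """Shift each clock value by a multiple of the period so all values sit
    near a common representative.

    A circular mean locates a provisional centre (robust to values
    straddling midnight); values are unwrapped to it, and a second pass
    unwraps to the median of the first pass, which is the representative
    the summary statistics use.
    """
    v = np.asarray(values, dtype=float) % period
    ang = v / period * 2 * np.pi
    center = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi) * period
    first = v + period * np.round((center - v) / period)
    med = np.median(first)
    return v + period * np.round((med - v) / period)


def circular_mean_hours(values: Sequence[float], period: float = 24.0) -> float:
    """Mean clock time (decimal hours, mod the period) after unwrapping."""
    return float(np.mean(_unwrap_to_center(np.asarray(values), period)) % period)


def clock_sd_hours(values: Sequence[float], period: float = 24.0) -> float:
    """Population SD of clock times after unwrapping across midnight."""
    return float(np.std(_unwrap_to_center(np.asarray(values), period)))


def _state_hours_between(
    series: EpochSeries, start: datetime, end: datetime, state: int
) -> float:
    """Hours of epochs with the given state whose midpoint lies in [start, end)."""
    s0 = (start - series.start).total_seconds()
    s1 = (end - series.start).total_seconds()
    lo = int(np.ceil(s0 / series.epoch_length - 0.5))
    hi = int(np.ceil(s1 / series.epoch_length - 0.5))
    lo = max(lo, 0)
    hi = min(hi, len(series))
    if hi <= lo:
        return 0.0
    n = int((series.states[lo:hi] == state).sum())
    return n * series.epoch_length / 3600.0


def daily_sleep_records(
    episodes: Sequence[SleepEpisode],
    series: EpochSeries,
    day_boundary: float = DEFAULT_DAY_BOUNDARY_HOURS,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
    day_validator: Callable[[DailySleepRecord], bool] | None = None,
) -> list[DailySleepRecord]:
    """Assign each 24-h window its main sleep period and daily metrics.

    Windows are half-open ``[boundary, boundary + 24 h)`` anchored at
    ``day_boundary`` (clock hours); the first window is the last boundary
    at or before the series start.  Days with no episode onset in the
    window are invalid; days whose main period is MISSING beyond
    ``max_missing_fraction`` of its length are invalid.  An optional
    ``day_validator`` predicate can veto further days (it can only turn a
    valid day invalid, never resurrect one).
    """
    pid = series.participant_id
    base = series.start.replace(hour=0, minute=0, second=0, microsecond=0) + timedelta(
        hours=day_boundary
    )
    if base > series.start:
        base -= timedelta(days=1)

    n_days = int(np.ceil((series.end - base).total_seconds() / 86400.0))
    eps = sorted(episodes, key=lambda e: e.onset)

    records: list[DailySleepRecord] = []
    for d in range(n_days):
        w0 = base + timedelta(days=d)
        w1 = w0 + timedelta(days=1)
        in_window = [e for e in eps if w0 <= e.onset < w1]
        if not in_window:
            records.append(DailySleepRecord(pid, d, None, None, None, None, False))
            continue
        # main sleep period: longest episode; ties -> earlier onset
        main = max(in_window, key=lambda e: (e.offset - e.onset, -e.onset.timestamp()))
        span_h = (main.offset - main.onset).total_seconds() / 3600.0
        sleep_h = _state_hours_between(series, main.onset, main.offset, SLEEP)
        missing_h = _state_hours_between(series, main.onset, main.offset, MISSING)
        mid = main.onset + (main.offset - main.onset) / 2
        valid = span_h > 0 and (missing_h / span_h) <= max_missing_fraction
        rec = DailySleepRecord(
            participant_id=pid,
            day_index=d,
            onset=main.onset,
            offset=main.offset,
            sleep_duration=sleep_h,
            mid_sleep=clock_hours(mid),
            valid=valid,
        )
        if valid and day_validator is not None and not day_validator(rec):
            rec = DailySleepRecord(pid, d, main.onset, main.offset, sleep_h,
                                   clock_hours(mid), False)
        records.append(rec)
    return records


def participant_summary(
    records: Sequence[DailySleepRecord],
    regularity: RegularityResult,
) -> ParticipantSummary | None:
    """Join daily records and the SRI into one participant summary.

    Returns None when the SRI is invalid (below the valid-pair-hours
    threshold) or when no valid day exists.  Onset/offset SDs are None
    with fewer than two valid days.
    """
    if not regularity.is_valid or regularity.sri is None:
        return None
    valid = [r for r in records if r.valid]
    if not valid:
        return None

    durations = np.array([r.sleep_duration for r in valid], dtype=float)
    mids = np.array([r.mid_sleep for r in valid], dtype=float)
    onsets = np.array([clock_hours(r.onset) for r in valid])
    offsets = np.array([clock_hours(r.offset) for r in valid])

    if len(valid) >= 2:
        onset_sd: float | None = clock_sd_hours(onsets)
        offset_sd: float | None = clock_sd_hours(offsets)
    else:
        onset_sd = offset_sd = None

    return ParticipantSummary(
        participant_id=regularity.participant_id,
        sri=float(regularity.sri),
        mean_sleep_duration=float(durations.mean()),
        mean_mid_sleep=circular_mean_hours(mids),
        onset_sd=onset_sd,
        offset_sd=offset_sd,
        n_valid_days=len(valid),
        valid_pair_hours=regularity.valid_pair_hours,
    )
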