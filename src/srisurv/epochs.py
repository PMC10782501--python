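"""Epoch-level representation of sleep--wake recordings.

An actigraphy recording is discretised into fixed-length epochs (30 s by
default), each carrying one of three states: WAKE, SLEEP, or MISSING
(device non-wear or otherwise unscoreable time).  The epoch length must
divide 86 400 s so that "the same epoch 24 hours later" is an exact index
shift, which is what the Sleep Regularity Index pairs on.

Interval-format inputs (sleep episodes and non-wear intervals with
timestamps) are rendered onto the epoch grid by the midpoint rule: an
epoch is SLEEP if its midpoint falls inside a sleep interval, MISSING if
it falls inside a non-wear interval (non-wear wins over sleep), WAKE
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400

# state codes; fixed small ints so state arrays are compact uint8
WAKE: int = 0
SLEEP: int = 1
MISSING: int = 2

STATE_TO_CODE = {"W": WAKE, "S": SLEEP, "M": MISSING}
CODE_TO_STATE = {v: k for k, v in STATE_TO_CODE.items()}


@dataclass(frozen=True)
class SleepEpisode:
    """One continuous sleep interval (onset, offset) for a participant."""

    participant_id: str
    onset: datetime
    offset: datetime

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(
                f"episode onset must precede offset for participant "
                f"{self.participant_id!r}: {self.onset} >= {self.offset}"
            )

    @property
    def duration_hours(self) -> float:
        return (self.offset - self.onset).total_seconds() / 3600.0


@dataclass
class EpochSeries:
    """Per-participant sequence of sleep/wake/missing states on a fixed grid.

    Attributes
    ----------
    participant_id : str
    start : datetime
        Timestamp of the leading edge of the first epoch (timezone-naive
        local clock time).
    epoch_length : int
        Epoch length in seconds; must divide 86 400.
    states : np.ndarray
        uint8 array over {WAKE, SLEEP, MISSING}.
    """

    participant_id: str
    start: datetime
    epoch_length: int
    states: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        validate_epoch_length(self.epoch_length)
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 1:
            raise ValueError("states must be a 1-D sequence")
        if self.states.size and self.states.max() > MISSING:
            bad = sorted(set(self.states.tolist()) - set(CODE_TO_STATE))
            raise ValueError(f"states contains invalid codes: {bad}")

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=self.epoch_length * len(self))

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_length

    def state_string(self) -> str:
        """Compact S/W/M encoding, used by the epoch CSV format."""
        lut = np.array(["W", "S", "M"])
        return "".join(lut[self.states])


def validate_epoch_length(epoch_length: int) -> None:
    if not (isinstance(epoch_length, (int, np.integer)) and epoch_length > 0):
        raise ValueError(f"epoch_length must be a positive integer, got {epoch_length!r}")
    if SECONDS_PER_DAY % int(epoch_length) != 0:
        raise ValueError(
            f"epoch_length must divide 86400 seconds, got {epoch_length}"
        )


def _interval_bounds_seconds(
    intervals: Sequence[tuple[datetime, datetime]], origin: datetime
) -> np.ndarray:
    """Flatten (start, end) pairs to an ascending boundary array of seconds."""
    out = np.empty(2 * len(intervals))
    for i, (a, b) in enumerate(intervals):
        out[2 * i] = (a - origin).total_seconds()
        out[2 * i + 1] = (b - origin).total_seconds()
    return out


def merge_intervals(
    intervals: Iterable[tuple[datetime, datetime]]
) -> list[tuple[datetime, datetime]]:
    """Union of possibly overlapping intervals, sorted."""
    ivs = sorted(intervals)
    merged: list[tuple[datetime, datetime]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def episodes_to_epoch_series(
    episodes: Sequence[SleepEpisode],
    non_wear: Sequence[tuple[datetime, datetime]],
    epoch_length: int,
    span: tuple[datetime, datetime],
    participant_id: str | None = None,
) -> EpochSeries:
    """Render interval-format sleep and non-wear data onto the epoch grid.

    An epoch is SLEEP if its midpoint lies inside any sleep episode,
    MISSING if inside any non-wear interval (non-wear takes precedence),
    else WAKE.

    Parameters
    ----------
    episodes : sequence of SleepEpisode
        Must be non-overlapping for the participant (overlap is rejected).
    non_wear : sequence of (start, end) datetimes
        May overlap each other; merged internally.
    epoch_length : int
        Seconds per epoch, must divide 86 400.
    span : (start, end)
        Covered interval; its length must be an integer number of epochs
        and must contain every episode.
    """
    validate_epoch_length(epoch_length)
    start, end = span
    span_s = (end - start).total_seconds()
    if span_s <= 0:
        raise ValueError("span end must be after span start")
    n_epochs, rem = divmod(span_s, epoch_length)
    if rem:
        raise ValueError("span length must be an integer multiple of epoch_length")
    n_epochs = int(n_epochs)

    if participant_id is None:
        ids = {e.participant_id for e in episodes}
        if len(ids) > 1:
            raise ValueError(f"episodes span multiple participants: {sorted(ids)}")
        participant_id = ids.pop() if ids else ""

    eps = sorted(episodes, key=lambda e: e.onset)
    for prev, cur in zip(eps, eps[1:]):
        if cur.onset < prev.offset:
            raise ValueError(
                f"overlapping sleep episodes for participant {participant_id!r}: "
                f"[{prev.onset}, {prev.offset}) overlaps [{cur.onset}, {cur.offset})"
            )
    for e in eps:
        if e.onset < start or e.offset > end:
            raise ValueError(
                f"episode [{e.onset}, {e.offset}) outside span [{start}, {end})"
            )

    mid = (np.arange(n_epochs) + 0.5) * epoch_length
    states = np.full(n_epochs, WAKE, dtype=np.uint8)

    if eps:
        bounds = _interval_bounds_seconds([(e.onset, e.offset) for e in eps], start)
        states[np.searchsorted(bounds, mid) % 2 == 1] = SLEEP
    nw = merge_intervals(non_wear)
    if nw:
        bounds = _interval_bounds_seconds(nw, start)
        states[np.searchsorted(bounds, mid) % 2 == 1] = MISSING

    return EpochSeries(
        participant_id=participant_id,
        start=start,
        epoch_length=int(epoch_length),
        states=states,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_episode_csv(path) -> dict[str, list[SleepEpisode]]:
    """Read an episode table (participant_id, onset, offset; ISO-8601 local).

    Returns a mapping participant_id -> episodes sorted by onset.  The same
    format is used for non-wear interval tables.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "onset", "offset"}
    if not required.issubset(df.columns):
        raise ValueError(f"episode CSV must have columns {sorted(required)}")
    df["onset"] = pd.to_datetime(df["onset"])
    df["offset"] = pd.to_datetime(df["offset"])
    out: dict[str, list[SleepEpisode]] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        eps = [
            SleepEpisode(pid, on.to_pydatetime(), off.to_pydatetime())
            for on, off in zip(grp["onset"], grp["offset"])
        ]
        out[pid] = sorted(eps, key=lambda e: e.onset)
    return out


def read_interval_csv(path) -> dict[str, list[tuple[datetime, datetime]]]:
    """Read a non-wear interval table with the same columns as episodes."""
    eps = read_episode_csv(path)
    return {pid: [(e.onset, e.offset) for e in lst] for pid, lst in eps.items()}


def write_episode_csv(path, episodes: Iterable[SleepEpisode]) -> None:
    rows = [
        {
            "participant_id": e.participant_id,
            "onset": e.onset.isoformat(),
            "offset": e.offset.isoformat(),
        }
        for e in episodes
    ]
    pd.DataFrame(rows, columns=["participant_id", "onset", "offset"]).to_csv(
        path, index=False
    )


def write_epoch_csv(path, series: Iterable[EpochSeries]) -> None:
    """Write epoch series in wide format: one row per participant with the
    state sequence encoded as an S/W/M string."""
    rows = [
        {
            "participant_id": s.participant_id,
            "start": s.start.isoformat(),
            "epoch_length_s": s.epoch_length,
            "states": s.state_string(),
        }
        for s in series
    ]
    pd.DataFrame(
        rows, columns=["participant_id", "start", "epoch_length_s", "states"]
    ).to_csv(path, index=False)


def read_epoch_csv(path) -> list[EpochSeries]:
    df = pd.read_csv(path, dtype={"participant_id": str, "states": str})
    required = {"participant_id", "start", "epoch_length_s", "states"}
    if not required.issubset(df.columns):
        raise ValueError(f"epoch CSV must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        codes = np.frombuffer(row.states.encode("ascii"), dtype=np.uint8)
        states = np.full(codes.size, 255, dtype=np.uint8)
        for sym, code in STATE_TO_CODE.items():
            states[codes == ord(sym)] = code
        if (states == 255).any():
            bad = sorted({chr(c) for c in codes} - set(STATE_TO_CODE))
            raise ValueError(
                f"invalid state symbols {bad} for participant {row.participant_id!r}"
            )
        out.append(
            EpochSeries(
                participant_id=row.participant_id,
                start=datetime.fromisoformat(row.start),
                epoch_length=int(row.epoch_length_s),
                states=states,
            )
        )
    return out
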