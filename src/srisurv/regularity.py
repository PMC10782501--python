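"""Sleep Regularity Index (SRI).

The SRI scores the day-to-day similarity of a sleep--wake recording as the
average concordance in sleep--wake state of all epoch pairs separated by
exactly 24 hours, linearly rescaled so that 100 is a perfectly repeating
pattern and 0 is the chance level for independent random states:

    SRI = 200 * (concordant pairs / valid pairs) - 100

A pair is *valid* when neither member is MISSING; a valid pair is
*concordant* when both members share the same state.  A score is
considered valid only when the recording provides at least
``validity_threshold_hours`` (default 120 h, i.e. 5 days) of
24-hour-separated valid pairs after non-wear removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import MISSING, SECONDS_PER_DAY, EpochSeries

DEFAULT_VALIDITY_HOURS = 120.0


@dataclass(frozen=True)
class RegularityResult:
    """SRI score for one participant with valid-pair accounting.

    ``sri`` is None when no valid pair exists or when the valid-pair time
    falls below the validity threshold (``is_valid`` False); the raw score
    is still exposed via ``sri_raw`` whenever at least one valid pair
    exists, for diagnostic use.
    """

    participant_id: str
    sri: float | None
    concordant_pairs: int
    valid_pairs: int
    valid_pair_hours: float
    is_valid: bool
    sri_raw: float | None = None

    def __post_init__(self) -> None:
        if (self.sri is not None) != self.is_valid:
            raise ValueError("sri must be present exactly when is_valid is True")
        if self.sri is not None and not (-100.0 <= self.sri <= 100.0):
            raise ValueError(f"sri out of range: {self.sri}")


def compute_sri(
    series: EpochSeries,
    validity_threshold_hours: float = DEFAULT_VALIDITY_HOURS,
) -> RegularityResult:
    """Compute the Sleep Regularity Index of an epoch series.

    Every epoch that has a partner exactly 24 h later forms one pair;
    pairs with a MISSING member are dropped from both numerator and
    denominator.  A series shorter than 24 h (or one whose missingness
    leaves no valid pair) yields ``is_valid=False`` with ``sri=None``
    rather than an error.
    """
    if len(series) == 0:
        raise ValueError("cannot compute SRI of an empty series")
    lag = SECONDS_PER_DAY // series.epoch_length
    states = series.states
    if len(states) <= lag:
        return RegularityResult(series.participant_id, None, 0, 0, 0.0, False)

    a = states[:-lag]
    b = states[lag:]
    valid = (a != MISSING) & (b != MISSING)
    n_valid = int(valid.sum())
    n_conc = int((valid & (a == b)).sum())
    hours = n_valid * series.epoch_length / 3600.0

    if n_valid == 0:
        return RegularityResult(series.participant_id, None, 0, 0, 0.0, False)

    raw = 200.0 * n_conc / n_valid - 100.0
    is_valid = hours >= validity_threshold_hours
    return RegularityResult(
        participant_id=series.participant_id,
        sri=raw if is_valid else None,
        concordant_pairs=n_conc,
        valid_pairs=n_valid,
        valid_pair_hours=hours,
        is_valid=is_valid,
        sri_raw=raw,
    )
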