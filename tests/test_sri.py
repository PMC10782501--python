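from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srisurv import EpochSeries, compute_sri
from srisurv.epochs import MISSING, SLEEP, WAKE

from conftest import START, nightly_episodes, series_for
from oracles import brute_force_sri


def make_series(states, epoch_length=3600, pid="p"):
    return EpochSeries(pid, START, epoch_length, np.asarray(states, dtype=np.uint8))


class TestBoundaryValues:
    def test_perfectly_repeating_pattern_scores_100(self, regular_week):
        _, series = regular_week
        res = compute_sri(series)
        assert res.sri == 100.0
        assert res.valid_pairs == 6 * 2880
        assert res.valid_pair_hours == 144.0

    def test_any_repeating_pattern_scores_100(self):
        rng = np.random.default_rng(0)
        day = rng.integers(0, 2, size=24)  # arbitrary daily template
        series = make_series(np.tile(day, 7))
        assert compute_sri(series).sri == 100.0

    def test_alternating_sleep_wake_days_score_minus_100(self):
        day_sleep = np.full(24, SLEEP)
        day_wake = np.full(24, WAKE)
        states = np.concatenate([day_sleep if d % 2 == 0 else day_wake
                                 for d in range(7)])
        res = compute_sri(make_series(states))
        assert res.sri == -100.0
        assert res.concordant_pairs == 0

    def test_random_patterns_score_near_zero_in_expectation(self):
        rng = np.random.default_rng(42)
        scores = []
        for _ in range(300):
            states = rng.integers(0, 2, size=6 * 2880)
            scores.append(compute_sri(make_series(states, epoch_length=30)).sri)
        scores = np.asarray(scores, dtype=float)
        mc_se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 3 * mc_se + 1e-9


class TestMissingHandling:
    def test_series_shorter_than_a_day_has_no_pairs(self):
        res = compute_sri(make_series([SLEEP] * 10))
        assert not res.is_valid and res.sri is None and res.valid_pairs == 0

    def test_all_missing_gives_invalid_not_error(self):
        res = compute_sri(make_series([MISSING] * 48))
        assert not res.is_valid and res.sri is None

    def test_missing_epochs_reduce_pair_hours_not_score(self, regular_week):
        _, series = regular_week
        st_ = series.states.copy()
        st_[:2880] = MISSING  # first day unusable
        res = compute_sri(EpochSeries("p", series.start, 30, st_))
        assert res.sri == 100.0
        assert res.valid_pair_hours == 120.0  # 5 days of pairs remain

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            compute_sri(make_series([]))


@settings(max_examples=150, deadline=None)
@given(
    n_epochs=st.integers(min_value=25, max_value=240),
    epoch_length=st.sampled_from([3600, 7200]),
    missing_frac=st.floats(0, 0.5),
    seed=st.integers(0, 2**31 - 1),
)
def test_sri_matches_bruteforce_pair_enumeration(n_epochs, epoch_length,
                                                 missing_frac, seed):
    """Vectorised SRI equals a literal loop over every 24-h pair."""
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 2, size=n_epochs)
    states[rng.random(n_epochs) < missing_frac] = MISSING
    series = make_series(states, epoch_length=epoch_length)
    res = compute_sri(series, validity_threshold_hours=0.0)
    expected, conc, valid = brute_force_sri(states, 86400 // epoch_length)
    assert res.valid_pairs == valid
    assert res.concordant_pairs == conc
    if expected is None:
        assert res.sri is None
    else:
        assert res.sri == expected  # identical arithmetic, exact match


@settings(max_examples=60, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_sri_invariant_to_sleep_wake_relabeling(seed):
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 3, size=rng.integers(30, 200))
    series = make_series(states)
    swapped = states.copy()
    swapped[states == SLEEP] = WAKE
    swapped[states == WAKE] = SLEEP
    a = compute_sri(series, validity_threshold_hours=0.0)
    b = compute_sri(make_series(swapped), validity_threshold_hours=0.0)
    assert a.sri_raw == b.sri_raw
    assert a.valid_pairs == b.valid_pairs


@settings(max_examples=60, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_sri_bounded(seed):
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 3, size=rng.integers(30, 400))
    res = compute_sri(make_series(states), validity_threshold_hours=0.0)
    if res.sri_raw is not None:
        assert -100.0 <= res.sri_raw <= 100.0


def test_validity_flips_exactly_at_threshold(regular_week):
    """Masking whole days sweeps valid-pair hours across the 120-h rule."""
    _, series = regular_week
    # 7-day recording: 144 h of pairs; each masked trailing day removes 24 h
    for days_masked, hours, expect_valid in [(0, 144.0, True), (1, 120.0, True),
                                             (2, 96.0, False)]:
        st_ = series.states.copy()
        if days_masked:
            st_[-days_masked * 2880:] = MISSING
        res = compute_sri(EpochSeries("p", series.start, 30, st_))
        assert res.valid_pair_hours == hours
        assert res.is_valid is expect_valid
    # one single epoch below the threshold already flips it
    st_ = series.states.copy()
    st_[-2880:] = MISSING
    st_[0] = MISSING
    res = compute_sri(EpochSeries("p", series.start, 30, st_))
    assert res.valid_pair_hours < 120.0 and not res.is_valid


def test_expected_sri_not_increasing_in_flip_noise():
    """State-flip noise applied to a regular template cannot raise SRI."""
    rng = np.random.default_rng(7)
    day = np.array([SLEEP] * 8 + [WAKE] * 16)
    template = np.tile(day, 7)
    means = []
    for flip_p in [0.0, 0.1, 0.25, 0.4, 0.5]:
        scores = []
        for _ in range(150):
            noisy = template.copy()
            flips = rng.random(template.size) < flip_p
            noisy[flips] = 1 - noisy[flips]
            scores.append(compute_sri(make_series(noisy),
                                      validity_threshold_hours=0.0).sri_raw)
        means.append(np.mean(scores))
    diffs = np.diff(means)
    assert (diffs <= 1.0).all()  # non-increasing up to Monte-Carlo noise
    assert means[0] == 100.0 and means[-1] < 10.0
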