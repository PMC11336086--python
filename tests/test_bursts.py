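"""Burst detection, merging, overuse classification, concordance."""

from statistics import mean

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sabaflow import bursts


def burst_day_oracle(counts, min_mean=3.0, baseline_days=14):
    """Literal re-statement of the rule with list slicing, 1-based days.

    Counts are coerced to plain Python numbers: statistics.mean silently
    truncates when fed numpy integer scalars.
    """
    c = [float(x) for x in counts]
    flagged = []
    for d in range(1, len(c) + 1):
        if d < 3:
            continue  # needs a previous day and >= 1 baseline day
        two_day = mean([c[d - 2], c[d - 1]])
        baseline = c[max(0, d - 2 - baseline_days) : d - 2]
        if two_day >= min_mean and two_day > mean(baseline):
            flagged.append(d)
    return flagged


def merge_oracle(raw_days, window=7):
    """Recursive onset-anchored partition of raw days."""
    if not raw_days:
        return []
    onset = raw_days[0]
    group = [d for d in raw_days if d - onset <= window]
    rest = [d for d in raw_days if d - onset > window]
    return [(onset, len(group))] + merge_oracle(rest, window)


def test_isolated_spike_flagged():
    counts = np.zeros(30)
    counts[9:11] = 4  # days 10 and 11
    assert bursts.detect_raw_burst_days(counts) == [11]


def test_constant_use_never_bursts():
    """Steady use fails the strict-increase condition no matter how high."""
    assert bursts.detect_raw_burst_days(np.full(84, 4.0)) == []


def test_tie_with_baseline_is_not_burst():
    # 2-day mean equals baseline mean exactly
    counts = np.array([3, 3, 3, 3.0])
    assert bursts.detect_raw_burst_days(counts) == []


def test_detection_matches_oracle_on_random_series():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        n = int(rng.integers(7, 90))
        counts = rng.poisson(rng.uniform(0.2, 4.0), size=n)
        assert bursts.detect_raw_burst_days(counts) == burst_day_oracle(counts)


def test_zero_padding_invariance():
    """Appending zero-use days after the window never changes detections."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        counts = rng.poisson(1.5, size=40)
        base = bursts.detect_raw_burst_days(counts)
        padded = bursts.detect_raw_burst_days(np.concatenate([counts, np.zeros(10)]))
        assert [d for d in padded if d <= 40] == base


def test_merge_examples():
    assert [(b.onset_day, b.merged_from) for b in bursts.merge_bursts([11])] == [(11, 1)]
    merged = bursts.merge_bursts([11, 13, 17, 25])
    assert [(b.onset_day, b.merged_from) for b in merged] == [(11, 3), (25, 1)]
    assert bursts.merge_bursts([]) == []


def test_merge_matches_recursive_oracle():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        raw = sorted(set(rng.integers(1, 85, size=rng.integers(0, 15)).tolist()))
        got = [(b.onset_day, b.merged_from) for b in bursts.merge_bursts(raw)]
        assert got == merge_oracle(raw)


@given(st.sets(st.integers(min_value=1, max_value=120), max_size=20))
@settings(max_examples=200, derandomize=True)
def test_merge_properties(raw_set):
    """Merging shrinks counts, separates onsets by >7 d, and is idempotent."""
    raw = sorted(raw_set)
    merged = bursts.merge_bursts(raw)
    assert len(merged) <= len(raw)
    assert sum(b.merged_from for b in merged) == len(raw)
    onsets = [b.onset_day for b in merged]
    assert all(b - a > 7 for a, b in zip(onsets, onsets[1:]))
    again = bursts.merge_bursts(onsets)
    assert [b.onset_day for b in again] == onsets


def test_burst_stats_recorded():
    counts = np.zeros(30)
    counts[9:11] = 5
    raw, merged = bursts.detect_bursts(counts, patient_id="P1")
    (b,) = merged
    assert b.patient_id == "P1"
    assert b.trigger_mean_2d == 5.0
    assert b.baseline_mean_14d == 0.0
    assert b.trigger_mean_2d >= 3 and b.trigger_mean_2d > b.baseline_mean_14d


def test_overuse_classification():
    steady = np.tile([2, 0, 0, 0, 0, 0, 0], 12)  # 2 per week, every week
    assert bursts.classify_overuse(steady).is_continuous_overuser
    lapsed = steady.copy()
    lapsed[35:42] = 0  # one all-zero week
    assert not bursts.classify_overuse(lapsed).is_continuous_overuser


def test_overuse_ignores_trailing_partial_week():
    counts = np.concatenate([np.tile([1, 1, 0, 0, 0, 0, 0], 4), [0, 0, 0]])
    status = bursts.classify_overuse(counts)
    assert status.weekly_counts == (2, 2, 2, 2)
    assert status.is_continuous_overuser


def test_overuse_needs_a_complete_week():
    with pytest.raises(ValueError, match="week"):
        bursts.classify_overuse(np.array([5, 5, 5]))


def test_zero_use_patient_is_quiet():
    counts = np.zeros(84)
    assert bursts.detect_raw_burst_days(counts) == []
    assert not bursts.classify_overuse(counts).is_continuous_overuser


def test_concordance_window():
    raw = {"P1": [11], "P2": []}
    exac = pd.DataFrame(
        {"patient_id": ["P1", "P1", "P2"], "onset_day": [12, 30, 12]}
    )
    table, frac = bursts.burst_exacerbation_concordance(raw, exac)
    assert list(table["concomitant"]) == [True, False, False]
    assert frac == pytest.approx(1 / 3)


def test_concordance_without_exacerbations():
    table, frac = bursts.burst_exacerbation_concordance(
        {"P1": [5]}, pd.DataFrame(columns=["patient_id", "onset_day"])
    )
    assert len(table) == 0 and np.isnan(frac)


def test_cohort_detection_shapes(small_cohort):
    _, events, patients, _, _ = small_cohort
    from sabaflow import episodes

    series = episodes.daily_counts(events, patients)
    burst_table, overuse_table, raw = bursts.detect_cohort(series)
    assert set(overuse_table["patient_id"]) == set(patients["patient_id"])
    if len(burst_table):
        per_patient = burst_table.groupby("patient_id")["onset_day"].apply(list)
        for days in per_patient:
            assert all(b - a > 7 for a, b in zip(days, days[1:]))
        assert (burst_table["trigger_mean_2d"] >= 3).all()
        assert (
            burst_table["trigger_mean_2d"] > burst_table["baseline_mean_14d"]
        ).all()
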