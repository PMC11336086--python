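"""Episode grouping, daily counts and use-pattern histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sabaflow import episodes
from tests.conftest import make_events


def _events_from_gaps(gaps_s, pid="P1"):
    t = pd.Timestamp("2023-01-01 08:00:00")
    times = [t]
    for g in gaps_s:
        times.append(times[-1] + pd.Timedelta(seconds=g))
    return make_events([(pid, ts, "ok", 60.0) for ts in times])


def grouping_oracle(times, gap_s=60.0):
    """Union-find over consecutive pairs: independent of the chain scan."""
    n = len(times)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(1, n):
        if (times[i] - times[i - 1]).total_seconds() <= gap_s:
            parent[find(i)] = find(i - 1)
    sizes = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return sorted(sizes.values())


def test_chain_rule_examples():
    eps = episodes.group_episodes(_events_from_gaps([30, 30, 120]))
    assert list(eps["n_inhalations"]) == [3, 1]
    single = episodes.group_episodes(_events_from_gaps([]))
    assert list(single["n_inhalations"]) == [1]


def test_boundary_gap_is_inclusive():
    eps = episodes.group_episodes(_events_from_gaps([60, 61]))
    assert list(eps["n_inhalations"]) == [2, 1]


def test_anchor_rule_differs_from_chain():
    # 40+40 s: chained into one episode; anchored splits at 80 s from start
    ev = _events_from_gaps([40, 40])
    assert list(episodes.group_episodes(ev, rule="chain")["n_inhalations"]) == [3]
    assert list(episodes.group_episodes(ev, rule="anchor")["n_inhalations"]) == [2, 1]


def test_unsorted_input_rejected():
    ev = _events_from_gaps([30, 30])
    with pytest.raises(ValueError, match="sorted"):
        episodes.group_episodes(ev.iloc[::-1])


def test_grouping_matches_union_find_oracle():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(1, 40))
        gaps = rng.exponential(90, size=n - 1)
        ev = _events_from_gaps(list(gaps))
        got = sorted(episodes.group_episodes(ev)["n_inhalations"])
        times = list(pd.to_datetime(ev["timestamp"]))
        assert got == grouping_oracle(times)


@given(st.lists(st.floats(min_value=1, max_value=300), max_size=30))
@settings(max_examples=100, derandomize=True)
def test_gap_monotonicity_and_conservation(gaps):
    """More permissive gaps never increase the episode count; sizes conserve events."""
    ev = _events_from_gaps(gaps)
    eps60 = episodes.group_episodes(ev, gap_s=60)
    eps120 = episodes.group_episodes(ev, gap_s=120)
    assert len(eps120) <= len(eps60)
    assert eps60["n_inhalations"].sum() == len(ev)
    assert eps120["n_inhalations"].sum() == len(ev)


def test_episode_size_distribution_hand_counts():
    eps = pd.DataFrame(
        {"patient_id": "P1", "start": pd.Timestamp("2023-01-01"), "end": pd.Timestamp("2023-01-01"), "n_inhalations": [1] * 5 + [2] * 3 + [3] + [5]}
    )
    dist = episodes.episode_size_distribution(eps).set_index("episode_size")
    # 19 events total: 5 singles, 6 in pairs, 3 in a triple, 5 in a >4
    assert dist.loc["1", "percent_of_events"] == pytest.approx(100 * 5 / 19)
    assert dist.loc["2", "percent_of_events"] == pytest.approx(100 * 6 / 19)
    assert dist.loc["3", "percent_of_events"] == pytest.approx(100 * 3 / 19)
    assert dist.loc["4", "percent_of_events"] == 0.0
    assert dist.loc[">4", "percent_of_events"] == pytest.approx(100 * 5 / 19)
    assert dist["percent_of_events"].sum() == pytest.approx(100.0)


def test_size_distribution_small_cases():
    eps = pd.DataFrame({"n_inhalations": [1, 1, 2]})
    dist = episodes.episode_size_distribution(eps).set_index("episode_size")
    assert dist.loc["1", "percent_of_events"] == 50.0
    assert dist.loc["2", "percent_of_events"] == 50.0
    allsingle = episodes.episode_size_distribution(pd.DataFrame({"n_inhalations": [1, 1]}))
    assert allsingle.set_index("episode_size").loc["1", "percent_of_events"] == 100.0


def test_daily_counts_zero_filled():
    patients = pd.DataFrame(
        {"patient_id": ["P1"], "enroll_date": ["2023-01-01"], "end_date": ["2023-01-03"]}
    )
    ev = make_events(
        [
            ("P1", "2023-01-02 08:00:00", "ok", 60.0),
            ("P1", "2023-01-02 20:00:00", "no_flow", None),
        ]
    )
    series = episodes.daily_counts(ev, patients)
    assert list(series["count"]) == [0, 2, 0]
    assert list(series["day_index"]) == [1, 2, 3]


def test_daily_counts_empty_events():
    patients = pd.DataFrame(
        {"patient_id": ["P1", "P2"], "enroll_date": ["2023-01-01"] * 2, "end_date": ["2023-01-05"] * 2}
    )
    series = episodes.daily_counts(make_events([]).iloc[0:0], patients)
    assert len(series) == 10 and series["count"].sum() == 0


def test_event_outside_window_rejected():
    patients = pd.DataFrame(
        {"patient_id": ["P1"], "enroll_date": ["2023-01-02"], "end_date": ["2023-01-03"]}
    )
    ev = make_events([("P1", "2023-01-01 08:00:00", "ok", 60.0)])
    with pytest.raises(ValueError, match="outside"):
        episodes.daily_counts(ev, patients)


def test_daily_counts_conservation(small_cohort):
    """Sum of daily counts equals the event count; days equal window lengths."""
    _, events, patients, _, _ = small_cohort
    series = episodes.daily_counts(events, patients)
    assert series["count"].sum() == len(events)
    windows = (
        pd.to_datetime(patients["end_date"]) - pd.to_datetime(patients["enroll_date"])
    ).dt.days + 1
    assert len(series) == windows.sum()


def test_use_histogram_hand_counts():
    series = pd.DataFrame({"patient_id": "P1", "day_index": [1, 2, 3, 4], "count": [0, 0, 1, 2]})
    hist = episodes.use_histogram(series).set_index("inhalations_per_day")
    assert hist.loc["0", "percent_of_days"] == 50.0
    assert hist.loc["1", "percent_of_days"] == 25.0
    assert hist.loc["2", "percent_of_days"] == 25.0
    assert hist["percent_of_days"].sum() == pytest.approx(100.0)
    allzero = episodes.use_histogram(pd.DataFrame({"count": [0, 0, 0]}))
    assert allzero.set_index("inhalations_per_day").loc["0", "percent_of_days"] == 100.0
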