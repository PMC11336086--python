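"""Window medians, the paired signed-rank contrast and rolling medians."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from sabaflow import event_qc, trends
from sabaflow.synthetic import SyntheticCohortSpec, generate_cohort
from tests.conftest import make_events


def exact_wilcoxon_oracle(diffs):
    """Two-tailed signed-rank p by full enumeration of sign assignments.

    Zero differences dropped; assumes no ties among |diffs| (the exact
    regime).  Independent of any library routine.
    """
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_plus = ranks[d > 0].sum()
    totals = []
    for signs in product([0, 1], repeat=n):
        totals.append(sum(r for r, s in zip(ranks, signs) if s))
    totals = np.asarray(totals)
    p_le = np.mean(totals <= w_plus)
    p_ge = np.mean(totals >= w_plus)
    return min(1.0, 2 * min(p_le, p_ge))


def test_wilcoxon_matches_enumeration_oracle():
    """Signed-rank p agrees with brute-force enumeration on 100 random sets."""
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 100:
        n = int(rng.integers(4, 12))
        d = np.round(rng.normal(0.3, 1.0, size=n), 3)
        d = d[d != 0]
        if len(np.unique(np.abs(d))) != len(d) or len(d) == 0:
            continue
        assert trends.wilcoxon_signed_rank(d) == pytest.approx(
            exact_wilcoxon_oracle(d), abs=1e-12
        )
        checked += 1


def test_wilcoxon_degenerate_and_symmetry():
    assert trends.wilcoxon_signed_rank(np.zeros(10)) == 1.0
    # antisymmetric differences: W+ is at the centre of the null
    p = trends.wilcoxon_signed_rank(np.array([1.0, -1.5, 2.0, -2.5, 0.5, -0.7]))
    assert p > 0.5


def _window_fixture():
    patients = pd.DataFrame(
        {
            "patient_id": ["P1", "P2"],
            "enroll_date": ["2023-01-01", "2023-01-05"],
            "end_date": ["2023-03-25", "2023-03-29"],  # 84-day windows
        }
    )
    rows = []
    # P1: pif 80 on day 2, pif 60 on final day; P2: single event in window 1
    rows.append(("P1", "2023-01-02 08:00:00", "ok", 80.0))
    rows.append(("P1", "2023-03-25 08:00:00", "ok", 60.0))
    rows.append(("P2", "2023-01-06 08:00:00", "ok", 70.0))
    return make_events(rows), patients


def test_window_medians_membership_and_values():
    events, patients = _window_fixture()
    first = trends.window_medians(events, patients, "first")
    last = trends.window_medians(events, patients, "last")
    assert set(first["patient_id"]) == {"P1", "P2"}
    assert set(last["patient_id"]) == {"P1"}
    assert first.set_index("patient_id").loc["P1", "pif_lpm"] == 80.0
    assert last.set_index("patient_id").loc["P1", "pif_lpm"] == 60.0


def test_paired_trend_hand_values():
    events, patients = _window_fixture()
    first = trends.window_medians(events, patients, "first")
    last = trends.window_medians(events, patients, "last")
    table = trends.paired_trend_test(first, last).set_index("parameter")
    row = table.loc["pif_lpm"]
    assert row["n_patients"] == 1  # only P1 is in both windows
    assert row["median_of_differences"] == 20.0  # first - last, decline positive
    assert row["median_pct_change"] == pytest.approx(-25.0)
    assert not row["p_reliable"]


def test_all_zero_differences():
    med = pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3", "P4", "P5", "P6"],
            "pif_lpm": 70.0,
            "volume_l": 1.2,
            "duration_s": 1.3,
            "time_to_pif_s": 0.4,
        }
    )
    table = trends.paired_trend_test(med, med).set_index("parameter")
    assert (table["median_of_differences"] == 0).all()
    assert (table["p_value"] == 1.0).all()
    assert table["p_reliable"].all()


def test_rolling_medians_flat_patient():
    patients = pd.DataFrame(
        {"patient_id": ["P1"], "enroll_date": ["2023-01-01"], "end_date": ["2023-03-25"]}
    )
    rows = [
        ("P1", f"2023-01-01 08:00:00", "ok", 70.0),
    ]
    rows += [
        ("P1", (pd.Timestamp("2023-01-01 09:00:00") + pd.Timedelta(days=d)).isoformat(), "ok", 70.0)
        for d in range(0, 84, 5)
    ]
    series = trends.rolling_medians(make_events(rows), patients, "10-day")
    assert (series["pif_lpm"] == 70.0).all()
    assert series["n_events"].sum() == len(rows)


def test_rolling_medians_excludes_short_observation():
    patients = pd.DataFrame(
        {
            "patient_id": ["P1", "P2"],
            "enroll_date": ["2023-01-01", "2023-01-01"],
            "end_date": ["2023-03-25", "2023-03-01"],  # P2 observed 60 days
        }
    )
    rows = [
        ("P1", "2023-01-02 08:00:00", "ok", 80.0),
        ("P2", "2023-01-02 08:00:00", "ok", 30.0),
    ]
    series = trends.rolling_medians(make_events(rows), patients, "10-day")
    assert (series["pif_lpm"] == 80.0).all()  # P2's events are excluded


def test_decline_recovery_small_cohort():
    """A generated decline reappears in the paired trend at small scale."""
    spec = SyntheticCohortSpec(n_patients=80, seed=3, frac_short_observation=0.0)
    events, patients, _, _ = generate_cohort(spec)
    flow, _ = event_qc.filter_flow_analyzable(events)
    first = trends.window_medians(flow, patients, "first")
    last = trends.window_medians(flow, patients, "last")
    table = trends.paired_trend_test(first, last).set_index("parameter")
    # all four parameters decline; heaviest configured declines test smallest p
    assert (table["median_pct_change"] < 0).all()
    assert table.loc["volume_l", "p_value"] < 1e-3
    assert table.loc["duration_s", "p_value"] < 1e-3
    assert (
        table.loc["duration_s", "median_pct_change"]
        < table.loc["pif_lpm", "median_pct_change"]
    )


def test_normality_check():
    rng = np.random.default_rng(8)
    lognorm = np.exp(rng.normal(0, 0.5, size=10_000))
    stat, p = trends.normality_check(lognorm)
    assert p < 1e-4
    normal = rng.normal(5, 2, size=10_000)
    _, p_null = trends.normality_check(normal)
    assert p_null > 0.05
    with pytest.raises(ValueError):
        trends.normality_check(np.ones(100))
    with pytest.raises(ValueError):
        trends.normality_check(np.arange(5))
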