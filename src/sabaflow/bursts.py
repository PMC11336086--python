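"""SABA-burst detection and continuous-overuse classification.

Acute short-term high reliever use ("SABA burst"): a day is a raw burst
day when the mean daily inhalation count over the last two days (the day
and the day before) is at least three AND strictly exceeds the mean over
the previous two weeks.  Raw detections within a 7-day period collapse
into a single burst.

Continuous SABA overuse: at least two reliever inhalations in every
7-day block of the observation period (blocks anchored at enrollment;
a trailing partial block is ignored).

Both rules operate on zero-filled daily-count series (see
:mod:`sabaflow.episodes`).  Day indices are 1-based study days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_2DAY_MEAN = 3.0
BASELINE_DAYS = 14
MERGE_WINDOW_DAYS = 7
OVERUSE_WEEKLY_MIN = 2


@dataclass(frozen=True)
class Burst:
    """One merged burst of acute reliever use.

    ``onset_day`` is the earliest raw detection day of the group (the
    second day of its 2-day trigger window); ``merged_from`` counts the
    raw detections collapsed into this burst.
    """

    patient_id: str
    onset_day: int
    trigger_mean_2d: float
    baseline_mean_14d: float
    merged_from: int


@dataclass(frozen=True)
class OveruseStatus:
    patient_id: str
    is_continuous_overuser: bool
    weekly_counts: tuple[int, ...]


def _check_series(counts: np.ndarray, day_index: np.ndarray | None) -> np.ndarray:
    counts = np.asarray(counts)
    if day_index is not None:
        day_index = np.asarray(day_index)
        expected = np.arange(1, len(counts) + 1)
        if not np.array_equal(day_index, expected):
            raise ValueError("daily series must be gap-free and 1-based")
    if (counts < 0).any():
        raise ValueError("daily counts must be nonnegative")
    return counts.astype(float)


def detect_raw_burst_days(
    counts: np.ndarray,
    day_index: np.ndarray | None = None,
    min_2day_mean: float = MIN_2DAY_MEAN,
    baseline_days: int = BASELINE_DAYS,
) -> list[int]:
    """Raw burst days of one patient's zero-filled daily series.

    Day ``d`` (1-based) is flagged iff ``mean(count[d-1], count[d]) >=
    min_2day_mean`` and this 2-day mean strictly exceeds the mean over
    the ``baseline_days`` days preceding the 2-day window, truncated at
    study start.  At least one baseline day is required, so the earliest
    evaluable day is day 3 of the study.  Ties with the baseline are not
    bursts.
    """
    c = _check_series(counts, day_index)
    flagged = []
    for d in range(3, len(c) + 1):
        sum2 = c[d - 2] + c[d - 1]
        if sum2 < 2.0 * min_2day_mean:
            continue
        lo = max(0, d - 2 - baseline_days)
        baseline = c[lo : d - 2]
        # strict-increase tie-break must be exact: compare cross-multiplied
        # sums rather than divided means, so integer counts never tie-break
        # on float rounding
        if sum2 * len(baseline) > 2.0 * baseline.sum():
            flagged.append(d)
    return flagged


def merge_bursts(
    raw_days: list[int],
    counts: np.ndarray | None = None,
    merge_window_days: int = MERGE_WINDOW_DAYS,
    patient_id: str = "",
    baseline_days: int = BASELINE_DAYS,
    mode: str = "onset",
) -> list[Burst]:
    """Collapse raw burst days within a 7-day period into single bursts.

    Greedy left-to-right: the first raw day opens a burst; under the
    default ``onset`` mode a later raw day merges when it lies within
    ``merge_window_days`` of the burst's onset; under ``chain`` mode,
    within ``merge_window_days`` of the most recent merged day.  The
    burst onset is the earliest raw detection day of the group.

    When ``counts`` is given, the trigger and baseline means of the
    opening raw day are recorded on the burst.
    """
    if mode not in ("onset", "chain"):
        raise ValueError(f"unknown merge mode {mode!r}")
    if sorted(raw_days) != list(raw_days):
        raise ValueError("raw_days must be sorted")
    bursts: list[Burst] = []
    group_first: int | None = None
    group_last: int | None = None
    group_n = 0

    def _close() -> None:
        d = group_first
        if counts is not None:
            c = np.asarray(counts, dtype=float)
            trig = (c[d - 2] + c[d - 1]) / 2.0
            lo = max(0, d - 2 - baseline_days)
            base = float(c[lo : d - 2].mean())
        else:
            trig, base = float("nan"), float("nan")
        bursts.append(
            Burst(
                patient_id=patient_id,
                onset_day=d,
                trigger_mean_2d=trig,
                baseline_mean_14d=base,
                merged_from=group_n,
            )
        )

    for day in raw_days:
        if group_first is None:
            group_first, group_last, group_n = day, day, 1
            continue
        anchor = group_first if mode == "onset" else group_last
        if day - anchor <= merge_window_days:
            group_last = day
            group_n += 1
        else:
            _close()
            group_first, group_last, group_n = day, day, 1
    if group_first is not None:
        _close()
    return bursts


def detect_bursts(
    counts: np.ndarray,
    patient_id: str = "",
    min_2day_mean: float = MIN_2DAY_MEAN,
    baseline_days: int = BASELINE_DAYS,
    merge_window_days: int = MERGE_WINDOW_DAYS,
    merge_mode: str = "onset",
) -> tuple[list[int], list[Burst]]:
    """Raw detection followed by merging, for one patient."""
    raw = detect_raw_burst_days(
        counts, min_2day_mean=min_2day_mean, baseline_days=baseline_days
    )
    merged = merge_bursts(
        raw,
        counts=counts,
        merge_window_days=merge_window_days,
        patient_id=patient_id,
        baseline_days=baseline_days,
        mode=merge_mode,
    )
    return raw, merged


def classify_overuse(
    counts: np.ndarray,
    patient_id: str = "",
    weekly_min: int = OVERUSE_WEEKLY_MIN,
) -> OveruseStatus:
    """Continuous-overuse status from a zero-filled daily series.

    Weeks are consecutive 7-day blocks from study day 1; only complete
    blocks count.  The patient is a continuous overuser iff every
    complete week has at least ``weekly_min`` inhalations.
    """
    c = _check_series(np.asarray(counts), None)
    n_weeks = len(c) // 7
    if n_weeks == 0:
        raise ValueError("series shorter than 7 days: no complete week")
    weekly = tuple(int(c[7 * w : 7 * (w + 1)].sum()) for w in range(n_weeks))
    return OveruseStatus(
        patient_id=patient_id,
        is_continuous_overuser=min(weekly) >= weekly_min,
        weekly_counts=weekly,
    )


def detect_cohort(
    series: pd.DataFrame,
    min_2day_mean: float = MIN_2DAY_MEAN,
    baseline_days: int = BASELINE_DAYS,
    merge_window_days: int = MERGE_WINDOW_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[int]]]:
    """Run burst detection and overuse classification per patient.

    ``series`` is a zero-filled cohort daily-count table (patient_id,
    day_index, count).  Returns a bursts table, an overuse table and the
    raw burst days per patient.
    """
    burst_rows = []
    overuse_rows = []
    raw_by_patient: dict[str, list[int]] = {}
    for pid, grp in series.groupby("patient_id", sort=True):
        grp = grp.sort_values("day_index")
        counts = grp["count"].to_numpy()
        _check_series(counts, grp["day_index"].to_numpy())
        raw, merged = detect_bursts(
            counts,
            patient_id=pid,
            min_2day_mean=min_2day_mean,
            baseline_days=baseline_days,
            merge_window_days=merge_window_days,
        )
        raw_by_patient[pid] = raw
        for b in merged:
            burst_rows.append(
                {
                    "patient_id": b.patient_id,
                    "onset_day": b.onset_day,
                    "trigger_mean_2d": b.trigger_mean_2d,
                    "baseline_mean_14d": b.baseline_mean_14d,
                    "merged_from": b.merged_from,
                }
            )
        status = classify_overuse(counts, patient_id=pid)
        overuse_rows.append(
            {
                "patient_id": pid,
                "is_continuous_overuser": status.is_continuous_overuser,
                "min_weekly_count": min(status.weekly_counts),
            }
        )
    bursts = pd.DataFrame(
        burst_rows,
        columns=[
            "patient_id",
            "onset_day",
            "trigger_mean_2d",
            "baseline_mean_14d",
            "merged_from",
        ],
    )
    overuse = pd.DataFrame(
        overuse_rows, columns=["patient_id", "is_continuous_overuser", "min_weekly_count"]
    )
    return bursts, overuse, raw_by_patient


def burst_exacerbation_concordance(
    raw_by_patient: dict[str, list[int]],
    exacerbations: pd.DataFrame,
    window_days: int = 7,
) -> tuple[pd.DataFrame, float]:
    """Fraction of exacerbations concomitant with a burst.

    An exacerbation is concomitant when its onset study day lies within
    +/- ``window_days`` of any raw burst day of the same patient.
    ``exacerbations`` must carry patient_id and onset_day (study-day
    index).  Returns the per-exacerbation table and the overall
    fraction (NaN when there are no exacerbations).
    """
    rows = []
    for _, ex in exacerbations.iterrows():
        pid = ex["patient_id"]
        onset = int(ex["onset_day"])
        raw = raw_by_patient.get(pid, [])
        concomitant = any(abs(onset - d) <= window_days for d in raw)
        rows.append(
            {"patient_id": pid, "onset_day": onset, "concomitant": concomitant}
        )
    table = pd.DataFrame(rows, columns=["patient_id", "onset_day", "concomitant"])
    frac = float(table["concomitant"].mean()) if len(table) else float("nan")
    return table, frac
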