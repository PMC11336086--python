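"""Inhalation-parameter trends over the observation period.

Inhalation parameters fluctuate day to day within a patient, so the
primary trend contrast aggregates each patient's flow-analyzable events
into two 10-day windows — study days 1-10 and the final 10 days of that
patient's own observation — and compares the per-patient medians with a
two-tailed Wilcoxon signed-rank test.  Cohort-level time courses (daily
or 10-day bins) instead pool events across patients, restricted to
patients observed for at least 70 days so late bins are not dominated by
dropouts.

Two summaries of change are reported with opposite sign conventions,
both deliberately: the median of per-patient differences (first - last;
positive when a parameter declines) and the median per-patient
percentage change ((last - first)/first * 100; negative when it
declines).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

PARAMETERS = ("pif_lpm", "volume_l", "duration_s", "time_to_pif_s")

WINDOW_DAYS = 10
MIN_OBSERVATION_DAYS = 70
MIN_PAIRS_FOR_TEST = 6


def _study_day(events: pd.DataFrame, patients: pd.DataFrame) -> pd.Series:
    pat = patients.set_index("patient_id")
    enroll = pd.to_datetime(pat["enroll_date"])
    ts = pd.to_datetime(events["timestamp"]).dt.normalize()
    enrolled = events["patient_id"].map(enroll)
    return (ts - enrolled).dt.days + 1


def _observation_days(patients: pd.DataFrame) -> pd.Series:
    enroll = pd.to_datetime(patients["enroll_date"])
    end = pd.to_datetime(patients["end_date"])
    return pd.Series(
        (end - enroll).dt.days.to_numpy() + 1, index=patients["patient_id"].to_numpy()
    )


def window_medians(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    window: str,
    window_days: int = WINDOW_DAYS,
) -> pd.DataFrame:
    """Per-patient parameter medians over the first or last 10 days.

    ``events`` must already be flow-filtered (18 <= PIF < 120).  The
    first window is study days 1..window_days; the last window is the
    final ``window_days`` of each patient's own observation.  Patients
    with no in-window events are omitted.
    """
    if window not in ("first", "last"):
        raise ValueError(f"window must be 'first' or 'last', got {window!r}")
    day = _study_day(events, patients)
    obs = _observation_days(patients)
    if window == "first":
        in_window = day <= window_days
    else:
        last_start = events["patient_id"].map(obs) - window_days + 1
        in_window = day >= last_start
    sub = events.loc[in_window]
    grouped = sub.groupby("patient_id")
    out = grouped[list(PARAMETERS)].median()
    out["n_events"] = grouped.size()
    out.insert(0, "window", window)
    return out.reset_index()


def _iqr(values: np.ndarray) -> float:
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def wilcoxon_signed_rank(diffs: np.ndarray) -> float:
    """Two-tailed Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped (classic convention); the exact null
    distribution is used for n <= 25 without ties in |diff|, and the
    tie-corrected normal approximation otherwise.  Returns 1.0 when all
    differences are zero (no evidence of shift).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks_unique = len(np.unique(np.abs(d))) == len(d)
    method = "exact" if (d.size <= 25 and ranks_unique) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=False, method=method)
    return float(res.pvalue)


def paired_trend_test(
    first: pd.DataFrame,
    last: pd.DataFrame,
    min_pairs: int = MIN_PAIRS_FOR_TEST,
) -> pd.DataFrame:
    """Paired first-vs-last window contrast, one row per parameter.

    Restricted to patients present in both window tables.  Reports the
    cohort medians of patient medians, the median and IQR of per-patient
    differences (first - last), the signed-rank p-value, and the median
    per-patient percentage change.  With fewer than ``min_pairs``
    patients the p-value is flagged unreliable.
    """
    merged = first.merge(last, on="patient_id", suffixes=("_first", "_last"))
    n = len(merged)
    rows = []
    for param in PARAMETERS:
        f = merged[f"{param}_first"].to_numpy(dtype=float)
        l = merged[f"{param}_last"].to_numpy(dtype=float)
        diffs = f - l
        pct = (l - f) / f * 100.0
        rows.append(
            {
                "parameter": param,
                "n_patients": n,
                "cohort_median_first": float(np.median(f)) if n else np.nan,
                "cohort_median_last": float(np.median(l)) if n else np.nan,
                "median_of_differences": float(np.median(diffs)) if n else np.nan,
                "iqr_of_differences": _iqr(diffs) if n else np.nan,
                "p_value": wilcoxon_signed_rank(diffs) if n else np.nan,
                "p_reliable": n >= min_pairs,
                "median_pct_change": float(np.median(pct)) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def rolling_medians(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    bin: str = "10-day",
    min_observation_days: int = MIN_OBSERVATION_DAYS,
) -> pd.DataFrame:
    """Cohort median time course per parameter, pooling events per bin.

    ``bin`` is "daily" or "10-day" (consecutive study-day blocks).
    Patients observed for fewer than ``min_observation_days`` days are
    excluded entirely.  Returns one row per bin with the event count and
    the pooled-event median of each parameter.
    """
    if bin not in ("daily", "10-day"):
        raise ValueError(f"bin must be 'daily' or '10-day', got {bin!r}")
    obs = _observation_days(patients)
    keep_patients = obs.index[obs >= min_observation_days]
    ev = events.loc[events["patient_id"].isin(keep_patients)].copy()
    day = _study_day(ev, patients)
    width = 1 if bin == "daily" else 10
    ev["bin_start_day"] = ((day - 1) // width) * width + 1
    grouped = ev.groupby("bin_start_day")
    out = grouped[list(PARAMETERS)].median()
    out["n_events"] = grouped.size()
    return out.reset_index()


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    Tests the sample against a normal with the sample's own mean and SD;
    reported for distribution documentation, not used as an analysis
    gate.  Requires n >= 10 and nonzero spread.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError(f"need at least 10 values, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) input")
    stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(stat), float(p)
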