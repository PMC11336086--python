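"""Use occasions and daily-count series.

Reliever inhalers are often actuated several times in quick succession
(one "puff" per actuation); a run of consecutive inhalations separated
by at most 60 seconds is treated as a single use occasion, or episode.
Episode grouping uses all recorded device events by default — including
no-flow cap-opens and vent-block artifacts — because use-pattern
summaries describe actuation behaviour, not inhalation quality.

Daily counts are calendar-day actuation totals over each patient's full
observation window, zero-filled so that days without use are explicit.
Study day 1 is the enrollment date.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_GAP_S = 60.0

#: Episode-size reporting categories.
SIZE_CATEGORIES = ("1", "2", "3", "4", ">4")


def group_episodes(
    events: pd.DataFrame,
    gap_s: float = DEFAULT_GAP_S,
    rule: str = "chain",
) -> pd.DataFrame:
    """Group each patient's events into episodes.

    Under the default ``chain`` rule an event joins the current episode
    iff its gap to the *previous event* is <= ``gap_s``; under the
    ``anchor`` rule the gap is measured to the episode's *first* event.
    Events must be sorted by timestamp within each patient.

    Returns one row per episode: patient_id, start, end, n_inhalations.
    """
    if rule not in ("chain", "anchor"):
        raise ValueError(f"unknown grouping rule {rule!r}")
    out = []
    for pid, grp in events.groupby("patient_id", sort=True):
        ts = pd.to_datetime(grp["timestamp"]).to_numpy()
        if len(ts) > 1 and (np.diff(ts) < np.timedelta64(0, "s")).any():
            raise ValueError(f"events for patient {pid!r} are not sorted by timestamp")
        gap = np.timedelta64(int(round(gap_s * 1e9)), "ns")
        start_idx = 0
        for i in range(1, len(ts) + 1):
            if i < len(ts):
                ref = ts[i - 1] if rule == "chain" else ts[start_idx]
                if ts[i] - ref <= gap:
                    continue
            out.append(
                {
                    "patient_id": pid,
                    "start": pd.Timestamp(ts[start_idx]),
                    "end": pd.Timestamp(ts[i - 1]),
                    "n_inhalations": i - start_idx,
                }
            )
            start_idx = i
    return pd.DataFrame(out, columns=["patient_id", "start", "end", "n_inhalations"])


def episode_size_distribution(episodes: pd.DataFrame) -> pd.DataFrame:
    """Share of *events* occurring in episodes of size 1, 2, 3, 4, >4.

    Percentages weight each episode by its size, so they are fractions
    of inhalation events (not of episodes) and sum to 100 up to
    rounding.
    """
    sizes = episodes["n_inhalations"].to_numpy(dtype=int) if len(episodes) else np.array([], dtype=int)
    total_events = int(sizes.sum())
    rows = []
    for cat in SIZE_CATEGORIES:
        if cat == ">4":
            events_in_cat = int(sizes[sizes > 4].sum())
            n_episodes = int((sizes > 4).sum())
        else:
            k = int(cat)
            n_episodes = int((sizes == k).sum())
            events_in_cat = k * n_episodes
        rows.append(
            {
                "episode_size": cat,
                "n_episodes": n_episodes,
                "n_events": events_in_cat,
                "percent_of_events": 100.0 * events_in_cat / total_events
                if total_events
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def daily_counts(events: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Zero-filled per-patient calendar-day event counts.

    One row per (patient, study day) over the patient's observation
    window [enroll_date, end_date]; ``day_index`` is 1-based from
    enrollment.  An event falling outside its patient's window is an
    error.
    """
    pat = patients.set_index("patient_id")
    enroll = pd.to_datetime(pat["enroll_date"])
    end = pd.to_datetime(pat["end_date"])
    frames = []
    counts_by_patient = {}
    if len(events):
        ts = pd.to_datetime(events["timestamp"])
        day = ts.dt.normalize()
        ev = pd.DataFrame({"patient_id": events["patient_id"].to_numpy(), "day": day.to_numpy()})
        for pid, grp in ev.groupby("patient_id", sort=False):
            if pid not in pat.index:
                raise ValueError(f"event for unknown patient {pid!r}")
            idx = (grp["day"] - enroll[pid]).dt.days + 1
            n_days = (end[pid] - enroll[pid]).days + 1
            if (idx < 1).any() or (idx > n_days).any():
                raise ValueError(
                    f"event outside observation window for patient {pid!r}"
                )
            counts_by_patient[pid] = idx.value_counts()
    for pid in pat.index:
        n_days = (end[pid] - enroll[pid]).days + 1
        series = np.zeros(n_days, dtype=int)
        if pid in counts_by_patient:
            vc = counts_by_patient[pid]
            series[vc.index.to_numpy() - 1] = vc.to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "day_index": np.arange(1, n_days + 1),
                    "count": series,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "day_index", "count"])
    return pd.concat(frames, ignore_index=True)


def use_histogram(series: pd.DataFrame, max_category: int = 6) -> pd.DataFrame:
    """Distribution of daily counts over patient-days.

    Categories 0, 1, ..., ``max_category - 1`` and ``>=max_category``;
    percentages are of total patient-days and sum to 100 up to rounding.
    """
    counts = series["count"].to_numpy(dtype=int) if len(series) else np.array([], dtype=int)
    total = counts.size
    rows = []
    for k in range(max_category):
        n = int((counts == k).sum())
        rows.append(
            {
                "inhalations_per_day": str(k),
                "n_patient_days": n,
                "percent_of_days": 100.0 * n / total if total else 0.0,
            }
        )
    n = int((counts >= max_category).sum())
    rows.append(
        {
            "inhalations_per_day": f">={max_category}",
            "n_patient_days": n,
            "percent_of_days": 100.0 * n / total if total else 0.0,
        }
    )
    return pd.DataFrame(rows)


def mean_inhalations_per_patient_day(series: pd.DataFrame) -> float:
    """Total events divided by total patient-days."""
    if not len(series):
        return float("nan")
    return float(series["count"].sum() / len(series))
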