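"""Readers, writers, configuration and the end-to-end pipeline driver.

All tables travel as flat UTF-8 CSV with ISO-8601 timestamps.  Readers
validate row by row and collect every problem with its line number
before failing, so a malformed export is reported once, completely.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bursts as bursts_mod
from . import cohort_stats, episodes, event_qc, trends
from .synthetic import (
    SyntheticCohortSpec,
    exacerbation_study_days,
    generate_cohort,
    write_ground_truth,
)

logger = logging.getLogger("sabaflow")

EVENT_COLUMNS = [
    "patient_id",
    "device_id",
    "timestamp",
    "status",
    "pif_lpm",
    "volume_l",
    "duration_s",
    "time_to_pif_s",
]


class ValidationError(ValueError):
    """Raised when an input table fails validation; carries row errors."""

    def __init__(self, path, problems: list[str]):
        self.problems = problems
        preview = "\n".join(problems[:20])
        more = f"\n... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(f"{path}: {len(problems)} invalid rows\n{preview}{more}")


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis, with study defaults."""

    out_dir: Path = Path("results")
    flow_floor: float = event_qc.FLOW_FLOOR
    flow_ceiling: float = event_qc.FLOW_CEILING
    episode_gap_s: float = episodes.DEFAULT_GAP_S
    burst_min_2day_mean: float = bursts_mod.MIN_2DAY_MEAN
    burst_baseline_days: int = bursts_mod.BASELINE_DAYS
    burst_merge_window_days: int = bursts_mod.MERGE_WINDOW_DAYS
    overuse_weekly_min: int = bursts_mod.OVERUSE_WEEKLY_MIN
    trend_window_days: int = trends.WINDOW_DAYS
    min_observation_days: int = trends.MIN_OBSERVATION_DAYS
    concordance_window_days: int = 7
    spec: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)

    def __post_init__(self) -> None:
        if self.flow_floor <= 0 or self.flow_ceiling <= self.flow_floor:
            raise ValueError("need 0 < flow_floor < flow_ceiling")
        for name in (
            "episode_gap_s",
            "burst_min_2day_mean",
            "burst_baseline_days",
            "burst_merge_window_days",
            "overuse_weekly_min",
            "trend_window_days",
            "min_observation_days",
            "concordance_window_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def read_events(path) -> pd.DataFrame:
    """Read and validate an event-log CSV.

    Checks the schema, timestamp parseability, status values, parameter
    sign and the sensor-floor rule, then returns the table sorted by
    (patient_id, timestamp).
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "device_id": str, "status": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(path, [f"missing columns: {missing}"])
    problems = []
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    for i in df.index[ts.isna()]:
        problems.append(f"line {i + 2}: unparseable timestamp {df.at[i, 'timestamp']!r}")
    bad_status = ~df["status"].isin(event_qc.STATUSES)
    for i in df.index[bad_status]:
        problems.append(f"line {i + 2}: unknown status {df.at[i, 'status']!r}")
    for col in ("pif_lpm", "volume_l", "duration_s", "time_to_pif_s"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & (vals < 0)
        for i in df.index[bad]:
            problems.append(f"line {i + 2}: negative {col} = {df.at[i, col]}")
        df[col] = vals
    ok_rows = df["status"] == event_qc.STATUS_OK
    no_pif = ok_rows & df["pif_lpm"].isna()
    for i in df.index[no_pif]:
        problems.append(f"line {i + 2}: status 'ok' without a recorded PIF")
    sub_floor = ok_rows & (df["pif_lpm"] < event_qc.FLOW_FLOOR)
    for i in df.index[sub_floor]:
        problems.append(
            f"line {i + 2}: status 'ok' with PIF {df.at[i, 'pif_lpm']} below the "
            f"{event_qc.FLOW_FLOOR} L/min sensor floor"
        )
    if problems:
        raise ValidationError(path, problems)
    df["timestamp"] = ts
    return df.sort_values(["patient_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    problems = []
    for col in ("enroll_date", "end_date"):
        parsed = pd.to_datetime(df[col], errors="coerce")
        for i in df.index[parsed.isna()]:
            problems.append(f"line {i + 2}: unparseable {col} {df.at[i, col]!r}")
        df[col] = parsed
    if not problems:
        bad = df["end_date"] < df["enroll_date"]
        for i in df.index[bad]:
            problems.append(f"line {i + 2}: end_date before enroll_date")
        if df["patient_id"].duplicated().any():
            problems.append("duplicate patient_id values")
    if problems:
        raise ValidationError(path, problems)
    return df


def read_exacerbations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "severity": str})
    problems = []
    parsed = pd.to_datetime(df["onset_date"], errors="coerce")
    for i in df.index[parsed.isna()]:
        problems.append(f"line {i + 2}: unparseable onset_date {df.at[i, 'onset_date']!r}")
    bad = ~df["severity"].isin(("moderate", "severe"))
    for i in df.index[bad]:
        problems.append(f"line {i + 2}: unknown severity {df.at[i, 'severity']!r}")
    if problems:
        raise ValidationError(path, problems)
    df["onset_date"] = parsed
    return df


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    ts = pd.to_datetime(out["timestamp"])
    out["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def simulate_to_dir(spec: SyntheticCohortSpec, out_dir) -> dict[str, Path]:
    """Generate a cohort and persist all four tables under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events, patients, exacerbations, truth = generate_cohort(spec)
    paths = {
        "events": out_dir / "events.csv",
        "patients": out_dir / "patients.csv",
        "exacerbations": out_dir / "exacerbations.csv",
        "ground_truth": out_dir / "ground_truth.csv",
    }
    events.to_csv(paths["events"], index=False)
    patients.to_csv(paths["patients"], index=False)
    exacerbations.to_csv(paths["exacerbations"], index=False)
    write_ground_truth(truth, paths["ground_truth"])
    return paths


def run_pipeline(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    exacerbations: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> dict:
    """Execute qc -> episodes -> bursts -> trends -> report on one cohort.

    Returns a bundle of result tables and headline statistics; when
    ``out_dir`` is given every intermediate is persisted as CSV and the
    headline statistics as JSON.
    """
    config = config or PipelineConfig()
    bundle: dict = {}

    band_summary = event_qc.summarize_bands(events) if len(events) else pd.DataFrame()
    flow_events, qc_counts = event_qc.filter_flow_analyzable(events)
    assert qc_counts["total"] == qc_counts["retained"] + qc_counts[
        "excluded_no_flow"
    ] + qc_counts["excluded_high_pif"] + qc_counts["excluded_technical_error"]
    logger.info("QC: %s", qc_counts)
    bundle["band_summary"] = band_summary
    bundle["qc_counts"] = qc_counts

    eps = episodes.group_episodes(events, gap_s=config.episode_gap_s)
    bundle["episodes"] = eps
    bundle["episode_sizes"] = episodes.episode_size_distribution(eps)
    series = episodes.daily_counts(events, patients)
    bundle["daily_series"] = series
    bundle["use_histogram"] = episodes.use_histogram(series)
    bundle["mean_inhalations_per_patient_day"] = (
        episodes.mean_inhalations_per_patient_day(series)
    )

    burst_table, overuse_table, raw_by_patient = bursts_mod.detect_cohort(
        series,
        min_2day_mean=config.burst_min_2day_mean,
        baseline_days=config.burst_baseline_days,
        merge_window_days=config.burst_merge_window_days,
    )
    bundle["bursts"] = burst_table
    bundle["overuse"] = overuse_table
    bundle["raw_burst_days"] = raw_by_patient

    exac = exacerbation_study_days(exacerbations, patients)
    conc_table, conc_frac = bursts_mod.burst_exacerbation_concordance(
        raw_by_patient, exac, window_days=config.concordance_window_days
    )
    bundle["concordance"] = conc_table
    bundle["concordant_fraction"] = conc_frac

    first = trends.window_medians(flow_events, patients, "first", config.trend_window_days)
    last = trends.window_medians(flow_events, patients, "last", config.trend_window_days)
    bundle["window_medians_first"] = first
    bundle["window_medians_last"] = last
    bundle["trend_table"] = trends.paired_trend_test(first, last)
    bundle["rolling_medians_10d"] = trends.rolling_medians(
        flow_events, patients, "10-day", config.min_observation_days
    )

    summaries = cohort_stats.summarize_patients(overuse_table, burst_table, exac)
    bundle["patient_summaries"] = summaries
    bundle["summary_table"] = (
        cohort_stats.build_summary_table(summaries) if len(summaries) else pd.DataFrame()
    )

    stats_block = {"qc_counts": qc_counts, "concordant_fraction": conc_frac}
    if len(summaries):
        with_b = summaries.loc[summaries["has_burst"]]
        without_b = summaries.loc[~summaries["has_burst"]]
        if len(with_b) and len(without_b):
            try:
                z, p = cohort_stats.two_proportion_z(
                    int(with_b["has_exacerbation"].sum()),
                    len(with_b),
                    int(without_b["has_exacerbation"].sum()),
                    len(without_b),
                )
                stats_block["z_exacerbation_burst_vs_none"] = {"z": z, "p": p}
            except ValueError:
                pass
        over = summaries.loc[summaries["is_continuous_overuser"]]
        non = summaries.loc[~summaries["is_continuous_overuser"]]
        if len(over) > 1 and len(non) > 1:
            t, df_, p = cohort_stats.pooled_t_from_summary(
                float(over["n_bursts"].mean()),
                float(over["n_bursts"].std(ddof=1)),
                len(over),
                float(non["n_bursts"].mean()),
                float(non["n_bursts"].std(ddof=1)),
                len(non),
            )
            stats_block["t_bursts_overuse_vs_none"] = {"t": t, "df": df_, "p": p}
    bundle["stats"] = stats_block

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in (
            "band_summary",
            "episodes",
            "episode_sizes",
            "daily_series",
            "use_histogram",
            "bursts",
            "overuse",
            "concordance",
            "window_medians_first",
            "window_medians_last",
            "trend_table",
            "rolling_medians_10d",
            "patient_summaries",
            "summary_table",
        ):
            table = bundle[name]
            if isinstance(table, pd.DataFrame):
                table.to_csv(out_dir / f"{name}.csv", index=False)
        with open(out_dir / "stats.json", "w") as fh:
            json.dump(stats_block, fh, indent=2, default=float)
    return bundle
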