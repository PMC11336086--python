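#!/usr/bin/env python
"""Summarise reliever-use patterns: episodes and daily-count histograms.

Groups inhalations into 60-second use occasions, tabulates the share of
events by episode size, builds the zero-filled daily-count series and
the inhalations-per-day histogram, and reports the mean number of
inhalations per patient per day.
"""

import argparse
from pathlib import Path

from sabaflow import episodes
from sabaflow import io as sio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "data")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    parser.add_argument("--gap-seconds", type=float, default=60.0)
    args = parser.parse_args()

    events = sio.read_events(args.data_dir / "events.csv")
    patients = sio.read_patients(args.data_dir / "patients.csv")

    eps = episodes.group_episodes(events, gap_s=args.gap_seconds)
    sizes = episodes.episode_size_distribution(eps)
    series = episodes.daily_counts(events, patients)
    hist = episodes.use_histogram(series)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    sizes.to_csv(args.out_dir / "episode_sizes.csv", index=False)
    series.to_csv(args.out_dir / "daily_counts.csv", index=False)
    hist.to_csv(args.out_dir / "use_histogram.csv", index=False)

    print("share of events by episode size:")
    print(sizes.to_string(index=False))
    print("\ninhalations per day over patient-days:")
    print(hist.to_string(index=False))
    mean_day = episodes.mean_inhalations_per_patient_day(series)
    print(f"\nmean inhalations/patient/day: {mean_day:.2f} "
          f"over {len(series)} patient-days")


if __name__ == "__main__":
    main()
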