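#!/usr/bin/env python
"""Classify events into flow bands and apply the flow-analysis filter.

Reports the band frequency table (count, percent, median/IQR of PIF)
and the QC ledger: how many events were retained as flow-analyzable
(18 <= PIF < 120 L/min) and how many were excluded by reason.
"""

import argparse
from pathlib import Path

from sabaflow import event_qc
from sabaflow import io as sio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "data")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    events = sio.read_events(args.data_dir / "events.csv")
    summary = event_qc.summarize_bands(events)
    _, counts = event_qc.filter_flow_analyzable(events)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.out_dir / "band_summary.csv", index=False)
    print(summary.to_string(index=False))
    pct = 100.0 * counts["retained"] / counts["total"]
    print(f"\nflow-analyzable: {counts['retained']}/{counts['total']} ({pct:.1f}%)")
    for reason in ("no_flow", "high_pif", "technical_error"):
        print(f"excluded ({reason}): {counts['excluded_' + reason]}")


if __name__ == "__main__":
    main()
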