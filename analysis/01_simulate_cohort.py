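#!/usr/bin/env python
"""Generate the default synthetic cohort and persist its four tables.

Writes events, patients, exacerbations and ground truth under
scratch/data/ (the event log is a few MB) and prints the cohort's
headline dimensions.  Every later stage reads these files.
"""

import argparse
from pathlib import Path

from sabaflow import io as sio
from sabaflow.synthetic import SyntheticCohortSpec

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-patients", type=int, default=360)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "data")
    args = parser.parse_args()

    spec = SyntheticCohortSpec(n_patients=args.n_patients, seed=args.seed)
    paths = sio.simulate_to_dir(spec, args.data_dir)
    events = sio.read_events(paths["events"])
    patients = sio.read_patients(paths["patients"])
    exacerbations = sio.read_exacerbations(paths["exacerbations"])
    print(f"cohort: {len(patients)} patients, {len(events)} events, "
          f"{len(exacerbations)} exacerbations")
    print(f"tables written to {args.data_dir}")


if __name__ == "__main__":
    main()
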