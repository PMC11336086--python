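import pandas as pd
import pytest

from sabaflow.synthetic import SyntheticCohortSpec, generate_cohort


def make_events(rows):
    """Build an event table from (pid, timestamp, status, pif) tuples."""
    columns = [
        "patient_id",
        "device_id",
        "timestamp",
        "status",
        "pif_lpm",
        "volume_l",
        "duration_s",
        "time_to_pif_s",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "device_id": "D1",
                "timestamp": pd.Timestamp(ts),
                "status": status,
                "pif_lpm": pif,
                "volume_l": 1.2 if status == "ok" else None,
                "duration_s": 1.4 if status == "ok" else None,
                "time_to_pif_s": 0.4 if status == "ok" else None,
            }
            for pid, ts, status, pif in rows
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    spec = SyntheticCohortSpec(n_patients=60, seed=11)
    events, patients, exacerbations, truth = generate_cohort(spec)
    return spec, events, patients, exacerbations, truth
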