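"""Event-level quality control for electronic-inhaler telemetry.

Each recorded inhaler event carries a device status and, when an
inhalation was detected, four inhalation parameters: peak inspiratory
flow (PIF, L/min), inhalation volume (L), inhalation duration (s) and
time to PIF (s).  The device's MEMS pressure sensor cannot resolve flows
below 18 L/min, so cap-opens without a real inhalation are recorded with
``status == "no_flow"`` and no parameter values.  PIF values of
120 L/min or more indicate the air-vent inlet was partially blocked
(lips or fingers), which inflates the apparent flow; such events are
recorded but excluded from flow analysis.

This module classifies events into the reporting flow bands, into the
coarser patient-app feedback bands, applies the flow-analysis
eligibility filter (18 <= PIF < 120), and summarises band frequencies
with median/IQR of PIF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: MEMS sensor floor: flows below this are recorded as "no flow".
FLOW_FLOOR = 18.0
#: Air-vent-block artifact threshold: PIF at or above this is excluded
#: from flow analysis.
FLOW_CEILING = 120.0

STATUS_OK = "ok"
STATUS_NO_FLOW = "no_flow"
STATUS_TECHNICAL_ERROR = "technical_error"
STATUSES = (STATUS_OK, STATUS_NO_FLOW, STATUS_TECHNICAL_ERROR)

#: Reporting bands, in display order.  All numeric bands are half-open
#: [lo, hi): a PIF of exactly 45 falls in pif_45_to_120, exactly 120 in
#: pif_120_to_200.
FLOW_BANDS = (
    "pif_ge_200",
    "pif_120_to_200",
    "pif_45_to_120",
    "pif_30_to_45",
    "pif_18_to_30",
    "no_flow",
    "technical_error",
)

#: The three bands eligible for flow analysis (18 <= PIF < 120).
FLOW_ANALYZABLE_BANDS = ("pif_45_to_120", "pif_30_to_45", "pif_18_to_30")

#: Band edges for status == ok events; the sensor floor guarantees
#: PIF >= 18 whenever flow was recorded.
_FLOW_BAND_EDGES = (
    (200.0, np.inf, "pif_ge_200"),
    (120.0, 200.0, "pif_120_to_200"),
    (45.0, 120.0, "pif_45_to_120"),
    (30.0, 45.0, "pif_30_to_45"),
    (18.0, 30.0, "pif_18_to_30"),
)

APP_BANDS = ("good", "fair", "low_or_no", "air_vent_block", "exhalation")


@dataclass(frozen=True)
class InhalationEvent:
    """One time-stamped inhaler actuation.

    Parameters are ``None`` when the device recorded no flow
    (``status != "ok"``).
    """

    patient_id: str
    device_id: str
    timestamp: pd.Timestamp
    status: str
    pif: float | None = None
    volume: float | None = None
    duration: float | None = None
    time_to_pif: float | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == STATUS_OK:
            if self.pif is None or not np.isfinite(self.pif):
                raise ValueError("status 'ok' requires a recorded PIF")
            if self.pif < FLOW_FLOOR:
                raise ValueError(
                    f"PIF {self.pif} below the {FLOW_FLOOR} L/min sensor floor "
                    "must be recorded as status 'no_flow'"
                )
        for name in ("volume", "duration", "time_to_pif"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")


def classify_flow_band(status: str, pif: float | None = None) -> str:
    """Assign one reporting flow band to an event.

    The taxonomy is total: every event falls in exactly one of the seven
    bands.  Numeric bands are half-open lower-inclusive.
    """
    if status == STATUS_NO_FLOW:
        return "no_flow"
    if status == STATUS_TECHNICAL_ERROR:
        return "technical_error"
    if status != STATUS_OK:
        raise ValueError(f"unknown status {status!r}")
    if pif is None or not np.isfinite(pif):
        raise ValueError("status 'ok' requires a recorded PIF")
    for lo, hi, label in _FLOW_BAND_EDGES:
        if lo <= pif < hi:
            return label
    raise ValueError(f"PIF {pif} below the sensor floor with status 'ok'")


def classify_app_band(status: str, pif: float | None = None) -> str:
    """Assign the patient-app feedback band.

    good: 45 <= PIF < 200; fair: 30 <= PIF < 45; air_vent_block:
    PIF >= 200; low_or_no: PIF < 30 or no inhalation recorded within a
    minute of the cap opening.  Technical errors that are recorded
    exhalations map to "exhalation"; other technical errors carry no
    flow and map to low_or_no.
    """
    if status == STATUS_NO_FLOW:
        return "low_or_no"
    if status == STATUS_TECHNICAL_ERROR:
        return "low_or_no"
    if status != STATUS_OK:
        raise ValueError(f"unknown status {status!r}")
    if pif is None or not np.isfinite(pif):
        raise ValueError("status 'ok' requires a recorded PIF")
    if pif >= 200.0:
        return "air_vent_block"
    if pif >= 45.0:
        return "good"
    if pif >= 30.0:
        return "fair"
    return "low_or_no"


def classify_flow_bands(events: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_flow_band` over an event table."""
    status = events["status"]
    pif = pd.to_numeric(events["pif_lpm"], errors="coerce")
    band = pd.Series("technical_error", index=events.index, dtype=object)
    band[status == STATUS_NO_FLOW] = "no_flow"
    ok = status == STATUS_OK
    if ok.any() and pif[ok].isna().any():
        raise ValueError("status 'ok' events must carry a recorded PIF")
    for lo, hi, label in _FLOW_BAND_EDGES:
        band[ok & (pif >= lo) & (pif < hi)] = label
    if (ok & (pif < FLOW_FLOOR)).any():
        raise ValueError("status 'ok' event with PIF below the sensor floor")
    return band.rename("flow_band")


def filter_flow_analyzable(
    events: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep events suitable for flow analysis (18 <= PIF < 120).

    Returns the retained subset (original order preserved) and a ledger
    of counts: retained, and excluded by reason (no_flow, high_pif,
    technical_error).
    """
    status = events["status"]
    pif = pd.to_numeric(events["pif_lpm"], errors="coerce")
    keep = (status == STATUS_OK) & (pif >= FLOW_FLOOR) & (pif < FLOW_CEILING)
    counts = {
        "total": int(len(events)),
        "retained": int(keep.sum()),
        "excluded_no_flow": int((status == STATUS_NO_FLOW).sum()),
        "excluded_high_pif": int(((status == STATUS_OK) & (pif >= FLOW_CEILING)).sum()),
        "excluded_technical_error": int((status == STATUS_TECHNICAL_ERROR).sum()),
    }
    return events.loc[keep], counts


def _iqr(values: np.ndarray) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles."""
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def summarize_bands(events: pd.DataFrame) -> pd.DataFrame:
    """Band frequency table: count, percent of all events, PIF median/IQR.

    Percentages are over all events and sum to 100 up to rounding;
    median and IQR are computed only for bands with recorded flow
    (NaN otherwise).
    """
    band = classify_flow_bands(events)
    pif = pd.to_numeric(events["pif_lpm"], errors="coerce")
    total = len(events)
    rows = []
    for label in FLOW_BANDS:
        mask = (band == label).to_numpy()
        n = int(mask.sum())
        flows = pif.to_numpy(dtype=float)[mask]
        flows = flows[np.isfinite(flows)]
        rows.append(
            {
                "band": label,
                "count": n,
                "percent": 100.0 * n / total if total else 0.0,
                "median_pif": float(np.median(flows)) if flows.size else np.nan,
                "iqr_pif": _iqr(flows) if flows.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
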