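"""Cohort-level contingency and summary statistics.

Comparisons between patient groups (e.g. exacerbation rates in patients
with vs without bursts, burst counts in continuous overusers vs the
rest) use the classical large-sample forms: a pooled two-proportion
z-test without continuity correction, and a pooled-variance two-sample
t-test computable from group means, SDs and sizes alone.  The Welch
(unequal-variance) t is available behind a flag for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PatientSummary:
    """Per-patient burst/overuse/exacerbation flags and counts."""

    patient_id: str
    is_continuous_overuser: bool
    n_bursts: int
    n_exacerbations: int

    @property
    def has_burst(self) -> bool:
        return self.n_bursts >= 1

    @property
    def has_exacerbation(self) -> bool:
        return self.n_exacerbations >= 1


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-tailed, no continuity correction.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled
    proportion (x1+x2)/(n1+n2).  Returns (z, two-tailed p).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError(f"invalid counts x={x}, n={n}")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1): SE undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def pooled_t_from_summary(
    m1: float,
    sd1: float,
    n1: int,
    m2: float,
    sd2: float,
    n2: int,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries (means, SDs, sizes).

    Default is the pooled-variance (equal-variance) form with
    df = n1 + n2 - 2; ``welch=True`` gives the Welch statistic with
    Satterthwaite df.  Returns (t, df, two-tailed p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        if se == 0:
            return (0.0, float(n1 + n2 - 2), 1.0) if m1 == m2 else (np.inf, np.nan, 0.0)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        df = float(n1 + n2 - 2)
        if sp2 == 0:
            return (0.0, df, 1.0) if m1 == m2 else (np.inf, df, 0.0)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (m1 - m2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def percent_of(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage rounded half-up to the stated decimal places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def summarize_patients(
    overuse: pd.DataFrame,
    bursts: pd.DataFrame,
    exacerbations: pd.DataFrame,
) -> pd.DataFrame:
    """One row per patient: overuse flag, burst count, exacerbation count."""
    out = overuse[["patient_id", "is_continuous_overuser"]].copy()
    n_bursts = bursts.groupby("patient_id").size() if len(bursts) else pd.Series(dtype=int)
    n_exac = (
        exacerbations.groupby("patient_id").size()
        if len(exacerbations)
        else pd.Series(dtype=int)
    )
    out["n_bursts"] = out["patient_id"].map(n_bursts).fillna(0).astype(int)
    out["n_exacerbations"] = out["patient_id"].map(n_exac).fillna(0).astype(int)
    out["has_burst"] = out["n_bursts"] >= 1
    out["has_exacerbation"] = out["n_exacerbations"] >= 1
    return out


def build_summary_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Nested bursts-by-overuse summary table.

    Rows: all patients; non-overusers split by burst status; overusers
    split by burst status.  Columns: patient count with percent of the
    parent denominator, mean (SD) bursts per patient, patients with
    exacerbations (percent of the row), and total exacerbations.
    """
    def _row(label: str, sub: pd.DataFrame, denom: int) -> dict:
        n = len(sub)
        nb = sub["n_bursts"].to_numpy(dtype=float)
        n_with_ex = int((sub["n_exacerbations"] >= 1).sum())
        return {
            "group": label,
            "n_patients": n,
            "pct_of_parent": percent_of(n, denom, 1) if denom else np.nan,
            "mean_bursts": float(nb.mean()) if n else np.nan,
            "sd_bursts": float(nb.std(ddof=1)) if n > 1 else 0.0,
            "n_with_exacerbation": n_with_ex,
            "pct_with_exacerbation": percent_of(n_with_ex, n, 0) if n else np.nan,
            "n_exacerbations": int(sub["n_exacerbations"].sum()),
        }

    total = len(summaries)
    non = summaries.loc[~summaries["is_continuous_overuser"]]
    over = summaries.loc[summaries["is_continuous_overuser"]]
    rows = [
        _row("all", summaries, total),
        _row("no_overuse", non, total),
        _row("no_overuse/no_bursts", non.loc[~non["has_burst"]], len(non)),
        _row("no_overuse/bursts", non.loc[non["has_burst"]], len(non)),
        _row("overuse", over, total),
        _row("overuse/no_bursts", over.loc[~over["has_burst"]], len(over)),
        _row("overuse/bursts", over.loc[over["has_burst"]], len(over)),
    ]
    return pd.DataFrame(rows)
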