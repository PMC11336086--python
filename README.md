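# sabaflow

Analysis of event streams from electronic short-acting beta2-agonist
(SABA) inhalers. A sensor-equipped dry powder inhaler logs one
time-stamped event per actuation together with four inhalation
parameters — peak inspiratory flow (PIF, L/min), inhalation volume
(L), inhalation duration (s) and time to PIF (s). Over a ~12-week
observation window these streams carry two clinically useful signals
at once: *how often* the reliever is needed (symptom burden) and *how
well* it is inhaled (technique). `sabaflow` is for biostatisticians
and digital-health researchers who need a tested, reproducible
implementation of the standard analyses of such streams.

## What it computes

* **Event QC** — every event is assigned one flow band
  (PIF ≥ 200, 120–<200, 45–<120, 30–<45, 18–<30 L/min, no flow,
  technical error; all ranges half-open lower-inclusive) and one
  app-style feedback band. Flow analysis keeps events with
  18 ≤ PIF < 120: the MEMS sensor cannot resolve flows below
  18 L/min, and readings ≥ 120 L/min are air-vent-block artifacts.
* **Use episodes** — runs of inhalations each ≤ 60 s after the
  previous one form one use occasion; episode-size shares, zero-filled
  daily counts and the inhalations-per-day histogram follow.
* **SABA bursts** — day *d* is a raw burst day when
  mean(countᵈ⁻¹, countᵈ) ≥ 3 and strictly exceeds the mean of the
  preceding 14 days; raw days within 7 days merge into one burst.
* **Continuous overuse** — ≥ 2 inhalations in every complete
  enrollment-anchored week of the observation window.
* **Parameter trends** — per-patient medians of flow-analyzable events
  over the first and last 10 days, compared with a two-tailed Wilcoxon
  signed-rank test; median percentage change per parameter; pooled
  10-day cohort median time courses (patients observed < 70 days
  excluded).
* **Cohort statistics** — pooled two-proportion z-test
  (z = (p̂₁ − p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂))), pooled-variance two-sample
  t-test from group summaries, half-up percentage rounding, and the
  nested bursts-by-overuse summary table.
* **Synthetic cohorts** — a generator that emulates the structure of
  such a study (zero-inflated daily use, habitual overusers, injected
  2-day bursts, exacerbation-linked spikes, linearly declining
  parameter medians, contaminating events) with ground-truth labels,
  so every detector can be validated by recovery.

## Worked example

Generate the default 360-patient cohort and run the analysis stages:

```
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_event_qc.py
python analysis/04_bursts_overuse.py
python analysis/05_parameter_trends.py
```

The QC stage prints the flow-analysis ledger:

```
flow-analyzable: 31010/39631 (78.2%)
excluded (no_flow): 4904
excluded (high_pif): 3284
excluded (technical_error): 433
```

— 78.2% of recorded events had a usable flow signal; the rest were
cap-opens without inhalation, vent-block artifacts, or device errors.
Burst detection then reports

```
bursts: 811 merged across 327 patients
continuous overusers: 97/360 (26.9%)
burst sensitivity vs injected: 100.0%
```

— every 2-day spike injected by the generator was recovered, and the
detected habitual-overuser fraction (26.9%) sits at the generator's
configured 29% up to binomial noise. The trend stage prints the
paired first-vs-last contrast (abridged):

```
 parameter   n_patients  median_of_differences   p_value   median_pct_change
 pif_lpm            316               2.900000  2.50e-07           -3.865737
 volume_l           316               0.199225  6.47e-40          -13.094787
```

— across 316 paired patients, median PIF fell by a median 3.9% and
inhalation volume by 13.1% between the first and last 10 days (the
generator's configured declines are 5.1% and 12.6%), both highly
significant by the signed-rank test. `analysis/03_use_patterns.py` and
`analysis/06_full_report.py` produce the remaining tables; everything
lands under `results/`.

The same computations are available as a library:

```python
from sabaflow import bursts, episodes, event_qc
from sabaflow.synthetic import SyntheticCohortSpec, generate_cohort

events, patients, exac, truth = generate_cohort(SyntheticCohortSpec(seed=0))
flow, ledger = event_qc.filter_flow_analyzable(events)
series = episodes.daily_counts(events, patients)
burst_table, overuse, raw_days = bursts.detect_cohort(series)
```

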