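# Methods

## Setting

Electronic dry powder inhalers (DPIs) with a built-in MEMS pressure
sensor record a time-stamped event every time the cap is opened, and,
when an inhalation is detected, four inhalation parameters: peak
inspiratory flow (PIF, L/min), inhalation volume (L), inhalation
duration (s) and time to PIF (s). For an as-needed reliever
(short-acting beta2-agonist, SABA), the event stream is simultaneously
a record of symptom burden (how often the reliever is needed) and of
inhaler technique (whether the inhalation was forceful enough to
de-aggregate the powder dose). `sabaflow` implements the analysis of
such streams over a ~12-week observation window.

## Event quality control

The MEMS sensor cannot resolve flows below **18 L/min**; cap-opens
without a real inhalation are recorded as *no flow* and carry no
parameter values. PIF readings of **120 L/min or more** indicate that
the air-vent inlet was partially blocked (lips or fingers over the
vent), which raises the internal pressure drop and inflates the
apparent flow and volume; readings of **200 L/min or more** are treated
as a separate reporting band of the same artifact. Flow analysis
therefore uses only events with `18 <= PIF < 120`.

Events are classified into seven reporting bands
(`>=200`, `120–<200`, `45–<120`, `30–<45`, `18–<30`, no flow,
technical error) and five coarser app-style feedback bands (good
`45–<200`, fair `30–<45`, low-or-no `<30`/no flow, air-vent block
`>=200`, exhalation). All numeric ranges are half-open and
lower-inclusive: a PIF of exactly 45 is a good inhalation, exactly 120
is excluded from flow analysis. Technical-error subtypes (double
inhalations recorded as one event, timeouts, exhalations into the
device) are collapsed into a single status; the app "exhalation" label
is retained in the taxonomy but never assigned, since the event log
does not distinguish exhalations from other technical errors.

## Use episodes and daily counts

A *use episode* is a maximal run of events in which each event follows
the previous one by at most **60 s** (chain rule). An anchored variant
(gap measured from the episode's first event) is available because the
definition "within 60 seconds" is ambiguous; the chain rule is the
default. Episode statistics are reported as shares of *events*, not of
episodes: an episode of size k contributes k events to its size
category.

Daily counts are calendar-day event totals per patient, zero-filled
over the patient's full observation window; study day 1 is the
enrollment date. All recorded events count — including no-flow
cap-opens and vent-block artifacts — because use-pattern analysis
describes actuation behaviour, not inhalation quality. A flag-level
restriction to flow-analyzable events is possible by filtering before
counting.

## SABA bursts and continuous overuse

A day *d* is a **raw burst day** when the mean daily count over days
`d-1, d` is at least **3** *and* strictly exceeds the mean over the
preceding **14 days** (`d-15 … d-2`), truncated at study start with at
least one baseline day required (so day 3 is the earliest evaluable
day). Evaluation is rolling (every day), the only reading under which
bursts can be detected on arbitrary days. Ties with the baseline are
not bursts, and the strict comparison is computed on cross-multiplied
sums so integer counts never tie-break on floating-point rounding.

Raw days within a **7-day** window collapse into one burst, greedily
left to right and anchored at the burst onset (earliest raw day of the
group); a chained variant (window from the most recent merged day) is
available behind a flag. Burst onsets of distinct bursts therefore
differ by more than 7 days, and merging is idempotent.

**Continuous overuse** is at least **2** inhalations in *every*
complete enrollment-anchored 7-day block of the observation window; a
trailing partial week is ignored. Enrollment-anchored blocks were
preferred over calendar weeks, which would make the classification
depend on the enrollment weekday.

An exacerbation is *concomitant* with a burst when its onset study day
lies within ±7 days of any raw burst day of the same patient. The
7-day window is a documented default, not a claim about how the
corresponding published fraction was computed.

## Inhalation-parameter trends

Within-patient day-to-day fluctuation is absorbed by aggregating each
patient's flow-analyzable events into two 10-day windows: study days
1–10, and the final 10 days of the patient's own observation (patients
ended on different dates, so the last window is patient-anchored). The
per-patient, per-parameter medians are compared with a two-tailed
Wilcoxon signed-rank test on the paired differences (zeros dropped;
exact null distribution for n ≤ 25 without ties, tie-corrected normal
approximation otherwise). Patients need at least one in-window event in
both windows to enter the pair; below 6 pairs the p-value is flagged
unreliable. Two change summaries are reported deliberately with
opposite signs: the median of per-patient differences (first − last;
positive for a decline, with its IQR as Q3 − Q1 of the paired
differences) and the median per-patient percentage change
((last − first)/first × 100; negative for a decline).

Cohort time courses (daily or 10-day bins) pool *events* rather than
patient medians, and exclude patients observed for fewer than 70 days
so late bins are not dominated by early leavers. A one-sample
Kolmogorov–Smirnov test against a normal fitted by sample mean/SD is
provided to document the non-normality that motivates the
nonparametric choices; it gates nothing.

## Cohort statistics

Group comparisons use the classical summary-statistic forms: the
pooled two-proportion z-test without continuity correction, and the
pooled-variance two-sample t-test computed from group means, SDs and
sizes (df = n1 + n2 − 2). The Welch t is available behind a flag; on
variance-imbalanced inputs it visibly differs from the pooled form,
which is the default. Printed-style percentages round half-up at the
stated precision (banker's rounding would disagree with printed tables
on exact halves). The nested bursts-by-overuse table reports, per
group: patient count and percent of the parent denominator, mean (SD)
bursts per patient, patients with exacerbations, and exacerbation
totals.

## Synthetic cohort generator

The study's raw data are not public, so the pipeline is exercised on a
generator that emulates the *structure* the analysis assumes and
carries ground-truth labels for everything the detectors should
recover. Defaults describe the study conditions: 360 patients, 84-day
windows (5% of patients leave at 60–69 days, exercising the 70-day
exclusion), 29% habitual overusers, on average 1.3 injected bursts per
patient, 18% of patients with exacerbations, and contamination
fractions 12.5% no-flow / 8.2% vent-block / 1.1% technical error.

Per-patient daily counts come from two regimes:

* **Ordinary patients**: zero-inflated negative binomial — a
  structural-zero probability of 0.68 and NB(mean 1.6, size 2.0) on
  active days. This reproduces a ~56% overall zero-use-day mass.
* **Habitual overusers**: a constant daily dose (lognormal around
  2.5/day, σ = 0.5, floored at 2), held flat over the study. Flatness
  is deliberate: under the burst rule's strict-increase condition any
  recurring wobble in a ≥3/day user is flagged as a burst, so
  dose-regular use is the regime that keeps *continuous* overuse
  distinct from *acute* surges. It is an idealization — real habitual
  users miss days — and it means essentially all overuser bursts in
  synthetic data are injected ones.

**Bursts** are injected as +6 inhalations/day on two consecutive days
(Poisson number per patient, onsets ≥ 16 days apart so each survives
the 7-day merge). **Exacerbations** multiply daily counts by 3 over a
3–7-day window and depress inhalation volume by 20% during the window
(a free knob motivated by the qualitative observation that flow and
volume dip around exacerbations, not a calibrated magnitude).

**Inhalation parameters** are drawn per event as
`median(day) × LogNormal(0, 0.18)`, where the patient's median is the
cohort start median times a patient-level `LogNormal(0, 0.18)` factor,
declining linearly in study day. The slope is scaled so the medians at
the centres of the first and last 10-day windows differ by exactly the
configured relative decline; the default declines are 5.1% (PIF),
12.6% (volume), 15.9% (duration) and 6.4% (time to PIF) from start
medians 77 L/min, 1.50 L, 1.58 s and 0.44 s. Flow-analyzable draws are
clipped into [18, 120) L/min, which leaves medians untouched except
for the rare patient whose median itself exceeds the ceiling.
Vent-block events draw PIF as 120 + Exp(30) L/min (so a few percent of
them exceed 200, as in the reporting bands) with volume inflated 1.3×.

**Timing**: use occasions are placed in waking hours (07:00–23:00)
with at least 90 s between occasions; multi-inhalation occasions
(probability 0.42, size 2 + geometric) space their inhalations
10–50 s apart, so the 60-s chain rule recovers the generated episode
structure exactly.

What the generator does *not* emulate: device swaps (one device per
patient), within-day circadian structure beyond waking hours,
autocorrelated symptom runs in ordinary patients, missed-dose noise in
overusers, seasonal trends, and any behavioural feedback. Passing
recovery tests on this cohort shows the detectors implement their
rules correctly at realistic marginals; it does not certify
performance on real streams, whose burst/background separation is less
clean.

## Verification against the generator

On the default cohort the pipeline recovers: injected-burst
sensitivity ≈ 100% (raw detection within ±2 days of injection
onset), detected continuous-overuse fraction within 3 binomial
standard errors of the configured 29% (chance qualifiers among heavy
ordinary users push it slightly above), and median percentage changes
within 2.5 percentage points of the configured declines — roughly
three times the seed-to-seed spread observed at this cohort size —
with signed-rank p < 0.001. Spurious (non-injected) bursts occur at
about 0.4–0.5 per patient-month, almost entirely among ordinary
patients whose active days happen to cluster; this measured rate is
frozen as the documented false-positive bound. Detection rules are
additionally checked event-by-event against independent brute-force
oracles (interval-membership scan for bands, union-find for episode
grouping, literal re-statement of the burst rule, recursive
partitioning for merging, full sign-enumeration for the signed-rank
p-value).

## Problem sizes

Unit and property tests run on cohorts of up to ~100 patients;
acceptance-level recovery checks use the full default 360-patient
cohort (~50,000 events), and Monte-Carlo calibration of the z-test
uses 10,000 replicates at n = 200 per arm. These sizes put
seed-to-seed spread well inside the stated tolerances.
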