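# Methods

This note documents the models and numerical choices behind `ratplm`: the
scoring pipeline (jerk detection, PLM sequencing, indices), the synthetic
recording generator and its calibration, and the statistical machinery.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scoring pipeline

### Envelope and tonic background

The EMG envelope is full-wave rectification followed by a 50-ms moving RMS
(`envelope_smoothing`, default 0.05 s). 50 ms is short enough to resolve a
0.2-s jerk (the minimum scoreable duration) and long enough to suppress
single-sample noise.

The *tonic background* against which jerk amplitude is judged is a robust
running median of the envelope. Implementation: the envelope is reduced to
0.1-s block-RMS values; running medians over a centered 20-s window
(`baseline_window`) and over a 5-s window are computed on the reduced
series (`scipy.ndimage.median_filter`); the background is their
elementwise maximum, linearly interpolated back to full resolution. One
refinement pass replaces reduced samples already exceeding
`amplitude_factor x` the first-pass background with that background and
re-medians, so that dense jerk trains cannot inflate their own reference
level.

Two windows are used because a single centered 20-s median lags abrupt
tonic rises — at a sleep-to-wake transition the threshold referenced to the
lagging median briefly sits inside the new, higher tonic noise and can
produce spurious sub-second "jerks" in early wake. The 5-s median tracks
the rise within ~2.5 s while remaining robust to true jerks (≤ 0.8 s, i.e.
< 16 % of the short window even at the 5-s minimum IMI). During steady
state both medians agree, so the maximum is the long-window median almost
everywhere.

### Detection criteria

An event is an interval where envelope ≥ `amplitude_factor` (2.0) × tonic
background. Intervals separated by < `merge_gap` (0.2 s) are merged — a
brief dip below threshold inside one movement does not split it — and
merged intervals are kept iff duration ∈ [0.2 s, 5 s], inclusive at both
ends, with half a sample of numerical slack. The amplitude comparison uses
the envelope *peak* (not area) against the background at the peak. Because
the threshold is purely relative, detection is invariant to rescaling the
raw trace by any positive constant; this is asserted by property tests.

Left/right events whose onsets differ by < `bilateral_window` (0.5 s) are
fused into one bilateral movement spanning their union. Greedy fusion on
onset-sorted lists attains the maximum matching for this one-dimensional
proximity relation (verified against an exhaustive matching oracle).

### Sequencing and indices

Events are partitioned into maximal runs whose consecutive onset-to-onset
IMIs are strictly < 90 s; ties at exactly 90 s break the run. Runs of ≥ 4
events are periodic (PLM) sequences, the rest are isolated. IMIs are
measured onset-to-onset, the standard PLM convention. Grouping is
state-blind — trains often begin in quiet wake immediately before sleep
onset and continue into SWS — and each member is afterwards attributed by
the stage of the epoch containing its onset (half-open epochs; a boundary
onset belongs to the later epoch). PLMWI counts sequence members in QW per
hour of QW; PLMSI likewise for SWS; sequence members in AW or REM belong to
no index. ILMSI counts isolated movements in sleep per hour of total sleep;
whether REM-stage isolated movements count is configurable
(`ilms_include_rem`, default true — "movements in sleep" divided by total
sleep time reads most naturally as including REM on both sides of the
ratio). A zero denominator yields an undefined index (`None`), never 0.

Episode (bout) metrics: episodes are maximal runs of one stage, with AW+QW
merged for wake metrics; no minimum-bout or smoothing rule is applied (a
single epoch is an episode). Episodes are clipped to the analysis window
*before* averaging, which makes per-window stage-time conservation exact.
Default staging epoch is 10 s, the common rodent convention; it is a
parameter everywhere.

## Synthetic generator

The generator exists to make the pipeline testable end to end: it programs
known indices into a recording and the tests ask whether the chain returns
them. It is **index-parameterized** — the motor rates in a preset *are* the
target indices — rather than a mechanistic model of spinal or dopaminergic
physiology.

### Hypnogram

An alternating-renewal chain over Wake/SWS/REM. Bout lengths in epochs are
geometric with mean `bout_min x 60 / epoch_s` (support ≥ 1 epoch) — the
discrete analogue of exponential bout durations that matches the
programmed mean bout duration exactly, unlike truncating or rounding an
exponential. Transitions: Wake→SWS always; SWS→REM with probability `q`,
else Wake; REM→SWS with probability `r`, else Wake (REM is entered only
from SWS, as in rodent sleep). Writing `n_s = percent_s / bout_s` for the
relative bout-start rates, stationarity gives `q = n_REM / n_SWS` and
`r = (n_SWS - n_Wake) / n_REM`; presets are chosen so both lie in [0, 1],
which requires `1 ≤ n_SWS/n_Wake ≤ 1 + n_REM/n_Wake`. For the 8-h
post-injection presets only stage totals (minutes per 8 h) are calibrated;
their bout means are generator choices set inside that feasibility region
(longer SWS bouts than the 24-h average, consistent with light-phase
sleep). Wake bouts carry an active-wake head and a quiet-wake tail
(`qw_fraction` = 0.4 of epochs): pre-sleep quiet wake is where wake PLM
trains live.

### Event placement

Rates are events per hour of the relevant state; budgets are
`round(rate x state-hours)`.

* *Wake-crossing trains* (only when the preset programs PLMW): at randomly
  chosen QW→SWS transitions, 1–3 events are placed backwards from sleep
  onset inside the QW tail (6–12-s IMIs, which fit the short tails) and
  the train continues into the SWS bout with preset IMIs, so the sequence
  spans the falling-asleep boundary.
* *SWS trains*: bouts are filled with trains of length 4 + geometric
  excess (mean train length 7), IMIs truncated-normal(25, 10) bounded to
  [5, 89] s — the bounds guarantee the periodicity criterion by
  construction; events stay ≥ 1.5 s from bout edges so stage attribution
  is unambiguous. The last train is clamped to ≥ 4 events, so the realized
  budget can differ from the target by at most ±2 events.
* *Isolated movements*: placed uniformly over sleep time, rejected if
  within 90 s of any train event (they would otherwise be absorbed into a
  sequence) or if they would create an isolated run of ≥ 4 (which would
  *be* a sequence), and kept ≥ 2.5 s apart.

These separation rules make the classifier's state-blind grouping
reproduce the generator's train/isolated labels exactly, so the programmed
indices are recovered with **zero** tolerance from the true events — the
self-consistency oracle. (Two trains may fall closer than 90 s and merge
into one longer run; membership, and hence every index, is unchanged.)

### EMG

Per-limb traces are Gaussian tonic noise with state-dependent SD
(AW/QW 0.85, SWS 0.6, REM 0.5 — wake > SWS > REM atonia) plus
cosine-tapered (25-ms ramps) noise bursts at the true event times. Burst
amplitude is 3.5–5 × the local tonic SD and duration 0.3–0.8 s, inside the
scoreable range with margin: the worst case — a 3.5 × 0.6 SWS burst just
after a wake→SWS transition, judged against a still-wake-level background
of 0.85 — clears the 2× threshold (2.1 > 1.7). Events are bilateral with
probability 0.5, else one limb at random. Units are arbitrary (detection
is scale-invariant). Default sampling rate 250 Hz; below 100 Hz the
0.2-0.8-s bursts and the 50-ms smoother are under-resolved and synthesis
refuses to run.

### Cohorts and calibration

Each animal draws an independent substream from
`numpy.random.SeedSequence(seed).spawn(n)`, so cohorts are reproducible
and order-independent. Per-animal variability: motor rates scaled by a
factor with CV 0.10, bout means by CV 0.05, hematocrit normal with the
preset group mean and SD, and PLMW present with probability 5/7 in the ID
preset (some ID animals show no wake PLM), with the nonzero rate drawn so
the cohort mean matches the calibration target. The jitter CVs are
generator choices: large enough that cohort SDs are nontrivial, small
enough that a 6-7-animal cohort mean remains a meaningful estimate of the
preset rate (CV 0.10 ⇒ ~4 % SEM at n=7). The printed between-animal SDs of
the motor indices (e.g. PLMSI 49.8 ± 16.9) are substantially larger; the
generator does not attempt to reproduce them, and cohort-mean recovery
tests average over replicate cohorts where a tighter tolerance demands it.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real recordings: EMG artifacts (movement, chewing,
electrode noise), non-Gaussian tonic activity, circadian modulation of
bout structure within a phase, IMI autocorrelation inside trains, and any
physiological coupling between hematocrit and motor rates beyond the
preset-level association. Detection performance on this clean synthetic
EMG (sensitivity/precision ≈ 1.0) is an upper bound, not a field result.

### Known calibration notes

* The source tables report ID hematocrit as 25.2 ± 1.5 in the group table
  and 20.6 ± 3.2 in the running text; the preset defaults to the table
  value and carries the alternative as `hct_alt`.
* Published correlation summaries print signed "R²" values; a squared
  correlation cannot be negative, so these are treated as signed Pearson
  r. The stats module always reports r and r² separately.

## Statistics

Pearson r uses `scipy.stats.pearsonr` (two-sided p from the t transform)
with explicit guards: n ≥ 3, finite input, nonzero variance (zero variance
raises rather than returning 0). ANOVA is `scipy.stats.f_oneway`, or
`statsmodels` `AnovaRM` when a subject map indicates the same animals
across conditions (the iron-replacement weeks); all-identical input is
short-circuited to F = 0, p = 1. Pairwise post hoc tests are (paired) t
tests with Bonferroni multiplication capped at 1. Dose-response tables
report mean ± SD per condition and a strict-monotonic-decrease flag over
the stated dose order. Densitometry ratios are per-animal DAT/actin OD
quotients (positive-OD validation; invariant to common exposure scaling),
compared across groups with the same ANOVA machinery.

## Problem sizes and determinism

End-to-end suites use 24-h cohorts of 6-7 animals at 250 Hz (the study's
recording structure), 8-h cohorts of 5 for the dose-response conditions,
and 1000 hypnogram replicates for architecture recovery; the acceptance
script averages the tightest-tolerance cohort mean over 3 independent
cohort replicates (21 animals). Event counts and indices are exactly
reproducible for a fixed seed; all randomness flows from a single integer
seed through `SeedSequence` substreams.
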