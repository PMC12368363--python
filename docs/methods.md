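# Methods

## Data model and cleaning

Raw input is a plain CSV sensor log (`participant_id,timestamp_ms,
sensor,x,y,z`; lux in `x` for the light sensor) plus a PHQ-9 CSV
(`participant_id,administration_date,q1..q9`).  Parsing validates each
row against a regular expression; malformed rows are dropped and
counted rather than raising, matching how field-collected logs are
cleaned.  Samples are grouped into participant-days over a single
local day window [00:00, 24:00); duplicate timestamps keep the first
occurrence and gaps are never imputed — every statistic operates on
the observed sample counts, not wall-clock interpolation.  A day is
"insufficient for analysis" when any sensor's sample count falls below
a coverage fraction (default 0.5) of `nominal_rate × 86400`; the
fraction is configurable because no principled universal cutoff
exists.

The sensors report 3-axis vectors, but all rate-of-change features and
detectors operate on a scalar series; we use the per-sample Euclidean
magnitude of the accelerometer (and gyroscope) vector.  Per-axis
series remain available and feed the per-axis IQR features.

## Features

Eighteen per-day features (20 numeric columns; the IQR family is one
per axis) are documented in `phonesense.features`.  Numerical choices
that were genuinely open:

* **Detector windows are specified in seconds** (50 s stillness for
  bedtime, 30 s for wake, 50 s for outings, 10 s for the light
  bedtime — the window lengths correspond to 5000/3000/1000 samples at
  a 100 Hz collection rate) and converted to sample counts via the
  stream's nominal rate.  This keeps detector semantics identical when
  streams are generated or down-sampled at lower rates.
* **Search windows.** Bedtime is searched in [00:00, 05:00); wake in
  [05:00, 12:00); the light bedtime wraps midnight, scanning
  [21:00, 24:00) before [00:00, 05:00).  The morning/noon/afternoon/
  evening outing slots are 07–10, 11–13, 14–17, 17–19 h.
* **Quartiles** follow the positional rule (Q1 at position (n+1)/4 of
  the sorted series, fractional positions averaging the two adjacent
  order statistics).  This is *not* numpy's interpolating quantile, so
  it is implemented directly and cross-checked in tests against an
  independent re-application of the rule.
* **Skewness** uses the n/((n−1)(n−2)) adjusted form with the (n−1)
  sample standard deviation; constant series are degenerate and
  reported as missing.
* **Spectrum.** The PSD estimator is the boxcar periodogram of the
  mean-removed series (`scipy.signal.periodogram`).  The spectral
  centroid/bandwidth/slope arithmetic downstream of the PSD is
  estimator-independent and is what the oracle tests pin down; the
  estimator itself is a config-level choice.  Spectral and skewness
  features are computed on the accelerometer magnitude.
* **Missing detections** (a night with no sustained stillness, a day
  with no qualifying wake window) are encoded as NaN.  For
  classification they are imputed with the participant's
  training-fold median, falling back to the training-fold cohort
  median — statistics always come from the training fold only, since
  leave-one-out otherwise leaks the test day into its own
  preprocessing.
* **Derived measures.** Activity duration counts consecutive-sample
  changes with |Δa| > 2.5 and converts to minutes via the rate; meal
  times are the first detected outing time in the noon (lunch) and
  evening (dinner) slots, and meal regularity is each day's deviation
  from the participant's mean meal time.

## PHQ-9 labels

Item scores 0–3 sum to a 0–27 total, banded none/mild/moderate/
moderately-severe/severe at 5/10/15/20.  Administrations repeat every
3 days; a participant whose totals spread by more than a consistency
threshold (default 5 points — one band width) is excluded as an
unreliable rater, and the rest are averaged.  Exclusion is applied
before averaging.  The screening label binarizes the averaged score at
5, and the *continuous* averaged score (copied to each of the
participant's days) is the label used for feature relevance.

## Feature selection

Two-stage Pearson filter: drop features with |r(feature, score)| <
0.2; then walk survivors in descending |relevance| and drop any
feature whose |r| with an already-retained feature is ≥ 0.8, keeping
the more label-relevant member (descending-relevance processing makes
the tie-break deterministic and preserves predictive signal).
Absolute correlation is used on both stages: several genuine
behavioral correlates (evening outings, activity) are *negatively*
related to severity and a signed threshold would discard them.
Constant or all-missing columns get relevance 0 and fall out at stage
one.

## Evaluation

Day-level leave-one-out cross-validation: each of the N days is the
test set once.  Five scikit-learn model families with library-default
hyperparameters (recorded verbatim in the report): `SVC`,
`DecisionTreeClassifier`, `KNeighborsClassifier`, `GaussianNB`,
`RandomForestClassifier`.  Inputs to the margin/distance-based models
(SVM, k-NN) are standardized per training fold; tree models and naive
Bayes consume raw values.  Held-out predictions pool into one
confusion matrix per model (accuracy, precision, recall, F1;
zero-denominator ratios are reported as missing), and the mean
per-fold 0/1 error is reported alongside — with one test sample per
fold the two views agree, and the invariant is asserted in tests.

Day-level folding lets the same participant appear in train and test
folds; that is the protocol being reproduced, and it inflates accuracy
when participants are behaviorally idiosyncratic.  A grouped
(leave-one-participant-out) mode is provided for the stricter reading.

## Synthetic cohorts

The generator exists so the pipeline is testable end to end; it
emulates the *directions* of severity–behavior coupling, not any real
cohort's distributions.  Each participant's `BehavioralProfile` is
drawn as a linear function of severity s ∈ [0, 27] (scaled by a
coupling preset: none/default/strong) plus small participant-level
jitter:

| parameter | at s = 0 | at s = 27 (default coupling) |
| --- | --- | --- |
| bedtime mean | 00:21 | 02:21 |
| bedtime SD | 5 min | 45 min |
| wake mean / SD | 07:30 / 8 min | 08:30 / 23 min |
| outing probability (morning/noon/afternoon/evening) | .70/.92/.60/.90 | .35/.77/.35/.30 |
| meal-time SD | 6 min | 31 min |
| movement-burst amplitude | 3.0 m/s² | 1.2 m/s² |
| daily activity | 90 min | 35 min |

The anchor bedtime of 00:21 at severity 0 is the regular-sleeper
reference; the evening slot carries the largest outing decline because
dinner outings are where behavior separates most.  Effect sizes are
otherwise chosen for testability — real effect sizes are unknown.

A day is laid out on a minute grid: pre-sleep phone use [00:00, b),
sleep [b, w), a 10-min wake stir, indoor sedentary time, 15-min
movement bouts filling the profile's activity budget, and 25-min
outings placed inside their slots (skipped when the slot has no room
after waking).  Segment noise is constructed so the detectors recover
the schedule: sleep |Δa| stays well inside ±2 with lux in [0, 0.9];
pre-sleep handling keeps |Δa| in (2.1, 2.4) — restless enough that the
stillness detector cannot fire early, but below the 2.5
physical-activity threshold; indoor |Δa| rarely reaches 2 and never 3;
outings hold ≥ 1000 lux (evening outings stay dark) with ~92% of
changes above 3; movement bouts avoid 16:45–19:05 so the
acceleration-only evening rule fires only for scheduled evening
outings.  Accelerometer samples alternate the sign of their deviation
around the 9.8 m/s² gravity baseline, so |Δa| between neighbours
equals the mean of the adjacent deviation magnitudes; axis components
share the magnitude through a mildly varying direction vector.
Gyroscope magnitudes exceed 0.1 rad/s exactly during movement
segments.  PHQ-9 administrations are generated every 3 days with
totals ~N(severity, 1.2) split across the nine items.

What this does **not** emulate: sensor dropout and non-uniform
sampling, phone-not-carried periods, naps, weekday/weekend structure,
seasonal light variation, and realistic accelerometer waveforms
(bursts are stylized alternating deviations, not gait).  Passing tests
therefore show the *pipeline* is correct and the couplings are
recoverable under the stated model — not that the features would
perform identically on field data.

## Problem sizes

All statistics are rate-invariant by construction, so tests and the
acceptance script run at reduced rates: 5 Hz for single-day detector
checks, 1 Hz for the 12-participant × 11-day classification cohort
(132 days, ~86 k samples per sensor-day), and 0.2 Hz for the 20-seed
coupling-direction sweep.  The acceptance script uses the 1 Hz cohort
and default models; random-forest permutation checks in the test suite
use 50 trees.

## Known limitations

* The screening label is a questionnaire score, not a diagnosis.
* Day-level LOO optimism (above) is inherent to the reproduced
  protocol.
* With 12 participants the continuous relevance label takes only 12
  distinct values across 132 days; feature–label correlations are
  driven by between-participant variation.
* Detector thresholds (±2, ≥ 1000 lux, > 3, > 2.5) are fixed domain
  constants; phones, cases, and habits differ, and on real data they
  would need per-device calibration.
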