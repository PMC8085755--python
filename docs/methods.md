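# Methods

This note documents the models, conventions and design choices behind
`toponet`, in the order data flows through the package.

## Preprocessing conventions

Per-second monitor feeds are averaged to one value per minute. Null and
zero readings are treated as sensor dropouts; within a minute they are
excluded from the mean, and a minute whose dropout fraction exceeds 30% is
emitted as missing. The 30% rule is applied **per channel** (heart rate,
respiratory rate, SpO2 independently): the alternative — a joint rule over
all variables — would discard a channel's valid minutes because another
channel's sensor failed, which is not how dropout behaves in practice.

Missing minutes are filled by last-observation-carried-forward, never by
interpolation that looks ahead: the same preprocessing must run in real
time, where the next observation does not exist yet. Leading minutes with
no predecessor are trimmed from the record start rather than back-filled,
again to avoid leaking future values. Channels are then truncated to their
common span so the three series share one 0-based minute grid. All windows
are half-open `[end − width, end)` in minutes; this convention is fixed
once here and asserted throughout the tests.

## Onset labeling

A tachycardia event is a maximal run of minutes with heart rate **strictly
above** a threshold whose length reaches the criterion duration:
(>100 bpm, ≥30 min), (>130, ≥20), (>150, ≥5). "Sustained over D minutes"
is read as run length ≥ D; this is consistent with the canonical worked
example used in the tests, where a 51-minute episode above 100 bpm is an
event under the 30-minute rule. The labeled onset is the **first minute of
the earliest qualifying run** across all criteria. When one run qualifies
under several criteria from the same start minute, the higher threshold is
reported; when a higher threshold is only reached later inside a run that
already qualified earlier, the earlier start wins — the clinical quantity
of interest is when deterioration began, not which rule matched. Only the
first onset labels a record for modelling; `detect_all_onsets` exists for
the simulator's bookkeeping.

The run-based detector is verified against a brute-force oracle that tests
every (start, criterion) window on series up to length 2,000.

## Feature extraction

Each sample summarises a 120-minute observing window as 21 sub-windows of
20 minutes at a 5-minute stride. Per sub-window, 21 statistics are
computed (10 HR, 5 RR, 5 SpO2, 1 cross-channel), in a fixed registry order
that is part of the model contract.

Numerical conventions, chosen once and oracle-tested:

- `std` features use the **sample** estimator (ddof 1); the autocorrelation
  normalisation uses the **population** variance, the conventional choice
  for R(l). A constant series returns R(l) = 0 (the coefficient is
  undefined at zero variance, and a flat signal has no similarity structure
  worth scoring).
- Quantiles interpolate linearly between order statistics (type-7), the
  numpy default.
- `hr_c2` is the c3 nonlinearity statistic at lag 2 — the name keys the
  lag, not a different functional.
- The slope is the least-squares linear coefficient against sample index,
  in units per minute.
- The cross-channel autocorrelation uses lag 40, which cannot fit in a
  20-sample sub-window; it is computed once per observing window (per
  channel over the full 120 minutes at lag 40, averaged over the three
  channels) and replicated at every time step. The single lag 40 is used
  rather than an average over lags 1..40.

## Sampling and cohort assembly

Records shorter than the monitoring floor (840 min ICU-style, 240 min
ward-style) or from patients aged ≤ 18 are excluded. Onset-free records
contribute negative windows every 60 minutes; records with an onset
contribute only positives (their pre-event quiet period is not recycled as
negatives). Positive windows end `forecast_range` hours before onset;
target replication re-extracts up to `replication_count` windows shifted 5
minutes **earlier** (shifting later would cross the forecast boundary).
`replication_count` defaults to 4 — bounded augmentation that brings the
class ratio near 1:1 on the default cohorts without unbounded duplication.
Negatives are then subsampled (seeded, without replacement) to the positive
count, and the set is split 80/20 **by patient**, so no patient's windows
appear on both sides.

## Classifier

The per-step feature vectors are concatenated with the 11-value static
encoding (age numeric; male indicator; admission type one-hot ×3; first
care unit one-hot ×5, all zero for ward patients; cardiovascular-history
indicator) at **every** time step, then z-scored using statistics computed
on the training set only (zero-variance columns pass through; among static
fields only age is scaled). The network is a bidirectional LSTM with
hidden size 32 per direction; the final hidden states of the two directions
are concatenated into a dense logistic head. Loss is binary cross-entropy,
optimised by Adam; defaults are learning rate 2e-4, 20 epochs, batch 64.

The network is implemented in numpy with hand-derived backpropagation
through time (gate order input/forget/cell/output, forget bias initialised
at 1, uniform ±1/√h weight init). The analytic gradients are tested
against central finite differences. All randomness — initialisation and
batch order — flows from a single seed, so `fit` is bit-reproducible.

Hyperparameter search samples uniformly from a learning-rate grid
1e-4..1e-2 (step 1e-4) and an epoch grid 5..95 (step 10), scoring each draw
by mean validation cross-entropy over patient-grouped 5-fold CV. The grids
are enforced in the search, not on `ModelConfig` itself, so callers can
train outside them (e.g. long overfitting runs in tests, or 0 finetuning
epochs as an identity).

Transfer finetuning continues Adam optimisation from pretrained weights on
a new cohort with the transfer recipe (lr 2e-4, 18 epochs, batch 32) and
recomputes normalisation statistics on the new training data — the feature
scales of a ward cohort differ from the ICU cohort the weights came from.

## Monitoring

Risk is evaluated every 5 minutes once 120 minutes of history exist, each
score a pure function of the trailing observing window (causality is
tested by truncation). An alarm fires at the k-th consecutive exceedance
of the threshold (defaults θ = 0.40, k = 1; the persistence requirement is
configurable because "sustained exceedance" has no canonical duration).
Lead time is onset minus alarm minute; alarms after onset are reported as
lead 0 with a late flag, and missed alarms are first-class outcomes.
Alarms are monotone in both θ and k: raising either can never produce an
earlier alarm.

## Metrics

AUROC is the rank statistic (ties counted half), computed via
scikit-learn and verified against brute-force pair counting. The five
threshold metrics use `score > threshold` (default 0.5, configurable);
undefined precision (no predicted positives) is reported as 0 with a flag
rather than NaN. Confidence intervals are class-stratified percentile
bootstrap (B = 1000 by default), applied uniformly to all six metrics —
stratification keeps every replicate two-class and preserves the class
ratio. Its empirical coverage is checked on a binormal score model.
Cross-validation folds are patient-disjoint and seeded.

## Synthetic cohort generator

The generator emulates the *structure* of monitored cohorts, not their
physiology: stationary AR(1) noise per channel around baselines
(HR 75 ± 8 bpm, RR 16 ± 3, SpO2 97 ± 1.5; AR coefficients 0.9/0.85/0.9 —
strong minute-scale persistence typical of vital signs), monitoring spans
of 15–24 h (ICU preset) or 8–14 h (ward preset), and static profiles drawn
from admission statistics of an ICU-style cohort (57.2% female, 79.8%
emergency admissions, five care units, 86.6% cardiovascular history,
median age ≈ 66) and a ward-style cohort (40.5% female, 87.6% elective, no
care unit, 90.3% cardiovascular history, median age 61). Ages are normal
draws matched to the cohort median and IQR, truncated above 18.

Event patients receive a **prodrome** — a linear ramp over a lead window
(defaults: 360 min lead, +18 bpm HR, +6 breaths/min RR, −3% SpO2, HR noise
×1.5) — followed by a plateau of 112 bpm for 45 minutes that satisfies the
>100 bpm/≥30 min rule by construction. The defaults place the whole
2-hour observing window inside the prodrome at a 2-hour forecast range,
and are motivated by the clinical observation that vital-sign
deterioration commonly begins 6–12 hours before serious adverse events.
The drift-free `NULL_PRODROME` keeps the events but removes all pre-onset
signal, giving a negative control whose held-out AUROC must sit at chance.

Two deliberate artificialities guarantee exact ground truth: event
patients' pre-onset HR is capped at 100.0 bpm (never strictly above
threshold, so noise cannot start the qualifying run early) and the plateau
is floored at 101 bpm (noise cannot split it). Event-free patients are
uncapped — at baseline 75 ± 8 bpm, thirty consecutive minutes above
100 bpm by noise alone is vanishingly improbable, which the tests confirm
over hundreds of seeded draws. All randomness derives from one root seed
via spawned per-patient seeds, so cohorts are byte-reproducible and any
patient can be regenerated alone.

What passing tests therefore show: the pipeline recovers a *planted,
linear, noise-free-in-expectation* drift, and does not hallucinate signal
where none exists. They do not show that real pre-tachycardia physiology
is linear, that real onset dynamics resemble the plateau, or what
performance to expect on clinical data — real records carry artifacts,
interventions (e.g. beta-blockade) and nonstationarity the generator does
not model.

## Problem sizes used in the checks

The end-to-end checks train on 200-patient synthetic cohorts (about 1,000
balanced samples) for 20 epochs, three seeds each for the prodrome and
null conditions; oracle-equivalence suites use 1,000 random feature
windows, series up to length 2,000 for the detector, 200 datasets of up to
200 samples for AUROC, and 500 random score series for alarm monotonicity.

## Known limitations

- The recurrent classifier reads the final hidden states only; per-step
  attention or pooling is out of scope.
- The bootstrap CI is percentile (not BCa); for metrics near 0 or 1 with
  small test sets its coverage degrades, as percentile intervals do.
- `fill_missing` carries the last value forward indefinitely; very long
  gaps are not flagged for exclusion beyond the per-minute dropout rule.
- Tachycardia subtype (sinus vs AF vs VT), waveform-level signal quality,
  and recurrence after a first onset are not modelled.
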