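# Methods

This note documents the models, conventions and parameter choices behind
`legagility`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic cohort does and does not show.

## Signals and units

A recording is one Leg Agility execution captured by a phone strapped to
the thigh, y-axis along the femur: time (s), 3-axis acceleration (g),
3-axis angular velocity (dps) and optionally pitch (degrees, rotation about
the device x-axis — with this mounting, pitch tracks thigh elevation).
Nominal rate 200 Hz. On ingest, m/s² acceleration is divided by 9.80665 and
millisecond timestamps are auto-detected from the median inter-sample
interval (≥ 0.5 ⇒ milliseconds). Rows that fail numeric parsing are
dropped and counted; duplicated timestamps are collapsed keeping the first
sample. The sampling rate, when not supplied, is the reciprocal of the
median inter-sample interval — robust to isolated gaps.

Clinical ground truth is the set of integer scores (0–4) from up to four
raters. The *mean* score is the continuous regression target; the class
label is the mean rounded **half away from zero** (2.5 → 3). This rounding
convention is used everywhere a continuous score becomes a label, including
the neural scorer's discrete output.

## Preprocessing

**Gravity recalibration.** The mounting never puts gravity exactly on the
z-axis. The mean acceleration over a reference window estimates the gravity
direction; the shortest-arc quaternion taking that direction to +z is
applied to both accelerometer and gyroscope (the antiparallel degenerate
case rotates π about x). The default reference window is the whole
recording: the task is seated and the thigh returns to rest between stomps,
so the full-record mean is gravity-dominated. A static-window override
exists for protocols with a guaranteed quiet lead-in. If the reference mean
magnitude falls outside [0.5, 1.5] g the device was likely moving (or
mis-scaled) and calibration refuses. When no orientation channel was
logged, pitch is recomputed from the rotated gravity direction as
atan2(−a_y, a_z).

**Filtering.** Each analysis channel is mean-removed and low-pass filtered
with an order-2 Butterworth applied forward–backward (`filtfilt`), i.e.
zero phase; the effective magnitude response is the square of the one-pass
response. "Order 2, zero lag" here means the order-2 *design* run in both
directions. Edges use odd-reflection padding of three filter lengths. The
default cutoff is 4 Hz, order 2; `select_cutoff` recomputes the cutoff as
the smallest frequency retaining 90% (configurable) of the cohort-averaged
normalized power — on simulated cohorts it lands at ≈ 3 Hz, comfortably
under the 4 Hz default, because rhythmic leg movement concentrates below
~3 Hz with low harmonics.

## Features

36 features = 12 families × {θₓ, ωₓ, α_z}. Spectra are one-sided FFTs of
the mean-removed signal with a rectangular window; at 10 s records the
0.1 Hz bin resolution makes leakage acceptable for these descriptors, and
no taper keeps the Parseval bookkeeping exact (sum of the power spectrum
equals the signal's mean square). Conventions the literature leaves open
are fixed as follows:

- **Dominant frequency**: argmax of the magnitude spectrum, ties toward the
  lower frequency.
- **Spectral entropy**: Shannon entropy of the power distribution divided
  by log(number of bins) — 0 for a pure tone, 1 for white power.
- **Regularity**: first positive-lag local maximum of the biased
  autocorrelation, normalized by the lag-0 value; 0 (with a warning) when
  no such maximum exists.
- **Dominant ratio**: power within ±0.25 Hz of the dominant frequency over
  total power.
- **Harmonics**: local maxima of the magnitude spectrum at least 0.25 Hz
  apart (larger amplitude wins on conflict) and above 10% of the dominant
  amplitude; width is full width at half maximum with linear interpolation
  between bins. `scipy`'s `peak_widths` measures width at a
  prominence-relative height rather than half maximum, so FWHM is computed
  directly from its definition. **Mean peak value** is the mean amplitude
  over detected harmonics — one number combining harmonic count and
  strength.
- **Time-domain entropy**: Shannon entropy of a 16-bin histogram over the
  signal's observed range; exactly 0 for a constant signal.
- **Mean amplitude**: the mean peak-to-peak excursion per movement cycle,
  with cycles segmented once on the pitch signal's rising zero crossings
  and shared by all three channels. This tracks the clinical emphasis on
  movement amplitude better than a mean rectified value would.

## Feature selection

Features are ranked by |Pearson r| against the *continuous* mean rater
score (more informative than the rounded label, and consistent with the
regression target). Features below the conventional 0.4 "weak correlation"
floor are discarded. Gaps — strictly positive drops between adjacent
ranked |r| values — are measured on the **full ranking**, the way they
appear on a ranked-correlation plot; the three largest define thresholds
C1 ≤ C2 ≤ C3 and the candidate subsets are the ranking prefixes ending at
each gap, truncated to the floor survivors. (Measuring gaps on the full
ranking lets the drop that straddles the floor select the entire surviving
set, which is typically the largest drop of all.) Each candidate is scored
by mean LOSO accuracy over a roster of {SVM, kNN, DT} (the neural scorer is
excluded from this inner loop for speed); ties go to the smaller subset.
Finally, any pair of chosen features more correlated with each other than
either is with the target loses its lower-ranked member, repeated to a
fixed point.

On clean synthetic cohorts the redundancy rule is deliberately aggressive:
severity proxies (rms, range, standard deviation of the same channel) are
nearly collinear, so the chosen set can shrink to a handful of features
with no loss of downstream accuracy. Real recordings, with more independent
noise per feature, retain larger sets.

## Models

- **SVM**: linear kernel, box constraint 36, one-vs-one multiclass.
- **kNN**: 5 neighbors, Euclidean, equal weights.
- **Decision tree**: Gini (Gini–Simpson) split criterion, at most 4 splits
  (`max_leaf_nodes = 5`).
- **Neural scorer**: input → 16 tanh → 16 tanh → 1 linear, trained on the
  un-rounded mean rater score with MSE loss by full-batch gradient descent.
  Learning rate starts at 0.01, multiplies by 1.10 after an epoch that does
  not increase the loss, and by 0.80 — with the step reverted — after one
  that does. Training stops at 2000 iterations or gradient norm < 1e-5.
  Weights start uniform in ±1/√fan_in from the run seed, so training is
  bit-reproducible. Its discrete label is clip(round(score), 0, 3).

Validation is leave-one-subject-out: one fold per subject, both legs held
out together. Features are z-scored per fold with training-fold statistics
only. Recordings labelled 4 are excluded from modeling by default (severe
patients often cannot perform the task; the monitoring use case targets
0–3) and reported as excluded. A small exhaustive grid search around the
shipped hyperparameters is available; the shipped defaults are used unless
it is explicitly invoked.

## Evaluation

Accuracy, per-class confusion and macro one-vs-rest AUC; for scalar
continuous scores the per-class ranking score is −|score − k|, and for
models with only a discrete output the same construction on the predicted
label serves as a coarse surrogate (documented as such). Agreement between
the continuous score and the mean clinician score: Pearson r, RMSE,
ICC(2,1) (two-way random effects, absolute agreement, single measure —
computed via `pingouin` and cross-checked against the ANOVA-table formula
in the tests) and Bland–Altman bias ± 1.96·SD limits. Inter-rater agreement
is pairwise Pearson correlation between raters, the index the automatic
score is compared against.

## The synthetic cohort

The simulator emulates the study conditions end to end. Pitch is a train of
raised-cosine pulses θ(t) = A/2·(1 − cos 2πt/T) — chosen over a pure
sinusoid so hesitations (flat gaps) and per-cycle amplitude decrement are
representable; ωₓ is its analytic derivative; α_z is gravity plus the
second derivative of the vertical sensor excursion (lever · sin θ, lever
0.04 m) plus a Gaussian stomp impulse (σ = 20 ms, 0.25 g at full amplitude)
at each foot strike. A fixed mounting tilt about x (8° ± 2° per recording)
leaks gravity into the y-axis, exercising the recalibration. Severity maps
linearly onto the motor parameters:

| parameter | severity 0 | severity 4 | unit |
|---|---|---|---|
| stomp frequency | 3.0 | 1.0 | Hz |
| pitch amplitude | 25 | 6 | deg |
| amplitude decrement | 0.005 | 0.085 | fraction/repetition |
| hesitations | 0 | 2 | per 10 s |
| cycle-time CV | 0.03 | 0.15 | — |
| tremor (5 Hz) | 0 | 0.6 | deg |

The severity-0 anchors were calibrated once so that the output respects the
young-adult sensor envelope: the analytic gyro peak A·π·f ≈ 236 dps and
acceleration peaks ≈ 1.1–1.6 g, inside the ±2000 dps / ±2 g smartphone
range. The tremor term is small because rest tremor is largely suppressed
during voluntary movement; this also keeps ≥ 90% of signal power below the
4 Hz analysis cutoff, consistent with the filtering design. All samples are
quantized to 40 mg / 60 mdps and clipped to range. Raters score
clip(round(severity + N(0, 0.5)), 0, 4); with four raters this puts
pairwise inter-rater correlation near var(truth)/(var(truth) + 2·0.25) ≈
0.7–0.85 on a balanced cohort, matching clinical experience. The two legs
of a subject share a severity effect and deviate from it with SD 0.3, so
they usually share a label and occasionally differ by one.

What the simulator does **not** capture: real stomp-impulse sharpness (no
raw data are published; the impulse width is a free parameter),
biomechanical coupling beyond a single rotation axis, dyskinesias,
tremor-subtype structure, sensor drift, and the long tail of real-world
artifacts (clothing slip, incomplete task compliance). Passing the recovery
tests therefore shows the pipeline is *internally correct and sensitive to
the severity cues it models* — not that it attains any particular accuracy
on clinical data.

## Problem sizes and numerical choices

The recovery cohort used by the tests and the acceptance script is 48
subjects (~95 recordings) with a balanced 0–3 severity mix, 10 s recordings
at 200 Hz — large enough for stable LOSO statistics while keeping a full
pipeline run around 15 s on one CPU. Selection-recovery checks use 200
recordings × 36 features × 10 seeds. Tolerances: spectra agree with a
brute-force DFT oracle to 1e-6 relative; metric implementations agree with
textbook formulas to 1e-9; filter passband flatness is asserted to 1% after
discarding 1 s edges. Degenerate inputs (constant signals, constant
targets, single-class folds, zero-variance raters) return explicit errors
or documented sentinel values rather than NaN.

## Known limitations

- The continuous scorer is a scalar regressor; class-probability
  calibration is out of scope.
- The AUC surrogate for discrete-only models compresses ranking
  information and should not be compared across model kinds.
- The redundancy filter can over-prune on low-noise cohorts (see above).
- Orientation ingestion supports Euler pitch directly and gravity-derived
  pitch; quaternion orientation streams must be converted upstream.
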