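# Methods

`fieldfatigue` models the estimation of physical/cognitive fatigue from a
single chest-worn sensor (tri-axial accelerometry at 100 Hz plus single-lead
ECG at 250 Hz) during a repeated field protocol: an hourly cycle of a
self-paced 3.8 km trail loop with 200 m of vertical gain followed by a
10-minute seated cognitive-load block, with a battery of performance tests
(finger tapping, vertical jump, Stroop, PVSAT, Trail Making A/B, spatial
memory) administered after the physical and after the cognitive load of each
cycle.  A 1-D CNN regresses short sensor windows onto a continuous fatigue
label derived from the performance tests, separately per activity type.

## Synthetic sessions

No recorded sessions ship with the package; every stage is exercised against
a generative model of the protocol whose ground truth is known.

**Fatigue trajectory.**  The latent state `f(t) ∈ [0, 1]` is monotone
non-decreasing by default, a linear ramp from 0 to 0.6 over the session —
progressive fatigue under repeated fixed load without reaching collapse.  An
optional bounded within-hour sinusoid models partial recovery during seated
blocks (off by default so the default trajectory stays monotone).  Labels
carry performance polarity (1 = freshest), so the default label declines
roughly linearly from 1 toward 0.

**Gait.**  Each step is a waveform on step phase: a narrow impact peak
followed by a broad mid-stance valley, riding on the +1 g gravity component
of the vertical channel.  Surfaces (tarseal, gravel, dirt, mud, grass,
boulders) select template parameters — peak sharpness, valley depth — giving
surface-specific waveform families.  Fatigue acts two ways: the per-step peak
amplitude scales by `1 − 0.3 f`, and both amplitude jitter
(`σ_amp = 0.05 + 0.10 f`, multiplicative) and step-period jitter
(`σ_T = 0.02 + 0.04 f`, relative) grow with `f`.  These magnitudes are free
parameters of the generator, chosen once to make fatigue recoverable but not
trivial; they are not claims about real gait.  The single-peak template
guarantees exactly one positive-going mean crossing per step outside a
±0.05 g band, so the cadence estimator can close the loop on the commanded
cadence (run 165 spm, walk 112 spm, per-segment ±2 spm jitter).  White
accelerometer noise is 0.02 g; seated blocks emit 0.01 g noise plus a faint
0.25 Hz respiratory component; gate crossings are short stereotyped
transients at fixed course positions.

**ECG.**  A PQRST Gaussian-sum template is evaluated on a beat-phase signal
whose rate tracks a per-second heart-rate profile
`HR = 55 + 110·intensity(activity) + 15·f`, smoothed with a 30 s moving
average for cardiac lag.  Additive baseline wander (0.08 and 0.2 Hz
sinusoids, 0.1 mV) and 0.01 mV noise exercise the baseline correction.  No
pathology or HRV structure is modelled.

**GPS.**  The course is laid out as a circular loop (23 sections, lengths
summing to 3800 m, climbs to ±200 m), sampled at 1 Hz with 2.5 m per-axis
horizontal noise and 3 m altimeter noise (≈6 m horizontal accuracy).

**Performance tests.**  Each test score is affine in `f` with Gaussian
noise; slopes and noise levels were calibrated analytically
(`R² = m²σ_f² / (m²σ_f² + σ²)` over an 11-cycle schedule) so the regenerated
sensitivity pattern ranks like the field battery — vertical jump ≈ 0.78 and
dominant-hand finger tapping ≈ 0.72 high, PVSAT ≈ 0.03 and spatial memory
near zero.  Only the pattern is calibrated; individual draws vary.

All randomness derives from one session seed through
`numpy.random.SeedSequence` spawning (separate streams for accelerometry,
ECG, GPS and scores), so identical configurations are bit-identical.

**What the generator does not emulate:** biomechanically valid gait, drift
or dropout in real sensors, self-pacing variability, weather/terrain
interaction, or any participant-specific structure.  Passing tests therefore
demonstrate that the pipeline recovers what the generator encodes — they are
closure and correctness checks, not field validation.

## Signal preparation

Accelerometry is up-sampled 100 → 250 Hz by linear interpolation (zero-order
hold would insert step artifacts into the CNN input); ECG is native 250 Hz.
ECG baseline wander is removed by two-stage running-median detrending
(~200 ms then ~600 ms windows — the short stage rejects QRS complexes, the
long stage smooths over T waves); the first-stage medians are evaluated on a
10-sample stride and interpolated, which is exact for the band-limited
baseline and ~10× cheaper.  Feature scaling is per-channel min–max onto
[0, 1], `x_new = (x − x_min)/(x_max − x_min)`; parameters are fit on the
training partition only and reused for test windows (fitting on all data
leaks label-correlated range shifts; `fit_on="all"` is available by passing
explicit parameters).  A degenerate range raises rather than dividing by
zero.

## Activity labelling

Label resolution is one second.  Cadence comes from positive-going zero
crossings of the mean-removed vertical channel in a 5 s centred window with
1 s hop.  Two numerical choices matter:

* **Hysteresis.**  A crossing requires rising above +0.05 g having last been
  below −0.05 g.  Without the band, seated noise crosses zero at the sample
  rate and everything stationary classifies as gait.
* **Refined rate.**  Cadence is `60·(c − 1)/Δt` with `Δt` the span between
  first and last crossing in the window; the plain count formula
  (`c · 60 / window`) has 12 spm granularity at a 5 s window and cannot meet
  a ±2 spm closure.  Both modes are exposed.

Gait classes read the threshold chain strictly: cadence ≤ 100 → other,
100 < cadence < 150 → walk, ≥ 150 → run (exactly 100 is other, exactly 150
is run; the convention is documented so it can be flipped).

Sections come from GPS closest approach to the course waypoints.  Lap
disambiguation uses cumulative *moving* track distance (positions smoothed
11 s; samples slower than 0.5 m/s do not accumulate, so stationary GPS noise
during seated blocks does not inflate distance), self-calibrated to the
track's measured lap length; each waypoint is searched within ±12 % of a lap
around its expected along-course position, and approaches farther than 50 m
are flagged, not assigned.  Slope class per section is the altitude
difference between waypoint-mean altitudes (9 nearest fixes) divided by the
section length, with |grade| < 2 % called flat, majority-voted across laps.
Obstacle seconds come from the course configuration; no waveform-based
obstacle detector is implemented.  Composite activities cross gait class
with slope class (run, run_up, run_down, walk, walk_up, walk_down), with
obstacle override and stationary non-gait seconds labelled sit; they
partition the labelled timeline.

## Fatigue labels

Scores are min–max normalized over their own observations (1 = freshest).
LTLF is the OLS line through normalized (time, score), evaluated on the
250 Hz grid and clipped to [0, 1]; ITI is piecewise-linear interpolation
through every observation with constant extrapolation beyond the ends.  ITI
is continuous across seated/active transitions; the discontinuities visible
in time-ordered prediction traces arise from per-activity concatenation in
windowing, not from the label.  Sensitivity is the squared Pearson
correlation of score against time, optionally per administration phase, with
an optional externally-studentized-residual (>3) outlier exclusion as a
reproducible proxy for manual screening.  The default label source is
dominant-hand finger tapping.

## Windowing and model

All 250 Hz samples of one activity are concatenated in time order and cut
into `D = floor(N/W)` non-overlapping windows (W ∈ {64, 128, 256, 512});
the window label is the mean of the aligned label over the window's source
samples.  Windows may span concatenation seams by default (preserving the
floor(N/W) accounting); a strict mode breaks windows at seams.  The
train/test split is uniformly random at window level with test fraction
0.33 — as specified, although adjacent-window autocorrelation leaks across
such a split; a blocked (contiguous-tail) mode is provided for stricter
evaluation.

The regression model is a 1-D CNN — Conv1D → ReLU → Conv1D → ReLU →
max-pool(2) → flatten → dense → ReLU → dense(1) — trained with Adam
(default rate 1e-3) on mean-absolute-error loss, implemented directly on
numpy with im2col convolutions and analytic backprop (verified against
numerical gradients in the test suite).  Unstated details resolved as:
kernel size 7, stride 1, "same" zero padding, ReLU hidden activations,
linear output, single multi-channel stack over the selected data group
(3 accelerometer channels, 1 ECG channel, or 4 combined).  Named presets:
`sweep` (256/256 filters, dense 128, 50 epochs), `final` (128/128/128,
100 epochs), and `desk` (16/16, dense 32, 100 epochs) — the reduced widths
used for the package's synthetic-session experiments, where the information
content of the generator does not support quarter-million-parameter models;
epochs and batch size (256) follow the larger presets.  Non-finite loss
aborts with a diagnostic.

The hyperparameter sweep enumerates the full 3 data-group × 9 activity ×
4 width grid (108 cells), recording sample and window counts per cell and
marking cells whose activity is missing or shorter than one window as
skipped; a dry-run mode performs the enumeration and accounting without
training.

## Evaluation

Predictions on the test windows of one activity are re-sorted into time
order, averaged over k consecutive windows (default k = 200; one estimate
spans `k·W/250` s — 102.4 s at W = 128), and compared against the window
label at the centre of each k-block (centre alignment minimizes lag bias).
MAE_k is the mean and RAE_k the maximum absolute difference; "range of
absolute error" is read as max|e| because it bounds the error of a future
prediction, with a `span` mode (max − min) preserving the alternative
reading.  Activities with fewer than k test windows are recorded as
excluded rather than evaluated.  Metrics are computed on the test split
only.

## Problem sizes and stochastic checks

The package's reference experiments run on the default four-lap synthetic
session (≈ 2.8 h, ≈ 1 M accelerometer samples, ≈ 2.5 M ECG samples;
walk_up ≈ 1520 s ≈ 3 000 windows at W = 128), with the rolling length
scaled to k = 50 so that several independent rolling estimates fit into the
test split.  The two analysis-level checks are:

* **Trajectory recovery:** the combined accel+ECG model trained on walk_up
  windows (W = 128, 100 epochs, batch 256, `desk` preset) must produce
  rolling test predictions with Spearman ρ ≥ 0.7 against the true
  trajectory and MAE_k below the mean-predictor baseline (≈ 0.25 for a
  uniform-ramp label).
* **Permutation null:** training on shuffled labels (20 epochs, a
  deterministic 1000-window subsample, 5 seeds) must give test MAE
  statistically indistinguishable from the mean predictor — the model finds
  nothing when there is nothing.

## Known limitations

Single synthetic participant model; the generator's fatigue→signal coupling
is simple and monotone, so recovery results bound feasibility, not field
accuracy.  The random window-level split inflates apparent accuracy in the
presence of autocorrelation (use the blocked split to quantify).  Slope
classification degrades for short sections when altimeter noise approaches
the section's relief.  The CNN implementation targets CPU-scale problems;
there is no GPU path.
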