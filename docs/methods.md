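# Methods

## Problem and model

`sparsepose` estimates a full-body pose — the orientations of 23 body
segments — from five inertial sensors worn on the pelvis, both lower arms
and both lower legs. Human poses are highly redundant once global body
orientation is removed, so a regressor can recover the remaining 18 segment
orientations from the five measured ones. All orientations are unit
quaternions in Hamilton convention, scalar first (w, x, y, z), body-to-global,
right-handed frames.

Inputs and outputs are expressed relative to the pelvis: every segment
quaternion is pre-multiplied by the inverse pelvis quaternion. This makes
features and targets invariant to heading and global attitude, shrinking the
learning problem. Two independent networks are trained per estimator: the
forearm pair predicts the 12 upper-body segments (48 outputs) and the
lower-leg pair predicts the 6 lower-body segments (24 outputs); with the 5
measured segments this covers all 23 (5 + 12 + 6).

### Stacked input windows

One example is built around a centre frame `t_i`: the `P` past and `F`
future feature frames at multiples of the sample interval `I` are collected,
giving a stacked input length `SIL = P + 1 + F` with inter-frame spacing
`Δt = I/fs`. The shallow stacked-input network (SINN) receives the flat
`(D·SIL,)` vector; the recurrent baseline receives the same data as a
`(D, SIL)` sequence. The window is paired with the pose target at `t_i`
alone. Using future frames delays the estimate by the acquisition delay
`F·I/fs` — 67 ms for the default `P=F=I=2` at 60 Hz. Incomplete windows at
sequence boundaries are dropped, never padded: padding would fabricate
sensor data. Frames are stacked oldest-first (an arbitrary but fixed
convention), left limb before right.

### Features

Per frame and body half, the base features are the two pelvis-relative limb
quaternions (8 values). Optionally, sensor accelerations add 6 more: each
sensor's specific force is rotated to the global frame with that sensor's
orientation, the pelvis sensor's global acceleration is subtracted, and the
difference is rotated into the pelvis frame. The accelerometer model is
specific force (gravity reaction included, sensor frame): under this model
the subtraction cancels gravity *exactly*, and also cancels any common-mode
(whole-body) acceleration. The sensor frame is assumed to coincide with the
segment frame (no mounting misalignment).

Quaternion sequences are canonicalized for the q/−q double cover: the first
frame is mapped to the w ≥ 0 hemisphere and later frames are sign-flipped
whenever their dot product with the previous frame is negative. Without
this, component-wise regression targets jump sign mid-sequence and corrupt
both training and the jerk metric.

### Networks

* **SINN** — fully connected, 2 hidden layers of 256 rectified units
  (configurable). Fit with Adam (learning rate 1e−3, batch 128), mean
  squared error on raw quaternion components, early stopping with patience
  10 on one held-out training subject (a fixed 10 % tail split when only one
  subject is available). Implemented over scikit-learn's `MLPRegressor`,
  driven one epoch at a time so the subject-held-out early stopping and
  best-epoch weight restore are explicit.
* **RNN baseline** — 2 bidirectional LSTM layers of 128 memory cells per
  direction, dropout 0.2 between layers, linear readout at the window's
  centre step, same optimizer settings. Implemented directly in numpy
  (forward pass, backpropagation through time, Adam); the analytic
  gradients are checked against central finite differences in the test
  suite. The SINN has ~6× fewer parameters than this baseline at the
  default sizes.

Predicted 4-tuples are renormalized to unit quaternions; an exactly-zero
output is replaced by the identity with a logged warning. One integer seed
controls weight initialization, batch order, dropout and the validation
subject choice; training is bit-reproducible given the seed.

### Metrics

Joint positions come from forward kinematics over an anthropometric
skeleton: per-segment origin offsets are fixed fractions of stature taken
from classical segment-proportion tables (head-to-toe chain ≈ 1.04 ×
stature). Only relative errors matter for comparing estimators, so this
proportional model replaces any subject-specific calibration. Positions are
computed in the pelvis frame with the pelvis at the origin, making both
metrics invariant to global body pose.

* **Mean joint position error** (m): per frame, the Euclidean distance
  between true and estimated joint positions averaged over the 23 joints.
* **Joint jerk error** (m/s³): jerk is the third time derivative of joint
  position, computed with a single five-point central stencil
  `[p(t+2h) − 2p(t+h) + 2p(t−h) − p(t−2h)]/(2h³)`, `h = 1/fs` at the 60 Hz
  working rate. The stencil is exact on cubic trajectories and O(h²)
  accurate in general — both properties are asserted in tests. A series of
  n frames yields n − 4 jerk frames. The error is the per-frame
  mean-over-joints norm of the jerk difference.

Poses are sign-canonicalized before forward kinematics, and forward
kinematics itself is invariant to quaternion sign, so q/−q mismatches never
inflate errors.

Evaluation is subject-wise k-fold cross-validation: each fold holds out one
subject entirely; normalization constants and early stopping use training
subjects only (verified by a hash-comparison leakage test). Every fold also
scores a constant-mean-pose baseline (predict the training-set mean target
everywhere) as the reference a useful estimator must beat. Summaries report
mean ± std over folds and per-activity medians.

## Synthetic data generator

The generator emulates the structure of a multi-subject inertial motion
study: several subjects, activity classes of differing dynamics, 23-segment
kinematics synthesized at 240 Hz and decimated by 4 to 60 Hz (plain
decimation, no filtering — quaternions cannot be low-pass filtered
component-wise without leaving the unit sphere).

Joint angles are sums of harmonics of a shared per-trial stride phase. The
coordination pattern — which joint leads which, by what phase lag, and the
harmonic phase offsets — is fixed per activity class, because that shared
inter-joint structure *is* the redundancy a sparse-sensor estimator
exploits; subjects differ in fundamental frequency, stature, a whole-body
excursion factor (±15 %) and mild per-joint amplitude/phase jitter, drawn
once per subject so subject-wise cross-validation is meaningful. Within a
trial, tempo and whole-body excursion drift slowly (±25 %, 10–30 s
periods), emulating protocols whose trials mix intensities (walk → jog →
sprint); this also means each subject covers a band of dynamics, so a
held-out subject's feature magnitudes — in particular the acceleration
magnitudes, which scale with amplitude × frequency² — lie inside the
training distribution rather than requiring extrapolation. Pelvis rotation,
pelvic list, the vertical bob and (for sports) ballistic vertical
excursions are all phase-locked to the stride phase with class-level lags,
as in real locomotion; the neck and head counter-rotate against pelvic
list (head stabilization). Classes:

* `gait` — cyclic, fundamental 0.85–1.05 Hz, contralateral anti-phase
  arm/leg swing, forward pelvis progression with double-support bobbing;
* `sports` — fundamental 1.3–1.7 Hz with ~1.9× gait's excursions (≥ 2×
  gait's velocity scale) and ballistic vertical pelvis excursions;
* `adl` — fundamental 0.28–0.42 Hz (≤ 0.5× gait's), ~0.55× excursions,
  near-stationary pelvis.

Mean absolute joint jerk therefore orders sports > gait > adl by
construction. Sensor accelerations are derived, not drawn: global sensor
positions (pelvis trajectory + forward kinematics) are differentiated with
a second central difference, gravity (0, 0, −9.81) m/s² is subtracted, and
the result is rotated into the sensor frame — exactly what an ideal
accelerometer reports. Measurement noise is applied last: small random
rotations (0.5° std, the orientation accuracy typical of commercial IMUs)
on every segment quaternion and 0.2 m/s² white noise on accelerations.
Smooth low-frequency joint-angle wander (0.02 rad, < 0.15 Hz) adds
irreducible per-joint variability.

What the generator does **not** model: ground contact and foot placement,
soft-tissue artefacts, sensor-to-segment misalignment, magnetometer
disturbances, non-stationary activity switching within a trial. Passing
tests on this data show the pipeline is correct and that the estimators
recover learnable redundancy; they do not certify error magnitudes on real
human motion.

## Problem sizes used in tests

Test problem sizes are the package's own choices for a desk-scale study:
the cross-validation recovery check uses 6 subjects × 60 s of gait at 60 Hz
(six-fold CV, ~18 k training windows per fold); trend checks (window length
vs jerk error, acceleration features on the high-dynamics class) use the
same 6 × 60 s datasets with a single held-out subject, averaged over 3
dataset seeds; the recurrent-vs-shallow smoothness comparison uses 3
subjects × 20 s; unit tests use seconds-long sequences. The mean-pose
baseline ratio achieved by the SINN in the recovery check is ~0.1, far
below the 0.5 acceptance bar.

## Numerical choices and edge cases

* Unit-norm tolerances: 1e−9 for algebraic post-conditions, 1e−6 for
  accepting input quaternions, 1e−3 for file validation (strict mode
  rejects; lenient mode renormalizes).
* Hemisphere ties (w = 0) are broken by requiring the first nonzero
  component to be non-negative.
* Windows shorter than the span `(P+F)·I` produce an empty sample list with
  a logged warning, not an error.
* The standardizer guards zero-variance features (scale 1), relevant for
  the constant pelvis-relative pelvis entry.
* Down-sampling keeps indices {0, k, 2k, …}; fs divides exactly.
* LSTM gates are clipped at ±60 before the logistic to avoid overflow; the
  forget gate starts at bias 1.

## Known limitations

* The anthropometric skeleton is an average-proportions model; absolute
  position errors on real data would depend on subject-specific segment
  lengths.
* The recurrent baseline re-runs its window per output frame (sliding
  window) rather than streaming state across frames.
* Harmonic motion is far more predictable than real human movement; error
  magnitudes on synthetic data are optimistic and only *relative*
  comparisons (between estimators, window configurations, feature sets)
  transfer qualitatively.
* BVH import fills unmapped segments with the identity orientation and
  flags them; it does not retarget skeletons.
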