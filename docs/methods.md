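# Methods

This note documents the models, conventions and numerical choices behind
`balancemocap`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate.

## Sensing model and synchronization

The platform delivers two 9-DoF IMU streams (head, waist: accelerometer
m/s², gyroscope deg/s, magnetometer a.u.), two insole streams (16 pressure
channels in N/cm² plus 3-axis accel/gyro) at a nominal 100 Hz, and
optionally 30 fps RGB-D frames. Timestamps are receiver-clock ("global
clock") annotations; BLE transport loses on the order of 1 % of samples.

Repair resamples each stream onto a uniform grid spanning its observed
time span (`floor(span·rate) + 1` samples) with a cubic spline through the
received samples. A gap larger than 1.5× the nominal period is treated as
loss rather than jitter. Cubic interpolation of a band-limited signal at
~1 % single-sample loss reconstructs to ~1e-7 absolute error (measured by
the repair oracle); the spline can overshoot at sharp load transients, so
pressure channels are clipped at zero, their physical floor. A session is
the set of repaired streams cropped to their common overlap (≥ 1 s
required); camera frames are never resampled, only timestamp-matched.
Processing windows (`timeinterval`, default 2000 ms, configurable — no
canonical value exists) partition the grid without overlap; a trailing
partial window is flagged and skipped by the online evaluator.

## Orientation

Attitude per IMU is estimated by a 7-state extended Kalman filter: unit
quaternion plus gyroscope bias. Prediction integrates the bias-corrected
gyro (body-frame rotation-vector exponential); the update observes the
normalized accelerometer direction against world gravity and the
normalized magnetometer direction against a reference field vector taken
from the first sample after tilt alignment — so yaw is referenced to the
subject's initial heading and no declination model is needed.
Accelerometer-as-gravity assumes quasi-static linear acceleration, which
holds for the head/waist placements in these exercises but would not for
e.g. running. Measurement noise defaults (0.35 / 0.5 on unit vectors)
weight the gyro heavily over short horizons; a complementary filter is
available behind the same interface for robustness comparisons.

Euler convention, stated prominently because every downstream "plane"
depends on it: **intrinsic z-y-x** (yaw, then pitch, then roll), world
frame x-east / y-north / z-up, angles in degrees, yaw positive
counter-clockwise from above. Angles are unwrapped (the "full-circle"
correction: congruent mod 360, first sample fixed, successive differences
< 180°), so they are unbounded; rates are the discrete time derivative of
the unwrapped angles. Samples with |pitch| > 85° are flagged as
gimbal-proximal rather than rejected — steep pitch occurs in bending
exercises. With exact (simulator-generated) inputs the filter tracks a
single-axis rotation within well under 2° RMS of direct quaternion
integration.

## Head movement

Per window and plane: unwrap → zero-phase 2nd-order Butterworth low-pass →
prominent local extrema → adjacent min–max pairs → per-pair range and
speed. Choices:

* **Cutoff.** Voluntary head movement lives below ~3 Hz; the default
  cutoff is 5 Hz. A cutoff at or above Nyquist is rejected with an error
  naming the fallback (at 100 Hz sampling a 50 Hz 2nd-order low-pass is
  degenerate). Zero-phase (forward-backward) filtering is used so extremum
  timestamps are unlagged; the design cutoff is pre-warped by
  (√2−1)^(−1/4) so the two-pass cascade still sits at −3 dB at the nominal
  cutoff.
* **Extrema.** Prominence ≥ 5°, separation ≥ 150 ms: suppresses
  tremor-scale ripple while keeping ~2 Hz vestibular head turns.
  Alternation is enforced by keeping the more extreme of consecutive
  same-kind extrema (earlier on exact ties).
* **Pairing.** With alternation enforced, minimum-time-distance pairing
  reduces to consecutive opposite-kind couples (a zig-zag; inner extrema
  belong to two pairs).
* **Repetition** = one min–max pair, i.e. one extreme-to-extreme sweep
  (half a full cycle); `turn_rate` is sweeps per second. A 0.5 Hz sinusoid
  therefore has an asymptotic turn rate of 1.0 /s, and a finite window of
  duration D yields (2fD − 1)/D, e.g. 0.917 at D = 12 s — the edge effect,
  not an estimation error.

Because every metric is a difference of *adjacent* extrema, slow gyro
drift cancels: a ramp of r deg/s perturbs a pair's range by at most
r × pair duration (≈ 0.09° at 1 deg/s drift on the reference sinusoid).

## Posture

Posture is evaluated only at the instants the head is most upright (local
maxima of head pitch), exactly as the capture procedure prescribes, not
continuously. Each instant maps to the nearest frame (≤ half frame period
+ 5 ms, earlier frame on ties, otherwise dropped); background is removed
by keeping the depth band ±0.4 m around the configured subject distance
(default 1.85 m, the camera placement) and the largest connected
component; a pluggable landmark provider returns head and waist image
points. The trunk lean is the angle of the waist→head vector to the image
vertical; the label is `upright` iff |lean − baseline| ≤ 10° (no numeric
criterion exists for "upright"; 10° is the package default, configurable),
with the baseline captured from an instructed upright stance. Landmarks
below 0.5 confidence, or instants with no matchable frame, yield
`uncomputable` — a value, not an error — and the per-session uncomputable
fraction is reported.

`classification_metrics` uses the conventional definitions
(precision = TP/(TP+FP), recall = TP/(TP+FN)). On the published 71-case
posture confusion matrix (TN=8, FP=5, FN=7, TP=51) these give accuracy
0.83, precision 0.911, recall 0.879; the source report prints
precision = 0.87 and recall = 0.91, consistent with the two labels having
been swapped there. This package reports the conventional values and
documents the discrepancy rather than reproducing it. The companion study
design (5 subjects × 10 standing + 5 sitting bends = 75; 71 assessable)
implies the 5.33 % uncomputable rate.

## Trunk sway

The stability index is the radius of the quarter-circle enclosing 95 % of
the (|pitch rate|, |roll rate|) points of the waist sensor: the 95th
percentile of the Euclidean norms. **Nearest-rank** (type-1) quantile is
used deliberately — it matches the "smallest radius enclosing ≥ 95 % of
points" reading and makes the index an observed value; interpolating
conventions would differ in the last digit. An axis-wise alternative (max
of per-axis percentiles) was rejected as inconsistent with a circular
quadrant. The index is exactly homogeneous (scaling both series by c
scales it by c) and order-invariant. For isotropic Gaussian angular
velocities with per-axis σ, the norms are Rayleigh(σ) and the index
converges to σ√(−2 ln 0.05) ≈ 2.448 σ, which the acceptance run verifies
within 1 % at n = 10⁵. During walking exercises, samples masked as turns
by the gait module are excluded first. Fewer than 100 retained samples is
an error: a 95 % rank statistic below that is dominated by single points.

## Gait

Straight-walking selection precedes event detection. Per foot, absolute
yaw is the cumulative trapezoidal integral of the insole yaw gyro; a
sliding 2 s window with |Δyaw| > 45° marks a turn (per-foot intervals
OR-combined); accel-magnitude standard deviation < 0.3 m/s² sustained for
≥ 1 s marks a stop. The complement, in runs ≥ 1 s, forms the bouts.

Events come from the summed rearfoot and forefoot pressure clusters of the
configurable 16-sensor layout, with *relative* thresholds (10 % of each
sum's per-bout maximum — robust to subject weight, unlike absolute
N/cm²): heel strike = upward rear crossing, heel rise = downward rear
crossing, toe off = downward fore crossing, flat foot = first sample with
both clusters loaded. Crossing times are linearly interpolated between
samples, giving sub-sample (≪ 10 ms) event timing on clean signals. Cycles
must run heel_strike → flat_foot → heel_rise → toe_off before the next
strike; incomplete cycles are dropped. A **full-scale step** is a complete
cycle inside a bout excluding the bout's first and last cycle
(initiation/termination half-steps). Edge cycles are kept in the table,
flagged, and still participate in stance-overlap bookkeeping — otherwise
single-support times of interior cycles next to an excluded edge stance
would be biased high by exactly one missing double-support interval.

Parameters (means over full-scale cycles only): stride = Δ between
same-foot heel strikes, step = Δ between opposite-foot strikes, double
support = each left/right stance overlap, single support = stance minus
its overlap portions, cadence = 60/mean step time (steps/min; strides/min
rejected as nonstandard). Double support is reported both in seconds and
as % of stride. The center of pressure is the pressure-weighted centroid
of the sensor coordinates (the standard plantar-pressure estimator; the
capture procedure names CoP without defining it), reported where the
summed pressure exceeds a contact threshold (0.5 N/cm² default); gaps, not
errors, where the foot is airborne. Max pressure per step is the largest
single-sensor value during the stance.

## Assessment

Online: each completed window's metrics are evaluated against the rule
set; a firing rule emits exactly one message, safety alerts ordered before
correction advice; evaluation is pure (identical inputs → identical
messages) and latency is bounded by one window because only that window's
data are used. Rules are either patient-independent (absolute threshold)
or baseline-dependent (threshold as offset from or ratio of a profile
value); validation — unknown metric, missing baseline key — happens at
load time. The shipped rule file is demonstrative; it does not reproduce
clinically elicited rule content.

Offline: every analytic's per-repetition values are averaged
(`M_t = (1/N) Σ m_i_t`), then
`MS = (1/k) Σ_j (M_j − Mb_j)/(T_j − Mb_j)`. The raw ratio can leave [0, 1]
(performance past target, or worse than baseline); each term is **clamped
to [0, 1] before averaging** — this is the package's reading of the
otherwise unspecified normalization, chosen so MS is a bounded progress
measure with MS = 0 at baseline and MS = 1 at target; the unclamped terms
are stored alongside for research use. The ratio form makes MS invariant
to per-analytic affine rescaling and handles lower-is-better analytics
(T < Mb) without sign special-casing; T = Mb is a configuration error.
Method agreement uses OLS R² plus Bland–Altman bias (mean of x − y, so a
device reading high against reference x shows a negative bias) with
±1.96 sd limits.

## Synthetic data

The simulator is the package's study-conditions generator, not an
afterthought: IMU synthesis is attitude-first (analytic Euler trajectories
→ exact body rates, gravity and field directions by inverse kinematics),
so orientation fusion has an exact oracle; gait synthesis is event-first
(heel strikes on a strict cadence; rear/fore cluster trapezoids with 10 %
ramps drawn around them), so every event time is known analytically at the
crossing the detector defines. Defaults represent the platform: 100 Hz,
1.2 % dropout (observed 1.0–1.3 % BLE loss), gyro noise 0.2 deg/s with a
0.3 deg/s per-run bias, accel noise 0.05 m/s², pressure noise 0.1 N/cm²,
landmark jitter 1 px; walks default to stride 1.2 s and stance fraction
0.6, head turns to 30° at 0.5 Hz, sway to 5 deg/s scale — typical adult
values. Problem sizes in the acceptance run (20 walks of 14 s; 12 s head
windows; 10⁵ sway samples) are chosen as the smallest grids on which the
statistics are stable.

What the simulator does **not** emulate: limb dynamics in the
accelerometers (gravity plus a swing-phase burst and a step-frequency
component stand in for them), magnetic disturbances, soft-tissue artifact,
pathological gait beyond parameter changes, multi-person or occluded
camera scenes. Passing recovery tests therefore demonstrates algorithmic
correctness — event geometry, rank statistics, filter convergence,
bookkeeping — under the platform's noise floor, not clinical validity on
real patients; the original system's human validation (R² against
commercial gait references, expert-rated messages) requires hardware and
subjects and is out of scope here.

## Known limitations

* The EKF linearizes around the current quaternion and normalizes after
  update; it is not a manifold (error-state) filter. For the rates and
  durations of these exercises the difference is far below the 2°
  acceptance band.
* Magnetometer hard/soft-iron calibration is out of scope; the
  initial-heading reference makes yaw relative, which suffices for range
  and repetition metrics but not for absolute heading.
* Turn rejection assumes turns change foot yaw by ≥ 45° within 2 s; very
  slow pivots could evade it (they also barely perturb the metrics).
* Spatial gait parameters (step length, speed) are deliberately absent —
  they would require double-integration of foot acceleration.
* A repetition is a half-cycle; double the `turn_rate` convention must be
  kept in mind when comparing with full-cycle counts.
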