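# balancemocap

Motion capture and exercise assessment for home-based **balance
rehabilitation**. People with vestibular dysfunction perform prescribed
balance exercises (head turns, bends, straight-line walking, quiet stance)
at home, monitored by a small wearable sensing platform: a 9-DoF IMU on the
forehead, one on the waist, a pair of 16-channel pressure insoles (each with
its own accelerometer/gyroscope), and optionally a depth camera. This
package turns those raw streams into the metrics a physiotherapist cares
about and scores each exercise — online, as safety alerts and correction
advice with about one processing window of latency, and offline, as a
scalar motor score summarizing progress.

It is aimed at digital-health and movement-science developers who need a
complete, testable reference pipeline for this class of system, including a
synthetic-data generator with ground truth for every metric.

## What it computes

| Stage | Method |
|---|---|
| Stream repair & sync | common 100 Hz grid, cubic interpolation of BLE sample loss (~1 %), windowing |
| Orientation | 7-state EKF (attitude quaternion + gyro bias) fusing accel/gyro/magnetometer → intrinsic z-y-x Euler angles (deg), unwrapped |
| Head movement | zero-phase 2nd-order Butterworth → prominent extrema → adjacent min–max pairs; per pair range `|max−min|` and speed `range/Δt`; repetition = one sweep (drift-immune by construction) |
| Posture | at head-pitch maxima (most-upright instants): nearest depth frame → background removal → head/waist landmarks → trunk lean vs. calibrated upright baseline |
| Trunk sway | radius of the quarter-circle enclosing 95 % of the (&#124;pitch-rate&#124;, &#124;roll-rate&#124;) points of the waist sensor (nearest-rank 95th percentile of the norms, deg/s) |
| Gait | turn/stop rejection from insole IMUs (integrated yaw > 45°/2 s; accel-magnitude std < 0.3 m/s² for ≥ 1 s) → rear/forefoot pressure-cluster threshold crossings → heel strike / flat foot / heel rise / toe off → stride & step time, double & single support, cadence, pressure-weighted center of pressure |
| Assessment | rule engine (patient-independent and baseline-relative thresholds) and motor score `MS = (1/k) Σ_j (M_j − Mb_j)/(T_j − Mb_j)`, each term clamped to [0, 1] |

## Worked example

Simulate a 16 s straight walk (stride period 1.2 s, stance fraction 0.6,
default sensor noise, 1.2 % BLE loss) and run the capture pipeline:

```bash
balancemocap simulate --exercise walk_straight --duration 16 --seed 7 --out session
balancemocap capture --session session --out metrics
```

`metrics/gait.json` then contains (abridged):

```json
{
  "stride_time_s":    {"mean": 1.20003, "sd": 0.00077},
  "step_time_s":      {"mean": 0.59999, "sd": 0.00067},
  "double_support_s": {"mean": 0.10562, "sd": 0.00056},
  "single_support_s": {"mean": 0.49440, "sd": 0.00057},
  "cadence_steps_per_min": 100.0009,
  "n_strides": {"left": 7, "right": 7}
}
```

The simulator's ground truth for this session is stride 1.2 s, step 0.6 s,
cadence 100 steps/min — recovered here to within 0.03 ms, 0.005 ms and
0.001 steps/min. Seven strides per foot survive full-scale selection: the
pipeline discards the standing pads at either end (accelerometer
quiescence) and each bout's first and last cycle (half-steps). The same
metrics directory also holds `metrics.json` (head/sway summary values),
`gait_events.csv` and `window_metrics.csv` for the online rule engine.

Scoring against a patient profile:

```bash
balancemocap assess --session session \
    --rules src/balancemocap/config/demo_rules.yaml \
    --profile profile.json --out assessment.json
balancemocap report --assessment assessment.json
```

prints the motor score in [0, 1] (1 = every analytic at its target) and the
ordered message log (safety alerts before correction advice). The shipped
rule thresholds are demonstrative, not clinical content.

From Python, the same pipeline is three calls:

```python
from balancemocap import ScenarioSpec, simulate, capture_session

session, truth = simulate(ScenarioSpec("walk_straight", duration_s=16.0, seed=7))
result = capture_session(session)
print(result.gait.to_dict()["stride_time_s"])   # {'mean': 1.20003..., 'sd': 0.00077...}
```

## Layout

```
src/balancemocap/
  sync_io.py      sessions, repair, windowing, session directory format
  orientation.py  quaternion EKF + complementary fallback, Euler conversion
  head_kinematics.py  filtering, extrema, min–max pairing, summaries
  posture.py      pitch peaks, frame matching, depth masking, lean labels
  sway.py         95 % quadrant index
  gait.py         turn/stop rejection, gait events, parameters, CoP
  assessment.py   rule engine, motor score, agreement statistics
  simdata.py      scenario simulator with ground truth
  pipeline.py     offline/online composition
  cli.py          balancemocap {simulate,capture,assess,benchmark,report}
  config/         insole layout, demonstrative rules
docs/methods.md   model, conventions, parameter rationale, limitations
```
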