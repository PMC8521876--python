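"""Synthetic sensor sessions with ground truth for every metric.

No public dataset exists for the sensing platform (two 9-DoF IMUs, two
16-channel pressure insoles, a 30 fps depth camera), so this module
generates sessions that exercise every pipeline branch, with ground truth
known *by construction*:

* IMU synthesis is attitude-first: an analytic Euler-angle trajectory is
  converted to exact body angular rates, gravity and magnetic-field
  directions by inverse kinematics, so orientation fusion has an exact
  oracle.
* Gait synthesis is event-first: heel-strike times are laid down on a
  strict cadence and rear/forefoot cluster pressures are trapezoids drawn
  around them, so every gait event time is known analytically (at the
  10 %-of-peak crossing the detector defines).
* BLE sample loss is emulated by deleting a random fraction of samples
  (defaults to the platform's observed 1.2 % loss) before session repair.

The generators emulate the kinematics and the sensor noise floor of the
platform, not musculoskeletal realism: accelerometers see gravity plus a
swing-phase burst, not limb dynamics, and pathological gait exists only as
parameter changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .orientation import GRAVITY
from .posture import LandmarkPair
from .sway import nearest_rank_quantile
from .sync_io import FrameRef, RawStream, SensorSession, build_session

EXERCISES = (
    "head_turns_yaw",
    "head_turns_pitch",
    "bend_stand",
    "bend_sit",
    "walk_straight",
    "walk_with_turns",
    "quiet_stance",
)

#: world magnetic field direction (north + downward dip), unit-free
MAG_REF = np.array([0.0, 0.88, -0.48])


@dataclass
class NoiseModel:
    """Sensor noise floor; defaults approximate consumer MEMS at 100 Hz."""

    gyro_noise_deg_s: float = 0.2
    gyro_bias_deg_s: float = 0.3       # constant per-run bias, random axis
    accel_noise: float = 0.05          # m/s^2
    mag_noise: float = 0.01
    pressure_noise: float = 0.1        # N/cm^2
    landmark_noise_px: float = 1.0

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class ScenarioSpec:
    exercise: str
    duration_s: float = 20.0
    seed: int = 0
    rate: float = 100.0
    # head exercises
    head_amplitude_deg: float = 30.0
    head_frequency_hz: float = 0.5
    # bends / posture
    n_bends: int = 5
    bend_angle_deg: float = 40.0
    bend_trunk_lean_deg: float = 45.0
    residual_lean_deg: float = 20.0    # trunk lean left when not returning upright
    return_probability: float = 0.6    # chance a bend returns to upright
    frame_rate: float = 30.0
    # gait
    stride_period_s: float = 1.2
    stance_fraction: float = 0.6
    pressure_peak: float = 12.0        # N/cm^2 per rearfoot sensor at full load
    turn_duration_s: float = 2.0
    # sway
    sway_scale_deg_s: float = 5.0
    # acquisition
    dropout_rate: float = 0.012        # BLE loss, observed 1.0-1.3 %

    def __post_init__(self) -> None:
        if self.exercise not in EXERCISES:
            raise ValueError(f"unknown exercise {self.exercise!r}")
        for name in ("duration_s", "rate", "head_frequency_hz", "stride_period_s", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout_rate < 0.05:
            raise ValueError("dropout_rate must lie in [0, 0.05)")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """True values the pipeline should recover, internally consistent."""

    exercise: str
    head_mean_range_deg: float | None = None
    head_mean_speed_deg_s: float | None = None
    head_turn_rate_per_s: float | None = None
    posture_labels: list[bool] = field(default_factory=list)  # per bend: returned upright?
    bend_peak_times: list[float] = field(default_factory=list)
    landmarks: list[LandmarkPair] = field(default_factory=list)
    trunk_lean_series: tuple[np.ndarray, np.ndarray] | None = None  # (t, lean_deg)
    events: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    stride_time_s: float | None = None
    step_time_s: float | None = None
    cadence_steps_per_min: float | None = None
    double_support_s: float | None = None
    single_support_s: float | None = None
    turn_intervals: list[tuple[float, float]] = field(default_factory=list)
    sway_radius_deg_s: float | None = None


# ---------------------------------------------------------------------------
# inverse kinematics: Euler trajectory -> exact IMU signals


def euler_rates_to_body_rates(
    yaw_deg: np.ndarray, pitch_deg: np.ndarray, roll_deg: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Body angular rates (deg/s, (n,3)) of an intrinsic z-y-x trajectory."""
    psi, th, ph = (np.deg2rad(a) for a in (yaw_deg, pitch_deg, roll_deg))
    dpsi, dth, dph = (np.gradient(a, t) for a in (psi, th, ph))
    p = dph - dpsi * np.sin(th)
    q = dth * np.cos(ph) + dpsi * np.cos(th) * np.sin(ph)
    r = -dth * np.sin(ph) + dpsi * np.cos(th) * np.cos(ph)
    return np.rad2deg(np.column_stack([p, q, r]))


def _rotmats(yaw_deg, pitch_deg, roll_deg) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    ang = np.column_stack([yaw_deg, pitch_deg, roll_deg])
    return Rotation.from_euler("ZYX", ang, degrees=True).as_matrix()


def imu_from_euler(
    t: np.ndarray,
    yaw_deg: np.ndarray,
    pitch_deg: np.ndarray,
    roll_deg: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Exact accel/gyro/mag channels for an attitude-only trajectory."""
    R = _rotmats(yaw_deg, pitch_deg, roll_deg)  # body->world
    accel = np.einsum("nij,j->ni", R.transpose(0, 2, 1), np.array([0.0, 0.0, GRAVITY]))
    mag = np.einsum("nij,j->ni", R.transpose(0, 2, 1), MAG_REF)
    gyro = euler_rates_to_body_rates(yaw_deg, pitch_deg, roll_deg, t)
    n = t.size
    bias_dir = rng.standard_normal(3)
    bias_dir /= max(np.linalg.norm(bias_dir), 1e-12)
    gyro = gyro + noise.gyro_noise_deg_s * rng.standard_normal((n, 3))
    gyro = gyro + noise.gyro_bias_deg_s * bias_dir
    accel = accel + noise.accel_noise * rng.standard_normal((n, 3))
    mag = mag + noise.mag_noise * rng.standard_normal((n, 3))
    return {
        "ax": accel[:, 0], "ay": accel[:, 1], "az": accel[:, 2],
        "gx": gyro[:, 0], "gy": gyro[:, 1], "gz": gyro[:, 2],
        "mx": mag[:, 0], "my": mag[:, 1], "mz": mag[:, 2],
    }


def _apply_dropout(stream: RawStream, rate: float, rng: np.random.Generator) -> RawStream:
    """Randomly delete interior samples, emulating BLE loss."""
    n = stream.timestamps.size
    if rate <= 0 or n < 8:
        return stream
    k = int(round(rate * n))
    if k == 0:
        return stream
    candidates = np.arange(2, n - 2)
    drop = rng.choice(candidates, size=min(k, candidates.size), replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    return RawStream(
        stream.device_id,
        stream.timestamps[keep],
        {c: v[keep] for c, v in stream.channels.items()},
        stream.nominal_rate,
    )


def _smooth_band(rng: np.random.Generator, n: int, fs: float, fc: float, sigma: float) -> np.ndarray:
    """Band-limited Gaussian series with target standard deviation sigma."""
    if sigma == 0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    b, a = butter(2, fc, btype="low", fs=fs)
    y = filtfilt(b, a, x)
    s = y.std()
    return y * (sigma / s) if s > 0 else y


def _raised_cosine_pulse(t: np.ndarray, t0: float, dur: float) -> np.ndarray:
    """0 -> 1 -> 0 smooth bump supported on [t0, t0 + dur]."""
    x = (t - t0) / dur
    y = np.zeros_like(t)
    sel = (x >= 0) & (x <= 1)
    y[sel] = 0.5 * (1 - np.cos(2 * np.pi * x[sel]))
    return y


def _trapezoid(t: np.ndarray, t0: float, t1: float, t2: float, t3: float) -> np.ndarray:
    """0, ramp up [t0,t1], plateau 1 [t1,t2], ramp down [t2,t3], 0."""
    y = np.zeros_like(t)
    up = (t >= t0) & (t < t1)
    y[up] = (t[up] - t0) / (t1 - t0)
    y[(t >= t1) & (t <= t2)] = 1.0
    dn = (t > t2) & (t <= t3)
    y[dn] = (t3 - t[dn]) / (t3 - t2)
    return y


# ---------------------------------------------------------------------------
# per-exercise signal builders


def _static_insoles(t, spec, noise, rng, load=6.0) -> dict[str, dict[str, np.ndarray]]:
    out = {}
    for foot in ("left", "right"):
        ch = {}
        for i in range(16):
            ch[f"p{i:02d}"] = np.clip(
                load + noise.pressure_noise * rng.standard_normal(t.size), 0, None
            )
        ch.update(
            Ax=noise.accel_noise * rng.standard_normal(t.size),
            Ay=noise.accel_noise * rng.standard_normal(t.size),
            Az=GRAVITY + noise.accel_noise * rng.standard_normal(t.size),
            Gx=noise.gyro_noise_deg_s * rng.standard_normal(t.size),
            Gy=noise.gyro_noise_deg_s * rng.standard_normal(t.size),
            Gz=noise.gyro_noise_deg_s * rng.standard_normal(t.size),
        )
        out[foot] = ch
    return out


def _waist_sway(t, spec, noise, rng, sigma=None):
    """Waist Euler trajectory whose pitch/roll rates are band-limited noise
    with scale sigma (deg/s); returns (yaw, pitch, roll, pv, pr)."""
    sigma = spec.sway_scale_deg_s if sigma is None else sigma
    fs = spec.rate
    pv = _smooth_band(rng, t.size, fs, 2.0, sigma)
    pr = _smooth_band(rng, t.size, fs, 2.0, sigma)
    dt = 1.0 / fs
    pitch = np.cumsum(pv) * dt
    roll = np.cumsum(pr) * dt
    return np.zeros_like(t), pitch, roll, pv, pr


def _build_head_turns(spec: ScenarioSpec, t, rng, noise) -> tuple[dict, GroundTruth]:
    A, f = spec.head_amplitude_deg, spec.head_frequency_hz
    angle = A * np.sin(2 * np.pi * f * t)
    zeros = np.zeros_like(t)
    if spec.exercise == "head_turns_yaw":
        yaw, pitch, roll = angle, zeros, zeros
    else:
        yaw, pitch, roll = zeros, angle, zeros
    head = imu_from_euler(t, yaw, pitch, roll, noise, rng)
    wy, wp, wr, pv, pr = _waist_sway(t, spec, noise, rng, sigma=1.0)
    waist = imu_from_euler(t, wy, wp, wr, noise, rng)
    truth = GroundTruth(
        exercise=spec.exercise,
        head_mean_range_deg=2 * A,
        head_mean_speed_deg_s=4 * A * f,   # 2A per half-period 1/(2f)
        head_turn_rate_per_s=2 * f,        # extreme-to-extreme sweeps per second
    )
    streams = {"head_imu": head, "waist_imu": waist}
    streams.update({f"insole_{k}": v for k, v in _static_insoles(t, spec, noise, rng).items()})
    return streams, truth


def _build_bend(spec: ScenarioSpec, t, rng, noise) -> tuple[dict, GroundTruth, list[FrameRef]]:
    n_b = spec.n_bends
    bend_dur = 3.0
    period = (spec.duration_s - 2.0) / n_b
    starts = [1.0 + k * period for k in range(n_b)]
    returned = rng.random(n_b) < spec.return_probability
    if n_b >= 2:  # guarantee both outcomes appear
        returned[0] = True
        returned[1] = False

    pitch = np.zeros_like(t)
    lean = np.zeros_like(t)  # trunk lean, deg from vertical
    peak_times: list[float] = []
    for k, t0 in enumerate(starts):
        pitch -= spec.bend_angle_deg * _raised_cosine_pulse(t, t0, bend_dur)
        # compensatory extension right after recovery marks the "most
        # upright" instant (and keeps the peak prominent enough to detect)
        t_over = t0 + bend_dur + 0.2
        pitch += 8.0 * _raised_cosine_pulse(t, t_over, 0.8)
        peak_times.append(t_over + 0.4)
        lean += spec.bend_trunk_lean_deg * _raised_cosine_pulse(t, t0, bend_dur)
        if not returned[k]:
            until = starts[k + 1] if k + 1 < n_b else spec.duration_s
            hold = (t > t0 + bend_dur) & (t < until)
            ramp = np.clip((t - (t0 + bend_dur)) / 0.3, 0, 1)
            lean[hold] += spec.residual_lean_deg * ramp[hold]

    zeros = np.zeros_like(t)
    head = imu_from_euler(t, zeros, pitch, zeros, noise, rng)
    waist = imu_from_euler(t, zeros, lean * 0.8, zeros, noise, rng)

    frame_t = np.arange(0, spec.duration_s, 1.0 / spec.frame_rate)
    waist_px = np.array([320.0, 360.0])
    trunk_len = 150.0
    lean_at = np.interp(frame_t, t, lean)
    landmarks = []
    for ft, lv in zip(frame_t, lean_at):
        ang = np.deg2rad(lv)
        head_px = waist_px + trunk_len * np.array([np.sin(ang), -np.cos(ang)])
        jitter = noise.landmark_noise_px * rng.standard_normal(2)
        landmarks.append(
            LandmarkPair(float(ft), tuple(head_px + jitter), tuple(waist_px + jitter * 0.3))
        )
    frames = [FrameRef(float(ft)) for ft in frame_t]
    truth = GroundTruth(
        exercise=spec.exercise,
        posture_labels=[bool(r) for r in returned],
        bend_peak_times=peak_times,
        landmarks=landmarks,
        trunk_lean_series=(t.copy(), lean),
    )
    streams = {"head_imu": head, "waist_imu": waist}
    streams.update({f"insole_{k}": v for k, v in _static_insoles(t, spec, noise, rng).items()})
    return streams, truth, frames


def _stance_pressures(
    t: np.ndarray,
    hs_nominal: list[float],
    stance_s: float,
    spec: ScenarioSpec,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, list[float]], np.ndarray]:
    """16-channel pressure for one foot given nominal stance start times.

    Returns (channels, true event times, swing-burst envelope).  True event
    times are the 10 %-of-peak crossings of the trapezoid geometry:
    rear cluster active over [0, 0.65 S], fore over [0.25 S, S] with 10 %-S
    ramps, all offsets relative to the nominal stance start.
    """
    S = stance_s
    ramp = 0.1 * S
    rear_env = np.zeros_like(t)
    fore_env = np.zeros_like(t)
    events = {k: [] for k in ("heel_strike", "flat_foot", "heel_rise", "toe_off")}
    swing = np.zeros_like(t)
    for t0 in hs_nominal:
        rear_env += _trapezoid(t, t0, t0 + ramp, t0 + 0.55 * S, t0 + 0.65 * S)
        fore_env += _trapezoid(t, t0 + 0.25 * S, t0 + 0.35 * S, t0 + 0.90 * S, t0 + S)
        events["heel_strike"].append(t0 + 0.1 * ramp)
        events["flat_foot"].append(t0 + 0.25 * S + 0.1 * ramp)
        events["heel_rise"].append(t0 + 0.55 * S + 0.9 * ramp)
        events["toe_off"].append(t0 + 0.90 * S + 0.9 * ramp)
        # swing-phase accelerometer burst between this toe-off and next strike
        swing += _raised_cosine_pulse(t, t0 + S, max(spec.stride_period_s - S, 0.2) * 0.9)
    peak = spec.pressure_peak
    channels: dict[str, np.ndarray] = {}
    rear_w = [1.0, 1.0, 0.9, 0.9, 0.8]
    mid_w = [0.25, 0.25, 0.2, 0.2]
    fore_w = [0.8, 0.9, 0.8, 0.9, 0.9, 0.7, 0.7]
    for i in range(16):
        if i < 5:
            base = peak * rear_w[i] * rear_env
        elif i < 9:
            base = peak * mid_w[i - 5] * 0.5 * (rear_env + fore_env)
        else:
            base = peak * fore_w[i - 9] * fore_env
        channels[f"p{i:02d}"] = np.clip(
            base + noise.pressure_noise * rng.standard_normal(t.size), 0, None
        )
    return channels, events, swing


def _build_walk(spec: ScenarioSpec, t, rng, noise) -> tuple[dict, GroundTruth]:
    T = spec.stride_period_s
    S = spec.stance_fraction * T
    pad = 1.5
    with_turn = spec.exercise == "walk_with_turns"
    turn_dur = spec.turn_duration_s
    walk_time = spec.duration_s - 2 * pad - (turn_dur if with_turn else 0.0)
    if with_turn:
        half = walk_time / 2
        seg_bounds = [(pad, pad + half), (pad + half + turn_dur, spec.duration_s - pad)]
        turn_start = pad + half
    else:
        seg_bounds = [(pad, spec.duration_s - pad)]
        turn_start = None

    hs = {"left": [], "right": []}
    for a, b in seg_bounds:
        k = 0
        while a + k * T + S <= b:
            hs["left"].append(a + k * T)
            if a + k * T + T / 2 + S <= b:
                hs["right"].append(a + k * T + T / 2)
            k += 1

    # the foot accelerometer is never quiet while walking: a continuous
    # step-frequency component spans the whole locomotion interval (turns
    # included), on top of per-swing bursts
    walk_env = _trapezoid(t, pad - 0.3, pad, spec.duration_s - pad, spec.duration_s - pad + 0.3)
    body = 1.2 * walk_env * np.sin(2 * np.pi * (2.0 / T) * t)

    events: dict[str, dict[str, list[float]]] = {}
    streams: dict[str, dict[str, np.ndarray]] = {}
    for foot in ("left", "right"):
        channels, ev, swing = _stance_pressures(t, hs[foot], S, spec, noise, rng)
        events[foot] = ev
        gz = noise.gyro_noise_deg_s * rng.standard_normal(t.size)
        if with_turn:
            # raised-cosine yaw-rate bump integrating to 180 degrees
            gz = gz + (180.0 / (0.5 * turn_dur)) * _raised_cosine_pulse(t, turn_start, turn_dur)
        burst = 3.0 * swing * np.sin(2 * np.pi * 6.0 * t) + body
        channels.update(
            Ax=burst + noise.accel_noise * rng.standard_normal(t.size),
            Ay=0.5 * burst + noise.accel_noise * rng.standard_normal(t.size),
            Az=GRAVITY + 0.8 * burst + noise.accel_noise * rng.standard_normal(t.size),
            Gx=noise.gyro_noise_deg_s * rng.standard_normal(t.size),
            Gy=noise.gyro_noise_deg_s * rng.standard_normal(t.size),
            Gz=gz,
        )
        streams[f"insole_{foot}"] = channels

    zeros = np.zeros_like(t)
    head = imu_from_euler(t, zeros, zeros, zeros, noise, rng)
    wy, wp, wr, pv, pr = _waist_sway(t, spec, noise, rng)
    waist = imu_from_euler(t, wy, wp, wr, noise, rng)
    streams.update({"head_imu": head, "waist_imu": waist})

    # truth parameters from the constructed event times (internally consistent)
    hs_l, hs_r = events["left"]["heel_strike"], events["right"]["heel_strike"]
    step = sorted([(x, "L") for x in hs_l] + [(x, "R") for x in hs_r])
    step_times = [b[0] - a[0] for a, b in zip(step[:-1], step[1:]) if a[1] != b[1]
                  and b[0] - a[0] < T]
    stance_dur = events["left"]["toe_off"][0] - events["left"]["heel_strike"][0]
    double = 2 * (stance_dur - T / 2)  # two overlaps per stride of T with offset T/2
    truth = GroundTruth(
        exercise=spec.exercise,
        events=events,
        stride_time_s=T,
        step_time_s=float(np.mean(step_times)),
        cadence_steps_per_min=60.0 / (T / 2),
        double_support_s=double / 2,       # per transition
        single_support_s=stance_dur - double,
        turn_intervals=[(turn_start, turn_start + turn_dur)] if with_turn else [],
        sway_radius_deg_s=float(nearest_rank_quantile(np.hypot(pv, pr), 0.95)),
    )
    return streams, truth


def _build_quiet_stance(spec: ScenarioSpec, t, rng, noise) -> tuple[dict, GroundTruth]:
    wy, wp, wr, pv, pr = _waist_sway(t, spec, noise, rng)
    waist = imu_from_euler(t, wy, wp, wr, noise, rng)
    head = imu_from_euler(t, np.zeros_like(t), np.zeros_like(t), np.zeros_like(t), noise, rng)
    streams = {"head_imu": head, "waist_imu": waist}
    streams.update({f"insole_{k}": v for k, v in _static_insoles(t, spec, noise, rng).items()})
    truth = GroundTruth(
        exercise=spec.exercise,
        sway_radius_deg_s=float(nearest_rank_quantile(np.hypot(pv, pr), 0.95)),
    )
    return streams, truth


# ---------------------------------------------------------------------------
# public API


def simulate(
    spec: ScenarioSpec, noise: NoiseModel | None = None
) -> tuple[SensorSession, GroundTruth]:
    """Generate a full sensor session plus ground truth for one scenario.

    Deterministic given ``spec.seed``; streams pass through dropout and
    session repair, so the returned session satisfies all session
    invariants.
    """
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate)) + 1
    t = np.arange(n) / spec.rate

    frames: list[FrameRef] = []
    if spec.exercise in ("head_turns_yaw", "head_turns_pitch"):
        streams, truth = _build_head_turns(spec, t, rng, noise)
    elif spec.exercise in ("bend_stand", "bend_sit"):
        streams, truth, frames = _build_bend(spec, t, rng, noise)
    elif spec.exercise in ("walk_straight", "walk_with_turns"):
        streams, truth = _build_walk(spec, t, rng, noise)
    else:
        streams, truth = _build_quiet_stance(spec, t, rng, noise)

    raw = [
        _apply_dropout(RawStream(dev, t, ch, spec.rate), spec.dropout_rate, rng)
        for dev, ch in streams.items()
    ]
    session = build_session(
        raw, frames, spec.rate, metadata={"exercise": spec.exercise, "seed": spec.seed}
    )
    return session, truth


def benchmark_suite(
    seed: int = 0, specs: list[ScenarioSpec] | None = None
) -> "pd.DataFrame":
    """Run the full pipeline on a grid of scenarios, truth vs estimate.

    Returns a long-format table (scenario, metric, truth, estimate, error);
    an empty spec list yields an empty table.
    """
    import pandas as pd

    from .pipeline import capture_session  # local import: avoids a cycle

    if specs is None:
        rng = np.random.default_rng(seed)
        specs = []
        for i, stride in enumerate((0.9, 1.1, 1.3)):
            specs.append(
                ScenarioSpec(
                    "walk_straight", duration_s=16.0, stride_period_s=stride,
                    seed=int(rng.integers(2**31)),
                )
            )
        for amp in (20.0, 30.0):
            specs.append(
                ScenarioSpec(
                    "head_turns_yaw", duration_s=12.0, head_amplitude_deg=amp,
                    seed=int(rng.integers(2**31)),
                )
            )
        specs.append(ScenarioSpec("quiet_stance", duration_s=30.0, seed=int(rng.integers(2**31))))

    rows = []
    for i, spec in enumerate(specs):
        session, truth = simulate(spec)
        result = capture_session(session)
        scenario = f"{spec.exercise}#{i}"
        if truth.stride_time_s is not None and result.gait is not None:
            est = result.gait.to_dict()
            for metric, tv in (
                ("stride_time_s", truth.stride_time_s),
                ("step_time_s", truth.step_time_s),
                ("double_support_s", truth.double_support_s),
                ("single_support_s", truth.single_support_s),
            ):
                ev = est[metric]["mean"]
                rows.append((scenario, metric, tv, ev, ev - tv))
            ev = est["cadence_steps_per_min"]
            rows.append((scenario, "cadence_steps_per_min", truth.cadence_steps_per_min,
                         ev, ev - truth.cadence_steps_per_min))
        if truth.head_mean_range_deg is not None and result.head is not None:
            ev = result.head.mean_range
            rows.append((scenario, "head_mean_range_deg", truth.head_mean_range_deg,
                         ev, ev - truth.head_mean_range_deg))
        if truth.sway_radius_deg_s is not None and result.sway is not None:
            ev = result.sway.radius_deg_per_s
            rows.append((scenario, "sway_radius_deg_s", truth.sway_radius_deg_s,
                         ev, ev - truth.sway_radius_deg_s))
    return pd.DataFrame(rows, columns=["scenario", "metric", "truth", "estimate", "error"])
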