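"""Attitude estimation: 9-DoF IMU fusion to Euler angle time series.

Accelerometer, gyroscope and magnetometer samples from the head- and
waist-mounted IMUs are fused into an orientation quaternion by an extended
Kalman filter (7 states: attitude quaternion + gyroscope bias), then
converted to Euler angles.

Conventions (documented prominently because "yaw/pitch/roll planes" depend
on them):

* World frame: x east, y north, z up.  At rest the accelerometer reads the
  specific force ``R(q)^T (0, 0, g)``.
* Euler angles are **intrinsic z-y-x**: yaw about the world z axis, then
  pitch about the intermediate y axis, then roll about the body x axis.
  Positive yaw is a counter-clockwise horizontal rotation seen from above.
* Output angles are in degrees and *unwrapped* (unbounded); wrapping yaw
  back to [0, 360) recovers the fused attitude.

The yaw zero reference is the subject's initial heading: the magnetometer
reference vector is taken from the first sample (tilt-corrected), so no
declination model is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, DegenerateGravityError, FormatError

GRAVITY = 9.81  # m/s^2
GIMBAL_PITCH_DEG = 85.0


# ---------------------------------------------------------------------------
# quaternion helpers (w, x, y, z ordering)


def _quat_mult_matrix_left(q: np.ndarray) -> np.ndarray:
    """Matrix L(q) with L(q) p = q (x) p."""
    w, x, y, z = q
    return np.array(
        [
            [w, -x, -y, -z],
            [x, w, -z, y],
            [y, z, w, -x],
            [z, -y, x, w],
        ]
    )


def _quat_mult_matrix_right(p: np.ndarray) -> np.ndarray:
    """Matrix Rm(p) with Rm(p) q = q (x) p."""
    w, x, y, z = p
    return np.array(
        [
            [w, -x, -y, -z],
            [x, w, z, -y],
            [y, -z, w, x],
            [z, y, -x, w],
        ]
    )


def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = float(np.linalg.norm(v))
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]]) / np.sqrt(
            1.0 + 0.25 * float(v @ v)
        )
    axis = v / angle
    return np.concatenate([[np.cos(angle / 2)], np.sin(angle / 2) * axis])


def _rotmat(q: np.ndarray) -> np.ndarray:
    """Body-to-world rotation matrix of quaternion (w, x, y, z)."""
    return Rotation.from_quat(q[[1, 2, 3, 0]]).as_matrix()


def _tilt_quaternion(accel: np.ndarray) -> np.ndarray:
    """Zero-yaw attitude whose body z axis matches the measured gravity."""
    a = accel / np.linalg.norm(accel)
    # roll/pitch for z-y-x convention from the gravity direction in body frame
    pitch = np.arcsin(np.clip(-a[0], -1.0, 1.0))
    roll = np.arctan2(a[1], a[2])
    r = Rotation.from_euler("ZYX", [0.0, pitch, roll])
    return r.as_quat()[[3, 0, 1, 2]]


@dataclass
class FusionParams:
    """Tunable noise model and options for the attitude filter.

    Defaults suit consumer MEMS IMUs sampled at 100 Hz.
    """

    gyro_noise_deg_s: float = 0.5       # gyro white noise driving attitude process noise
    bias_drift_deg_s: float = 0.02      # random-walk intensity of the gyro bias
    accel_noise: float = 0.35           # measurement noise of the normalized gravity dir
    mag_noise: float = 0.5              # measurement noise of the normalized field dir
    use_mag: bool = True
    init_mode: str = "from-accel"       # or "identity"
    method: str = "ekf"                 # or "complementary"
    complementary_gain: float = 0.02

    @classmethod
    def from_dict(cls, d: dict) -> "FusionParams":
        return cls(**d)


@dataclass
class EulerSeries:
    """Unwrapped yaw/pitch/roll (degrees) on the session grid, with rates.

    ``pitch_rate``/``roll_rate`` of the waist placement are the trunk
    angular velocities feeding the sway index.
    """

    placement: str
    t: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    yaw_rate: np.ndarray = field(default=None)  # deg/s
    pitch_rate: np.ndarray = field(default=None)
    roll_rate: np.ndarray = field(default=None)
    gimbal_flag: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.yaw_rate is None:
            self.yaw_rate = np.gradient(self.yaw, self.t)
        if self.pitch_rate is None:
            self.pitch_rate = np.gradient(self.pitch, self.t)
        if self.roll_rate is None:
            self.roll_rate = np.gradient(self.roll, self.t)
        if self.gimbal_flag is None:
            self.gimbal_flag = np.abs(self.pitch) > GIMBAL_PITCH_DEG

    def angle(self, plane: str) -> np.ndarray:
        return {"yaw": self.yaw, "pitch": self.pitch, "roll": self.roll}[plane]


def unwrap_full_circle(series: np.ndarray) -> np.ndarray:
    """Remove the 360-degree wrap discontinuity from an angle series.

    The output is congruent to the input modulo 360 at every sample, the
    first sample is unchanged, and successive differences are < 180 deg in
    magnitude.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        return series.copy()
    return np.unwrap(series, period=360.0)


def _run_ekf(
    accel: np.ndarray,
    gyro_rad: np.ndarray,
    mag: np.ndarray | None,
    dt: float,
    params: FusionParams,
    q0: np.ndarray,
    m_ref: np.ndarray | None,
) -> np.ndarray:
    """7-state EKF over n samples; returns (n, 4) quaternions (w, x, y, z)."""
    n = accel.shape[0]
    x = np.concatenate([q0, np.zeros(3)])  # quaternion + gyro bias (rad/s)
    P = np.diag([1e-2] * 4 + [1e-4] * 3)
    sq = np.deg2rad(params.gyro_noise_deg_s) * dt
    sb = np.deg2rad(params.bias_drift_deg_s) * dt
    Q = np.diag([0.25 * sq**2] * 4 + [sb**2] * 3)
    g_ref = np.array([0.0, 0.0, 1.0])
    quats = np.empty((n, 4))
    eps = 1e-6

    for k in range(n):
        if k > 0:
            q = x[:4]
            omega = gyro_rad[k] - x[4:]
            dq = _quat_from_rotvec(omega * dt)
            q_new = _quat_mult_matrix_left(q) @ dq
            F = np.zeros((7, 7))
            F[:4, :4] = _quat_mult_matrix_right(dq)
            # d(q (x) dq)/d bias: dq vector part ~ -0.5*dt*db
            ddq_db = np.zeros((4, 3))
            ddq_db[1:, :] = -0.5 * dt * np.eye(3)
            F[:4, 4:] = _quat_mult_matrix_left(q) @ ddq_db
            F[4:, 4:] = np.eye(3)
            x = np.concatenate([q_new / np.linalg.norm(q_new), x[4:]])
            P = F @ P @ F.T + Q

        # measurement update: normalized gravity (+ field) direction
        a = accel[k]
        a_norm = np.linalg.norm(a)
        obs: list[np.ndarray] = []
        refs: list[np.ndarray] = []
        noises: list[float] = []
        if a_norm > 1e-3:
            obs.append(a / a_norm)
            refs.append(g_ref)
            noises.append(params.accel_noise)
        if mag is not None and m_ref is not None:
            m = mag[k]
            m_norm = np.linalg.norm(m)
            if m_norm > 1e-9:
                obs.append(m / m_norm)
                refs.append(m_ref)
                noises.append(params.mag_noise)
        if obs:
            q = x[:4]
            z = np.concatenate(obs)
            def h_of(qv: np.ndarray) -> np.ndarray:
                Rb = _rotmat(qv / np.linalg.norm(qv)).T
                return np.concatenate([Rb @ r for r in refs])
            h = h_of(q)
            H = np.zeros((z.size, 7))
            for j in range(4):
                qp = q.copy()
                qp[j] += eps
                H[:, j] = (h_of(qp) - h) / eps
            Rm = np.diag(np.repeat(np.square(noises), 3))
            S = H @ P @ H.T + Rm
            K = P @ H.T @ np.linalg.solve(S, np.eye(S.shape[0]))
            x = x + K @ (z - h)
            x[:4] /= np.linalg.norm(x[:4])
            P = (np.eye(7) - K @ H) @ P
            P = 0.5 * (P + P.T)
        quats[k] = x[:4]
    return quats


def _run_complementary(
    accel: np.ndarray,
    gyro_rad: np.ndarray,
    mag: np.ndarray | None,
    dt: float,
    params: FusionParams,
    q0: np.ndarray,
    m_ref: np.ndarray | None,
) -> np.ndarray:
    """Gyro integration with a small proportional pull toward the reference
    directions; same interface as the EKF, used for robustness comparisons."""
    n = accel.shape[0]
    q = q0.copy()
    g_ref = np.array([0.0, 0.0, 1.0])
    gain = params.complementary_gain
    quats = np.empty((n, 4))
    for k in range(n):
        if k > 0:
            dq = _quat_from_rotvec(gyro_rad[k] * dt)
            q = _quat_mult_matrix_left(q) @ dq
            q /= np.linalg.norm(q)
        Rb = _rotmat(q).T
        err = np.zeros(3)
        a = accel[k]
        a_norm = np.linalg.norm(a)
        if a_norm > 1e-3:
            err += np.cross(Rb @ g_ref, a / a_norm)
        if mag is not None and m_ref is not None:
            m = mag[k]
            m_norm = np.linalg.norm(m)
            if m_norm > 1e-9:
                err += np.cross(Rb @ m_ref, m / m_norm)
        if np.any(err):
            corr = _quat_from_rotvec(-gain * err)
            q = _quat_mult_matrix_left(q) @ corr
            q /= np.linalg.norm(q)
        quats[k] = q
    return quats


def fuse_orientation(
    accel: np.ndarray,
    gyro: np.ndarray,
    mag: np.ndarray | None,
    rate: float,
    params: FusionParams | None = None,
    placement: str = "head",
) -> EulerSeries:
    """Fuse 3-axis accel (m/s^2), gyro (deg/s) and magnetometer into Euler angles.

    Parameters
    ----------
    accel, gyro, mag
        (n, 3) arrays on a gap-free uniform grid; ``mag`` may be None or
        disabled via ``params.use_mag``.
    rate
        Sampling rate in Hz.

    Returns
    -------
    EulerSeries
        Unwrapped yaw/pitch/roll in degrees plus angular rates; deterministic
        given identical inputs.
    """
    params = params or FusionParams()
    if rate <= 0:
        raise ConfigurationError("rate must be positive")
    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    if accel.shape != gyro.shape or accel.ndim != 2 or accel.shape[1] != 3:
        raise FormatError("accel and gyro must be equal-shaped (n, 3) arrays")
    if mag is not None:
        mag = np.asarray(mag, dtype=float)
        if mag.shape != accel.shape:
            raise FormatError("mag must match accel shape")
    if not params.use_mag:
        mag = None
    if np.all(np.linalg.norm(accel, axis=1) < 1e-3):
        raise DegenerateGravityError("accelerometer norm ~ 0 over the whole window")

    dt = 1.0 / rate
    gyro_rad = np.deg2rad(gyro)

    if params.init_mode == "from-accel":
        q0 = _tilt_quaternion(accel[0])
    elif params.init_mode == "identity":
        q0 = np.array([1.0, 0.0, 0.0, 0.0])
    else:
        raise ConfigurationError(f"unknown init_mode {params.init_mode!r}")

    m_ref = None
    if mag is not None:
        m0 = mag[0]
        if np.linalg.norm(m0) > 1e-9:
            # reference field = first sample rotated to world by the initial
            # attitude; fixes yaw zero at the initial heading
            m_ref = _rotmat(q0) @ (m0 / np.linalg.norm(m0))

    runner = {"ekf": _run_ekf, "complementary": _run_complementary}.get(params.method)
    if runner is None:
        raise ConfigurationError(f"unknown fusion method {params.method!r}")
    quats = runner(accel, gyro_rad, mag, dt, params, q0, m_ref)

    eul = Rotation.from_quat(quats[:, [1, 2, 3, 0]]).as_euler("ZYX", degrees=True)
    yaw = unwrap_full_circle(eul[:, 0])
    pitch = eul[:, 1]  # ZYX pitch lives in [-90, 90]; no wrap possible
    roll = unwrap_full_circle(eul[:, 2])
    t = np.arange(accel.shape[0]) * dt
    return EulerSeries(placement, t, yaw, pitch, roll)
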