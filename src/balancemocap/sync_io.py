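"""Session I/O, stream repair and windowing.

Wearable streams (two 9-DoF IMUs, two pressure insoles, an optional depth
camera) arrive over BLE with receiver-clock timestamps and a 1.0-1.3 %
sample-loss rate.  This module aligns them on one uniform grid, fills the
gaps by cubic interpolation and cuts the fixed-length processing windows the
online assessment consumes.

A session on disk is a directory: ``manifest.json`` plus one CSV per stream
(columns ``t`` then the channel names, UTF-8, '.' decimal separator, time in
seconds as float).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import AlignmentError, ConfigurationError, FormatError, UnusableStreamError

DEVICE_IDS = ("head_imu", "waist_imu", "insole_left", "insole_right", "camera")

#: channels expected per device kind (used for validation, not enforcement of order)
IMU_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz")
INSOLE_PRESSURE_CHANNELS = tuple(f"p{i:02d}" for i in range(16))
INSOLE_CHANNELS = INSOLE_PRESSURE_CHANNELS + ("Ax", "Ay", "Az", "Gx", "Gy", "Gz")


@dataclass
class RawStream:
    """One device's time-stamped channel bundle before grid alignment.

    Units follow the sensing platform: accelerometer m/s^2, gyroscope deg/s,
    magnetometer arbitrary units, insole pressure N/cm^2.
    """

    device_id: str
    timestamps: np.ndarray  # seconds, strictly increasing
    channels: dict[str, np.ndarray]
    nominal_rate: float = 100.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if self.device_id not in DEVICE_IDS:
            raise FormatError(f"unknown device_id {self.device_id!r}")
        if self.timestamps.ndim != 1:
            raise FormatError("timestamps must be one-dimensional")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise FormatError(f"{self.device_id}: timestamps not strictly increasing")
        for name, series in self.channels.items():
            if series.shape != self.timestamps.shape:
                raise FormatError(
                    f"{self.device_id}: channel {name!r} length {series.size} "
                    f"!= timestamp length {self.timestamps.size}"
                )
        if self.device_id.startswith("insole"):
            npress = sum(1 for c in self.channels if c.startswith("p"))
            if npress and npress != 16:
                raise FormatError(f"{self.device_id}: expected 16 pressure channels, got {npress}")
            for name in self.channels:
                if name.startswith("p") and np.any(self.channels[name] < 0):
                    raise FormatError(f"{self.device_id}: negative pressure in {name!r}")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.timestamps, **self.channels})


def uniform_grid(t_first: float, t_last: float, grid_rate: float) -> np.ndarray:
    """Uniform time grid spanning [t_first, t_last] at grid_rate Hz.

    Sample count is ``floor((t_last - t_first) * grid_rate) + 1``; a small
    tolerance absorbs float rounding so a nominally exact span is not
    truncated by one sample.
    """
    span = t_last - t_first
    n = int(np.floor(span * grid_rate + 1e-9)) + 1
    return t_first + np.arange(n) / grid_rate


def _clip_physical(device_id: str, channel: str, values: np.ndarray) -> np.ndarray:
    """Cubic interpolation can overshoot at sharp load transitions; pressure
    cannot be negative, so insole pressure channels are clipped at zero."""
    if device_id.startswith("insole") and channel.startswith("p"):
        return np.clip(values, 0.0, None)
    return values


def repair_stream(stream: RawStream, grid_rate: float = 100.0) -> RawStream:
    """Resample a stream onto a uniform grid, filling dropped samples.

    BLE loss shows up as gaps longer than the nominal period; every channel
    is interpolated with a cubic spline through the received samples, so
    samples already on the grid are reproduced to numerical tolerance and
    gaps are filled smoothly.

    Raises
    ------
    UnusableStreamError
        Fewer than 4 samples (a cubic needs 4 support points).
    """
    if grid_rate <= 0:
        raise ConfigurationError("grid_rate must be positive")
    if stream.timestamps.size < 4:
        raise UnusableStreamError(
            f"{stream.device_id}: {stream.timestamps.size} samples, need >= 4 for cubic repair"
        )
    grid = uniform_grid(stream.timestamps[0], stream.timestamps[-1], grid_rate)
    out: dict[str, np.ndarray] = {}
    for name, series in stream.channels.items():
        spline = CubicSpline(stream.timestamps, series)
        out[name] = _clip_physical(stream.device_id, name, spline(grid))
    return RawStream(stream.device_id, grid, out, nominal_rate=grid_rate)


def dropped_sample_fraction(stream: RawStream) -> float:
    """Fraction of expected samples missing, gaps > 1.5x the nominal period."""
    period = 1.0 / stream.nominal_rate
    gaps = np.diff(stream.timestamps)
    extra = np.round(gaps[gaps > 1.5 * period] / period).astype(int) - 1
    expected = (stream.span[1] - stream.span[0]) / period + 1
    return float(extra.sum() / expected)


@dataclass
class FrameRef:
    """Pointer to one camera frame (30 fps; never resampled)."""

    t: float
    rgb_ref: str | None = None
    depth_ref: str | None = None


@dataclass
class SensorSession:
    """All streams of one exercise recording, on a single uniform clock."""

    streams: dict[str, RawStream]
    grid_rate: float = 100.0
    frames: list[FrameRef] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def grid(self) -> np.ndarray:
        return next(iter(self.streams.values())).timestamps

    @property
    def span(self) -> tuple[float, float]:
        g = self.grid
        return float(g[0]), float(g[-1])

    @property
    def duration(self) -> float:
        a, b = self.span
        return b - a

    def stream(self, device_id: str) -> RawStream:
        return self.streams[device_id]


def build_session(
    streams: list[RawStream],
    frames: list[FrameRef] | None = None,
    grid_rate: float = 100.0,
    metadata: dict | None = None,
    min_overlap_s: float = 1.0,
) -> SensorSession:
    """Repair all streams and crop them to their common temporal overlap.

    Raises :class:`AlignmentError` if the streams overlap for less than
    ``min_overlap_s`` seconds.
    """
    if not streams:
        raise AlignmentError("no streams supplied")
    t0 = max(s.span[0] for s in streams)
    t1 = min(s.span[1] for s in streams)
    if t1 - t0 < min_overlap_s:
        raise AlignmentError(
            f"streams overlap for {max(t1 - t0, 0.0):.3f} s, need >= {min_overlap_s} s"
        )
    grid = uniform_grid(t0, t1, grid_rate)
    repaired: dict[str, RawStream] = {}
    for s in streams:
        r = repair_stream(s, grid_rate)
        # re-evaluate on the common grid (repair used the stream's own span)
        out = {
            name: _clip_physical(s.device_id, name, CubicSpline(s.timestamps, series)(grid))
            for name, series in s.channels.items()
        }
        repaired[s.device_id] = RawStream(r.device_id, grid, out, nominal_rate=grid_rate)
    kept_frames = [f for f in (frames or []) if t0 <= f.t <= t1]
    return SensorSession(repaired, grid_rate, kept_frames, metadata or {})


@dataclass
class SessionWindow:
    """A contiguous slice of the session grid, for online evaluation."""

    session: SensorSession
    start_idx: int
    stop_idx: int  # exclusive
    partial: bool = False

    @property
    def t(self) -> np.ndarray:
        return self.session.grid[self.start_idx : self.stop_idx]

    @property
    def duration(self) -> float:
        return (self.stop_idx - self.start_idx) / self.session.grid_rate

    def channel(self, device_id: str, name: str) -> np.ndarray:
        return self.session.stream(device_id).channels[name][self.start_idx : self.stop_idx]


def windows(session: SensorSession, timeinterval_ms: float = 2000.0) -> list[SessionWindow]:
    """Cut the session into contiguous, non-overlapping processing windows.

    The online assessment operates on one window at a time, every
    ``timeinterval`` milliseconds; a trailing partial window is flagged.
    """
    if timeinterval_ms < 500:
        raise ConfigurationError("timeinterval must be >= 500 ms")
    n = session.grid.size
    step = int(round(timeinterval_ms / 1000.0 * session.grid_rate))
    out: list[SessionWindow] = []
    i = 0
    while i < n:
        j = min(i + step, n)
        out.append(SessionWindow(session, i, j, partial=(j - i) < step))
        i = j
    return out


# ---------------------------------------------------------------------------
# Session directory format


def save_session(session: SensorSession, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "grid_rate": session.grid_rate,
        "metadata": session.metadata,
        "streams": {},
        "frames": [
            {"t": f.t, "rgb_ref": f.rgb_ref, "depth_ref": f.depth_ref} for f in session.frames
        ],
    }
    for device_id, stream in session.streams.items():
        fname = f"{device_id}.csv"
        stream.to_frame().to_csv(path / fname, index=False, float_format="%.17g")
        manifest["streams"][device_id] = {
            "file": fname,
            "nominal_rate": stream.nominal_rate,
            "channels": list(stream.channels),
        }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def load_session(path: str | Path) -> SensorSession:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    streams: dict[str, RawStream] = {}
    for device_id, info in manifest["streams"].items():
        df = pd.read_csv(path / info["file"], float_precision="round_trip")
        t = df["t"].to_numpy()
        channels = {c: df[c].to_numpy() for c in df.columns if c != "t"}
        streams[device_id] = RawStream(device_id, t, channels, info.get("nominal_rate", 100.0))
    frames = [FrameRef(f["t"], f.get("rgb_ref"), f.get("depth_ref")) for f in manifest.get("frames", [])]
    return SensorSession(streams, manifest["grid_rate"], frames, manifest.get("metadata", {}))
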