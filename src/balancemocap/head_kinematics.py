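"""Head-movement metrics: range, speed and repetition counting.

The head exercises (yaw turns, nodding, lateral tilts) are quantified per
processing window from the head Euler-angle series:

1. unwrap the 360-degree discontinuity,
2. low-pass filter (zero-phase 2nd-order Butterworth),
3. find prominent local extrema and enforce min/max alternation,
4. pair temporally adjacent opposite extrema,
5. per pair: range = |max - min|, speed = range / pair duration.

Because every metric is a *difference of adjacent extrema*, slow gyro drift
cancels: a ramp of r deg/s changes a pair's range by at most r times the
pair duration (a fraction of a second for voluntary head turns).

A "repetition" is one min-max pair, i.e. one extreme-to-extreme sweep
(half a full cycle); ``turn_rate`` counts these sweeps per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .errors import ConfigurationError
from .orientation import EulerSeries, unwrap_full_circle

#: Voluntary head movement lives below ~3 Hz; the default cutoff keeps fast
#: vestibular head turns (~2 Hz) and suppresses tremor-scale ripple.
DEFAULT_FC_HZ = 5.0
DEFAULT_PROMINENCE_DEG = 5.0
DEFAULT_MIN_SEPARATION_S = 0.15


@dataclass
class HeadMovementParams:
    fc_hz: float = DEFAULT_FC_HZ
    prominence_deg: float = DEFAULT_PROMINENCE_DEG
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S

    @classmethod
    def from_dict(cls, d: dict) -> "HeadMovementParams":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class ExtremumPoint:
    t: float
    value: float
    kind: str  # "min" | "max"


@dataclass
class MovementPair:
    t_start: float
    t_end: float
    range_deg: float
    speed_deg_per_s: float


@dataclass
class HeadMovementSummary:
    plane: str
    pairs: list[MovementPair]
    window_duration_s: float
    extrema: list[ExtremumPoint] = field(default_factory=list)

    @property
    def repetitions(self) -> int:
        return len(self.pairs)

    @property
    def turn_rate(self) -> float:
        """Extreme-to-extreme sweeps per second over the window."""
        return self.repetitions / self.window_duration_s if self.window_duration_s else 0.0

    @property
    def mean_range(self) -> float:
        return float(np.mean([p.range_deg for p in self.pairs])) if self.pairs else 0.0

    @property
    def mean_speed(self) -> float:
        return float(np.mean([p.speed_deg_per_s for p in self.pairs])) if self.pairs else 0.0


#: forward-backward filtering squares the magnitude response, so the design
#: cutoff is raised by (sqrt(2)-1)^(-1/4) to keep the -3 dB point at fc
_FILTFILT_CUTOFF_CORRECTION = (2.0**0.5 - 1.0) ** -0.25


def lowpass2(series: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """Zero-phase second-order Butterworth low-pass (DC gain 1, -3 dB at fc).

    Zero-phase (forward-backward) filtering keeps extremum timestamps
    unlagged, which matters because pair durations enter the speed metric;
    the design cutoff is pre-warped so the two-pass cascade still attenuates
    a sine at fc to 1/sqrt(2).
    """
    if not 0 < fc < fs / 2:
        raise ConfigurationError(
            f"cutoff fc={fc} Hz must lie in (0, fs/2)={fs / 2} Hz; "
            f"fall back to the default fc={DEFAULT_FC_HZ} Hz"
        )
    series = np.asarray(series, dtype=float)
    if series.size < 10:
        return series.copy()
    fc_design = min(fc * _FILTFILT_CUTOFF_CORRECTION, 0.499 * fs)
    b, a = butter(2, fc_design, btype="low", fs=fs)
    return filtfilt(b, a, series)


def find_extrema(
    series: np.ndarray,
    t: np.ndarray,
    prominence_deg: float = DEFAULT_PROMINENCE_DEG,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> list[ExtremumPoint]:
    """Prominent local extrema of an angle series, min/max alternating.

    Alternation is enforced by discarding the lesser of two consecutive
    same-kind extrema (more extreme value wins; on an exact tie the earlier
    one is kept).
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if series.size < 3:
        return []
    fs = 1.0 / float(np.median(np.diff(t)))
    distance = max(1, int(round(min_separation_s * fs)))
    imax, _ = find_peaks(series, prominence=prominence_deg, distance=distance)
    imin, _ = find_peaks(-series, prominence=prominence_deg, distance=distance)
    pts = [ExtremumPoint(float(t[i]), float(series[i]), "max") for i in imax]
    pts += [ExtremumPoint(float(t[i]), float(series[i]), "min") for i in imin]
    pts.sort(key=lambda p: p.t)

    out: list[ExtremumPoint] = []
    for p in pts:
        if out and out[-1].kind == p.kind:
            prev = out[-1]
            if p.kind == "max":
                better = p.value > prev.value  # strict: exact tie keeps the earlier
            else:
                better = p.value < prev.value
            if better:
                out[-1] = p
        else:
            out.append(p)
    return out


def pair_min_max(extrema: list[ExtremumPoint]) -> list[MovementPair]:
    """Pair each extremum with its temporally adjacent opposite, zig-zag style.

    With alternation already enforced, the minimum-time-distance partner of
    every extremum is its neighbour, so the pairs are simply consecutive
    (min, max) / (max, min) couples; inner extrema belong to two pairs.
    """
    pairs: list[MovementPair] = []
    for a, b in zip(extrema[:-1], extrema[1:]):
        if a.kind == b.kind:  # defensive; alternation should prevent this
            continue
        dt = b.t - a.t
        rng = abs(b.value - a.value)
        pairs.append(MovementPair(a.t, b.t, rng, rng / dt if dt > 0 else np.inf))
    return pairs


def head_movement(
    window: EulerSeries,
    plane: str = "yaw",
    params: HeadMovementParams | None = None,
) -> HeadMovementSummary:
    """Range/speed/repetition summary of one plane over one window."""
    params = params or HeadMovementParams()
    t = window.t
    if t[-1] - t[0] < 1.0:
        raise ConfigurationError("head_movement needs a window of >= 1 s")
    fs = 1.0 / float(np.median(np.diff(t)))
    series = unwrap_full_circle(window.angle(plane))
    filtered = lowpass2(series, params.fc_hz, fs)
    extrema = find_extrema(filtered, t, params.prominence_deg, params.min_separation_s)
    pairs = pair_min_max(extrema)
    return HeadMovementSummary(plane, pairs, float(t[-1] - t[0]), extrema)
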