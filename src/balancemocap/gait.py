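"""Gait analysis from pressure insoles: full-scale step selection, gait
events, temporal parameters and center of pressure.

Home walking exercises involve many back-and-forth routes, so the pipeline
first rejects body turns and stops using the insoles' own IMUs (absolute
foot rotation from integrated gyro yaw; stops from accelerometer
quiescence), leaving straight-walking *bouts*.  Gait events — heel strike,
flat foot, heel rise, toe off — are then detected per foot from the summed
rearfoot/forefoot pressure-cluster signals via relative-threshold
crossings, and the temporal parameters of Table-style gait reports (double
and single support, step and stride time, cadence) are derived from the
event table.  Only *full-scale* steps count: complete cycles inside a bout,
excluding each bout's first and last cycle (half-steps at gait initiation
and termination).

The center of pressure is the pressure-weighted centroid of the sensor
coordinates in the insole layout, reported while the summed pressure
exceeds a contact threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, InsufficientStepsError

EVENT_ORDER = ("heel_strike", "flat_foot", "heel_rise", "toe_off")
FEET = ("left", "right")


# ---------------------------------------------------------------------------
# Insole layout


@dataclass
class InsoleLayout:
    """Sensor coordinates (mm, heel origin, +x toward toes) and clusters."""

    coords: dict[str, dict[str, tuple[float, float]]]  # foot -> channel -> (x, y)
    clusters: dict[str, dict[str, str]]                # foot -> channel -> cluster

    def cluster_channels(self, foot: str, cluster: str) -> list[str]:
        return [ch for ch, cl in self.clusters[foot].items() if cl == cluster]

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "InsoleLayout":
        if path is None:
            text = (resources.files("balancemocap") / "config" / "insole_layout.yaml").read_text()
            raw = yaml.safe_load(text)
        else:
            raw = yaml.safe_load(Path(path).read_text())
        coords: dict[str, dict[str, tuple[float, float]]] = {}
        clusters: dict[str, dict[str, str]] = {}
        for foot, table in raw.items():
            if len(table) != 16:
                raise ConfigurationError(f"layout for {foot!r} has {len(table)} sensors, need 16")
            coords[foot] = {ch: (float(v["x"]), float(v["y"])) for ch, v in table.items()}
            clusters[foot] = {ch: str(v["cluster"]) for ch, v in table.items()}
        return cls(coords, clusters)


# ---------------------------------------------------------------------------
# Turn / stop rejection


@dataclass
class TurnStopParams:
    turn_angle_deg: float = 45.0   # yaw change that marks a turn ...
    turn_window_s: float = 2.0     # ... within this sliding window
    stop_std: float = 0.3          # m/s^2; accel-magnitude std below => stopped
    stop_min_s: float = 1.0
    min_bout_s: float = 1.0


@dataclass
class ValidityMask:
    t: np.ndarray
    mask: np.ndarray  # True = inside a straight-walking bout
    bouts: list[tuple[float, float]]

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.mask)) if self.mask.size else 0.0


def foot_rotation(gyro_yaw_deg_s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Absolute foot yaw (degrees): cumulative trapezoidal integral from 0."""
    return cumulative_trapezoid(np.asarray(gyro_yaw_deg_s, float), np.asarray(t, float), initial=0.0)


def _mark_intervals(n: int, starts: np.ndarray, stops: np.ndarray) -> np.ndarray:
    """Boolean array with [start, stop] index intervals set, via a diff array."""
    acc = np.zeros(n + 1, dtype=int)
    np.add.at(acc, starts, 1)
    np.add.at(acc, np.minimum(stops + 1, n), -1)
    return np.cumsum(acc[:-1]) > 0


def omit_turns_and_stops(
    t: np.ndarray,
    accel: dict[str, np.ndarray],
    gyro_yaw: dict[str, np.ndarray],
    params: TurnStopParams | None = None,
) -> ValidityMask:
    """Detect the time frames of full-scale straight walking.

    ``accel`` maps foot -> (n, 3) insole accelerometer (m/s^2); ``gyro_yaw``
    maps foot -> yaw-axis gyro (deg/s).  A turn is flagged per foot when the
    integrated yaw changes by more than ``turn_angle_deg`` within
    ``turn_window_s``; turn intervals of the two feet are OR-combined.  A
    stop is flagged when the accel-magnitude standard deviation stays below
    ``stop_std`` for at least ``stop_min_s``.  The mask is the complement;
    bouts shorter than ``min_bout_s`` are discarded.
    """
    params = params or TurnStopParams()
    t = np.asarray(t, float)
    n = t.size
    fs = 1.0 / float(np.median(np.diff(t)))
    invalid = np.zeros(n, dtype=bool)

    w_turn = max(1, int(round(params.turn_window_s * fs)))
    for foot in gyro_yaw:
        yaw = foot_rotation(gyro_yaw[foot], t)
        if n > w_turn:
            delta = np.abs(yaw[w_turn:] - yaw[:-w_turn])
            hits = np.flatnonzero(delta > params.turn_angle_deg)
            if hits.size:
                invalid |= _mark_intervals(n, hits, hits + w_turn)

    w_stop = max(2, int(round(params.stop_min_s * fs)))
    for foot in accel:
        mag = np.linalg.norm(np.asarray(accel[foot], float), axis=1)
        if n >= w_stop:
            # rolling std over trailing windows of stop_min_s
            c1 = np.cumsum(np.insert(mag, 0, 0.0))
            c2 = np.cumsum(np.insert(mag**2, 0, 0.0))
            s1 = c1[w_stop:] - c1[:-w_stop]
            s2 = c2[w_stop:] - c2[:-w_stop]
            var = np.maximum(s2 / w_stop - (s1 / w_stop) ** 2, 0.0)
            quiet = np.flatnonzero(np.sqrt(var) < params.stop_std)
            if quiet.size:
                invalid |= _mark_intervals(n, quiet, quiet + w_stop - 1)

    mask = ~invalid
    bouts: list[tuple[float, float]] = []
    if mask.any():
        edges = np.diff(mask.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        stops = list(np.flatnonzero(edges == -1))
        if mask[0]:
            starts.insert(0, 0)
        if mask[-1]:
            stops.append(n - 1)
        for a, b in zip(starts, stops):
            if t[b] - t[a] >= params.min_bout_s:
                bouts.append((float(t[a]), float(t[b])))
            else:
                mask[a : b + 1] = False
    return ValidityMask(t, mask, bouts)


# ---------------------------------------------------------------------------
# Gait events


@dataclass
class GaitEvent:
    t: float
    kind: str
    foot: str
    bout_id: int


@dataclass
class GaitCycle:
    """One complete heel_strike -> flat_foot -> heel_rise -> toe_off stance.

    ``full_scale`` is False for each bout's first and last cycle (gait
    initiation/termination half-steps); parameters are reported only over
    full-scale cycles, but edge stances still participate in support-time
    overlap bookkeeping.
    """

    foot: str
    bout_id: int
    heel_strike: float
    flat_foot: float
    heel_rise: float
    toe_off: float
    full_scale: bool = True

    @property
    def stance(self) -> tuple[float, float]:
        return (self.heel_strike, self.toe_off)


@dataclass
class GaitEventTable:
    cycles: dict[str, list[GaitCycle]]  # foot -> ordered complete cycles

    def events(self, foot: str) -> list[GaitEvent]:
        out: list[GaitEvent] = []
        for c in self.cycles.get(foot, []):
            for kind in EVENT_ORDER:
                out.append(GaitEvent(getattr(c, kind), kind, foot, c.bout_id))
        return out

    def full_scale_cycles(self, foot: str) -> list[GaitCycle]:
        return [c for c in self.cycles.get(foot, []) if c.full_scale]

    @property
    def n_cycles(self) -> dict[str, int]:
        return {f: len(self.full_scale_cycles(f)) for f in self.cycles}


def _cross_times(t: np.ndarray, y: np.ndarray, thr: float, direction: str) -> list[float]:
    """Linear-interpolated threshold-crossing times (sub-sample accuracy)."""
    if direction == "up":
        hits = np.flatnonzero((y[:-1] < thr) & (y[1:] >= thr))
    else:
        hits = np.flatnonzero((y[:-1] >= thr) & (y[1:] < thr))
    out = []
    for i in hits:
        frac = (thr - y[i]) / (y[i + 1] - y[i]) if y[i + 1] != y[i] else 0.0
        out.append(float(t[i] + frac * (t[i + 1] - t[i])))
    return out


def detect_gait_events(
    t: np.ndarray,
    pressure: np.ndarray,
    layout: InsoleLayout,
    foot: str,
    mask: ValidityMask | None = None,
    threshold_fraction: float = 0.10,
    trim_bout_edges: bool = True,
) -> list[GaitCycle]:
    """Detect complete stance cycles of one foot from its 16 pressure channels.

    ``pressure`` is (n, 16) in channel order p00..p15 (N/cm^2).  Within each
    bout, rear(t) and fore(t) are the summed rearfoot/forefoot cluster
    pressures and the per-bout thresholds are ``threshold_fraction`` of each
    sum's bout maximum: heel strike = upward rear crossing, heel rise =
    downward rear crossing, toe off = downward fore crossing, flat foot =
    first sample with both clusters above threshold.  Incomplete cycles are
    dropped; with ``trim_bout_edges`` the first and last cycle of every bout
    are dropped too (half-steps).
    """
    t = np.asarray(t, float)
    pressure = np.asarray(pressure, float)
    channels = list(layout.coords[foot])
    idx = {ch: k for k, ch in enumerate(channels)}
    rear_ix = [idx[ch] for ch in layout.cluster_channels(foot, "rearfoot")]
    fore_ix = [idx[ch] for ch in layout.cluster_channels(foot, "forefoot")]
    rear = pressure[:, rear_ix].sum(axis=1)
    fore = pressure[:, fore_ix].sum(axis=1)

    if mask is None:
        bouts = [(float(t[0]), float(t[-1]))]
    else:
        bouts = mask.bouts
    cycles: list[GaitCycle] = []
    for bout_id, (a, b) in enumerate(bouts):
        sel = (t >= a) & (t <= b)
        if sel.sum() < 4:
            continue
        tb, rb, fb = t[sel], rear[sel], fore[sel]
        rmax, fmax = rb.max(), fb.max()
        if rmax <= 0 or fmax <= 0:
            continue
        thr_r = threshold_fraction * rmax
        thr_f = threshold_fraction * fmax
        hs = _cross_times(tb, rb, thr_r, "up")
        hr = _cross_times(tb, rb, thr_r, "down")
        to = _cross_times(tb, fb, thr_f, "down")
        above_both = np.flatnonzero((rb > thr_r) & (fb > thr_f))
        ff_times = tb[above_both]

        bout_cycles: list[GaitCycle] = []
        for k, t_hs in enumerate(hs):
            t_next = hs[k + 1] if k + 1 < len(hs) else np.inf
            ffc = ff_times[(ff_times > t_hs) & (ff_times < t_next)]
            if ffc.size == 0:
                continue
            t_ff = float(ffc[0])
            hrc = [x for x in hr if t_ff < x < t_next]
            if not hrc:
                continue
            t_hr = hrc[0]
            toc = [x for x in to if t_hr < x < t_next]
            if not toc:
                continue
            bout_cycles.append(GaitCycle(foot, bout_id, t_hs, t_ff, t_hr, toc[0]))
        if trim_bout_edges and bout_cycles:
            bout_cycles[0].full_scale = False
            bout_cycles[-1].full_scale = False
        cycles.extend(bout_cycles)
    return cycles


def detect_gait_events_both(
    t: np.ndarray,
    pressures: dict[str, np.ndarray],
    layout: InsoleLayout,
    mask: ValidityMask | None = None,
    threshold_fraction: float = 0.10,
    trim_bout_edges: bool = True,
) -> GaitEventTable:
    return GaitEventTable(
        {
            foot: detect_gait_events(t, p, layout, foot, mask, threshold_fraction, trim_bout_edges)
            for foot, p in pressures.items()
        }
    )


# ---------------------------------------------------------------------------
# Temporal parameters


def _mean_sd(x: list[float]) -> tuple[float, float]:
    arr = np.asarray(x, float)
    if arr.size == 0:
        return float("nan"), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


@dataclass
class GaitMetrics:
    stride_times_s: dict[str, list[float]]
    step_times_s: list[float]
    double_support_s: list[float]
    single_support_s: list[float]

    @property
    def stride_time_mean_sd(self) -> tuple[float, float]:
        allc = [v for vs in self.stride_times_s.values() for v in vs]
        return _mean_sd(allc)

    @property
    def step_time_mean_sd(self) -> tuple[float, float]:
        return _mean_sd(self.step_times_s)

    @property
    def double_support_mean_sd(self) -> tuple[float, float]:
        return _mean_sd(self.double_support_s)

    @property
    def single_support_mean_sd(self) -> tuple[float, float]:
        return _mean_sd(self.single_support_s)

    @property
    def cadence_steps_per_min(self) -> float:
        m, _ = self.step_time_mean_sd
        return 60.0 / m if m and np.isfinite(m) else float("nan")

    @property
    def double_support_pct_stride(self) -> float:
        ds, _ = self.double_support_mean_sd
        st, _ = self.stride_time_mean_sd
        # two double-support phases per stride
        return 100.0 * 2 * ds / st if st and np.isfinite(st) else float("nan")

    def to_dict(self) -> dict:
        sm, ss = self.stride_time_mean_sd
        pm, ps = self.step_time_mean_sd
        dm, dsd = self.double_support_mean_sd
        om, osd = self.single_support_mean_sd
        return {
            "stride_time_s": {"mean": sm, "sd": ss},
            "step_time_s": {"mean": pm, "sd": ps},
            "double_support_s": {"mean": dm, "sd": dsd},
            "single_support_s": {"mean": om, "sd": osd},
            "cadence_steps_per_min": self.cadence_steps_per_min,
            "double_support_pct_stride": self.double_support_pct_stride,
            "n_strides": {f: len(v) for f, v in self.stride_times_s.items()},
        }


def gait_parameters(table: GaitEventTable) -> GaitMetrics:
    """Temporal gait parameters from the full-scale cycle table.

    stride time: between consecutive heel strikes of the same foot (same
    bout); step time: between heel strikes of opposite feet; double support:
    each overlap of left and right stance; single support: a foot's stance
    minus its double-support portions; cadence = 60 / mean step time.
    """
    full = {foot: table.full_scale_cycles(foot) for foot in table.cycles}
    n_strides_possible = max((len(cs) - 1 for cs in full.values() if len(cs) >= 2), default=0)
    if n_strides_possible < 2:
        raise InsufficientStepsError("need >= 2 complete strides on at least one foot")

    stride: dict[str, list[float]] = {}
    for foot, cs in full.items():
        stride[foot] = [
            b.heel_strike - a.heel_strike
            for a, b in zip(cs[:-1], cs[1:])
            if a.bout_id == b.bout_id
        ]

    strikes = sorted(
        ((c.heel_strike, c.foot, c.bout_id, c.full_scale)
         for cs in table.cycles.values() for c in cs)
    )
    step = [
        b[0] - a[0]
        for a, b in zip(strikes[:-1], strikes[1:])
        if a[1] != b[1] and a[2] == b[2] and a[3] and b[3]
    ]

    # edge (non-full-scale) stances still count for overlap bookkeeping so
    # support times of interior cycles are unbiased
    stances = {
        foot: [(c.heel_strike, c.toe_off, c.bout_id, c.full_scale) for c in cs]
        for foot, cs in table.cycles.items()
    }
    double: list[float] = []
    overlaps_by_stance: dict[tuple[str, int], float] = {}
    for i, (l0, l1, lb, lf) in enumerate(stances.get("left", [])):
        for j, (r0, r1, rb, rf) in enumerate(stances.get("right", [])):
            if lb != rb:
                continue
            lo, hi = max(l0, r0), min(l1, r1)
            if hi > lo:
                if lf and rf:
                    double.append(hi - lo)
                overlaps_by_stance[("left", i)] = overlaps_by_stance.get(("left", i), 0.0) + (hi - lo)
                overlaps_by_stance[("right", j)] = overlaps_by_stance.get(("right", j), 0.0) + (hi - lo)
    single: list[float] = []
    for foot, st in stances.items():
        for i, (s0, s1, _, fs) in enumerate(st):
            if fs:
                single.append((s1 - s0) - overlaps_by_stance.get((foot, i), 0.0))

    return GaitMetrics(stride, step, double, single)


# ---------------------------------------------------------------------------
# Center of pressure


@dataclass
class CopSeries:
    t: np.ndarray
    x_mm: np.ndarray       # NaN where the foot is off the ground
    y_mm: np.ndarray
    total_force: np.ndarray
    max_pressure_per_step: list[float] = field(default_factory=list)  # N/cm^2


def cop_trajectory(
    t: np.ndarray,
    pressure: np.ndarray,
    layout: InsoleLayout,
    foot: str,
    stances: list[tuple[float, float]] | None = None,
    contact_threshold: float = 0.5,
) -> CopSeries:
    """Pressure-weighted centroid of the active sensors (the standard
    plantar-pressure CoP), plus per-step maximum sensor pressure.

    Where the summed pressure is at or below ``contact_threshold`` (N/cm^2)
    the CoP is undefined (NaN), a gap rather than an error.  The CoP always
    lies inside the convex hull of the sensor coordinates.
    """
    t = np.asarray(t, float)
    pressure = np.asarray(pressure, float)
    channels = list(layout.coords[foot])
    xy = np.array([layout.coords[foot][ch] for ch in channels])  # (16, 2)
    total = pressure.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = pressure @ xy[:, 0] / total
        y = pressure @ xy[:, 1] / total
    off = total <= contact_threshold
    x[off] = np.nan
    y[off] = np.nan
    max_per_step: list[float] = []
    for a, b in stances or []:
        sel = (t >= a) & (t <= b)
        if sel.any():
            max_per_step.append(float(pressure[sel].max()))
    return CopSeries(t, x, y, total, max_per_step)
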