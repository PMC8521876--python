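"""End-to-end capture pipeline: session in, metrics out.

Composes the processing stages — orientation fusion, head kinematics,
trunk sway, gait analysis, posture — over a full session (offline pass)
or one processing window at a time (online pass).  Each stage degrades
gracefully: a session without insoles still yields head metrics, a
too-short window simply reports no value for the affected metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import gait as gait_mod
from .assessment import Message, Rule, evaluate_online
from .errors import BalanceMocapError, InsufficientDataError, InsufficientStepsError
from .head_kinematics import HeadMovementParams, HeadMovementSummary, head_movement
from .orientation import EulerSeries, FusionParams, fuse_orientation
from .posture import PostureReport, assess_posture_session
from .sway import SwayResult, sway_index
from .sync_io import SensorSession, SessionWindow, windows

log = logging.getLogger("balancemocap")

PLANES = ("yaw", "pitch", "roll")


def _imu_arrays(session_or_window, device: str):
    if isinstance(session_or_window, SessionWindow):
        get = lambda name: session_or_window.channel(device, name)  # noqa: E731
    else:
        get = lambda name: session_or_window.stream(device).channels[name]  # noqa: E731
    accel = np.column_stack([get("ax"), get("ay"), get("az")])
    gyro = np.column_stack([get("gx"), get("gy"), get("gz")])
    mag = np.column_stack([get("mx"), get("my"), get("mz")])
    return accel, gyro, mag


def fuse_device(session: SensorSession, device: str, params: FusionParams | None = None) -> EulerSeries:
    accel, gyro, mag = _imu_arrays(session, device)
    placement = "head" if device == "head_imu" else "waist"
    es = fuse_orientation(accel, gyro, mag, session.grid_rate, params, placement)
    es.t = session.grid.copy()
    return es


@dataclass
class CaptureResult:
    """Offline metrics of one session."""

    head_by_plane: dict[str, HeadMovementSummary] = field(default_factory=dict)
    gait: gait_mod.GaitMetrics | None = None
    event_table: gait_mod.GaitEventTable | None = None
    validity: gait_mod.ValidityMask | None = None
    cop: dict[str, gait_mod.CopSeries] = field(default_factory=dict)
    sway: SwayResult | None = None
    posture: PostureReport | None = None
    head_euler: EulerSeries | None = None
    waist_euler: EulerSeries | None = None

    @property
    def head(self) -> HeadMovementSummary | None:
        """Summary of the dominant plane (largest mean range)."""
        if not self.head_by_plane:
            return None
        return max(self.head_by_plane.values(), key=lambda s: s.mean_range)

    def metrics_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for plane, s in self.head_by_plane.items():
            out[f"head_range_{plane}_deg"] = s.mean_range
            out[f"head_speed_{plane}_deg_s"] = s.mean_speed
            out[f"head_turn_rate_{plane}_per_s"] = s.turn_rate
            out[f"head_repetitions_{plane}"] = s.repetitions
        if self.sway is not None:
            out["sway_radius_deg_s"] = self.sway.radius_deg_per_s
        if self.gait is not None:
            d = self.gait.to_dict()
            out["stride_time_s"] = d["stride_time_s"]["mean"]
            out["step_time_s"] = d["step_time_s"]["mean"]
            out["double_support_s"] = d["double_support_s"]["mean"]
            out["single_support_s"] = d["single_support_s"]["mean"]
            out["cadence_steps_per_min"] = d["cadence_steps_per_min"]
        if self.posture is not None:
            out["posture_uncomputable_fraction"] = self.posture.uncomputable_fraction
            labels = [d.label for d in self.posture.decisions]
            n_known = sum(1 for l in labels if l != "uncomputable")
            if n_known:
                out["posture_upright_fraction"] = sum(
                    1 for l in labels if l == "upright"
                ) / n_known
        return out


def capture_session(
    session: SensorSession,
    layout: gait_mod.InsoleLayout | None = None,
    fusion: FusionParams | None = None,
    head_params: HeadMovementParams | None = None,
    landmark_provider: Callable | None = None,
    baseline_lean_deg: float = 0.0,
) -> CaptureResult:
    """Run every applicable analysis stage over a complete session."""
    result = CaptureResult()
    head_params = head_params or HeadMovementParams()

    if "head_imu" in session.streams:
        result.head_euler = fuse_device(session, "head_imu", fusion)
        for plane in PLANES:
            try:
                result.head_by_plane[plane] = head_movement(result.head_euler, plane, head_params)
            except BalanceMocapError as exc:
                log.warning("head_movement(%s) skipped: %s", plane, exc)

    have_insoles = {"insole_left", "insole_right"} <= set(session.streams)
    if have_insoles:
        layout = layout or gait_mod.InsoleLayout.from_yaml()
        t = session.grid
        accel = {}
        gyro_yaw = {}
        pressures = {}
        for foot in ("left", "right"):
            ch = session.stream(f"insole_{foot}").channels
            accel[foot] = np.column_stack([ch["Ax"], ch["Ay"], ch["Az"]])
            gyro_yaw[foot] = ch["Gz"]
            pressures[foot] = np.column_stack([ch[f"p{i:02d}"] for i in range(16)])
        result.validity = gait_mod.omit_turns_and_stops(t, accel, gyro_yaw)
        result.event_table = gait_mod.detect_gait_events_both(
            t, pressures, layout, result.validity
        )
        try:
            result.gait = gait_mod.gait_parameters(result.event_table)
        except InsufficientStepsError as exc:
            log.warning("gait parameters skipped: %s", exc)
        for foot in ("left", "right"):
            stances = [c.stance for c in result.event_table.cycles.get(foot, [])]
            result.cop[foot] = gait_mod.cop_trajectory(
                t, pressures[foot], layout, foot, stances
            )

    if "waist_imu" in session.streams:
        result.waist_euler = fuse_device(session, "waist_imu", fusion)
        mask = None
        if result.validity is not None and result.validity.mask.any():
            mask = result.validity.mask
        try:
            result.sway = sway_index(
                result.waist_euler.pitch_rate, result.waist_euler.roll_rate, mask
            )
        except InsufficientDataError as exc:
            log.warning("sway index skipped: %s", exc)

    if session.frames and landmark_provider is not None and result.head_euler is not None:
        frame_times = np.array([f.t for f in session.frames])
        result.posture = assess_posture_session(
            result.head_euler, frame_times, landmark_provider, baseline_lean_deg
        )
    return result


def window_metrics(
    session: SensorSession,
    window: SessionWindow,
    fusion: FusionParams | None = None,
    head_params: HeadMovementParams | None = None,
) -> dict[str, float]:
    """Metrics of one processing window, for the online rule evaluation.

    Only metrics computable from the window's data appear; the fusion runs
    on the window alone, so evaluation latency is bounded by one window.
    """
    out: dict[str, float] = {}
    head_params = head_params or HeadMovementParams()
    if "head_imu" in window.session.streams and window.duration >= 1.0:
        accel, gyro, mag = _imu_arrays(window, "head_imu")
        es = fuse_orientation(accel, gyro, mag, session.grid_rate, fusion, "head")
        es.t = window.t.copy()
        for plane in PLANES:
            s = head_movement(es, plane, head_params)
            out[f"head_range_{plane}_deg"] = s.mean_range
            out[f"head_speed_{plane}_deg_s"] = s.mean_speed
            out[f"head_turn_rate_{plane}_per_s"] = s.turn_rate
    if "waist_imu" in window.session.streams:
        accel, gyro, mag = _imu_arrays(window, "waist_imu")
        es = fuse_orientation(accel, gyro, mag, session.grid_rate, fusion, "waist")
        es.t = window.t.copy()
        try:
            out["sway_radius_deg_s"] = sway_index(es.pitch_rate, es.roll_rate).radius_deg_per_s
        except InsufficientDataError:
            pass
    return out


def assess_session(
    session: SensorSession,
    rules: list[Rule],
    baseline: dict[str, float] | None = None,
    timeinterval_ms: float = 2000.0,
    fusion: FusionParams | None = None,
    head_params: HeadMovementParams | None = None,
) -> tuple[list[Message], dict[str, float], CaptureResult]:
    """Online-then-offline assessment.

    Streams the windows through the online rule evaluation, then recomputes
    all metrics over the complete recording (the offline pass) and returns
    (message log, offline metrics, full capture result).
    """
    messages: list[Message] = []
    for w in windows(session, timeinterval_ms):
        if w.partial:
            continue
        wm = window_metrics(session, w, fusion, head_params)
        messages.extend(evaluate_online(wm, rules, baseline, t=float(w.t[0])))
    offline = capture_session(session, fusion=fusion, head_params=head_params)
    return messages, offline.metrics_dict(), offline
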