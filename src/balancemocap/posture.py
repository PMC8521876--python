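"""Upright-posture assessment from depth frames and body landmarks.

During bending exercises the subject must return to an upright trunk
position.  Rather than classifying continuously, posture is evaluated only
at the instants the head is most upright (local pitch maxima of the head
IMU series): at each such instant the nearest camera frame is selected, the
background is removed using depth, a landmark provider locates the head and
waist, and the trunk lean angle relative to the subject's calibrated
upright baseline decides the label.

The landmark provider is pluggable — any callable ``(frame, mask) ->
LandmarkPair``; the package ships a synthetic provider that reads simulator
ground truth (the external pose-network backend is out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from scipy import ndimage

from .head_kinematics import HeadMovementParams, find_extrema, lowpass2
from .orientation import EulerSeries

DEFAULT_SUBJECT_DISTANCE_M = 1.85  # camera placement distance
DEFAULT_DEPTH_BAND_M = 0.4
DEFAULT_LEAN_THRESHOLD_DEG = 10.0
CONFIDENCE_FLOOR = 0.5


@dataclass
class LandmarkPair:
    """Head and waist image positions at one frame time."""

    t: float
    head_xy: tuple[float, float]
    waist_xy: tuple[float, float]
    conf_head: float = 1.0
    conf_waist: float = 1.0


@dataclass
class PostureDecision:
    t: float
    label: str  # "upright" | "not_upright" | "uncomputable"
    lean_deg: float | None = None


class LandmarkProvider(Protocol):
    def __call__(self, frame, mask) -> LandmarkPair | None: ...


def pitch_peak_times(
    head_pitch: EulerSeries, params: HeadMovementParams | None = None
) -> list[float]:
    """Times at which the head is most upright (local pitch maxima)."""
    params = params or HeadMovementParams()
    t = head_pitch.t
    fs = 1.0 / float(np.median(np.diff(t)))
    filtered = lowpass2(head_pitch.pitch, params.fc_hz, fs)
    extrema = find_extrema(filtered, t, params.prominence_deg, params.min_separation_s)
    return [e.t for e in extrema if e.kind == "max"]


def match_frames(
    times: list[float],
    frame_times: np.ndarray,
    frame_rate: float = 30.0,
    jitter_tolerance_s: float = 0.005,
) -> list[tuple[float, int]]:
    """Map each time to the index of the nearest frame.

    A time farther than half a frame period (+ jitter tolerance) from every
    frame is dropped.  On an exact tie the earlier frame wins.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size == 0:
        return []
    tol = 0.5 / frame_rate + jitter_tolerance_s
    out: list[tuple[float, int]] = []
    for tt in times:
        i = int(np.searchsorted(frame_times, tt))
        candidates = [j for j in (i - 1, i) if 0 <= j < frame_times.size]
        # earlier frame first so that an exact tie keeps it
        best = min(candidates, key=lambda j: (abs(frame_times[j] - tt), j))
        if abs(frame_times[best] - tt) <= tol:
            out.append((tt, best))
    return out


def remove_background(
    depth_frame: np.ndarray,
    subject_distance_m: float = DEFAULT_SUBJECT_DISTANCE_M,
    band_m: float = DEFAULT_DEPTH_BAND_M,
) -> np.ndarray:
    """Foreground mask: pixels within the depth band, largest component only.

    ``depth_frame`` is in meters; zeros (invalid depth) never match.
    """
    depth = np.asarray(depth_frame, dtype=float)
    mask = (depth >= subject_distance_m - band_m) & (depth <= subject_distance_m + band_m)
    mask &= depth > 0
    if not mask.any():
        return mask
    labels, nlab = ndimage.label(mask)
    if nlab > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, nlab + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


def lean_angle_deg(landmarks: LandmarkPair) -> float:
    """Angle between the waist->head vector and the image vertical axis.

    Image coordinates have y growing downward, so "up" is (0, -1).
    Invariant to uniform scaling and translation of both landmarks.
    """
    dx = landmarks.head_xy[0] - landmarks.waist_xy[0]
    dy = landmarks.head_xy[1] - landmarks.waist_xy[1]
    # component along up = -dy; perpendicular magnitude = |dx|
    return math.degrees(math.atan2(abs(dx), -dy))


def classify_posture(
    landmarks: LandmarkPair | None,
    baseline_lean_deg: float = 0.0,
    threshold_deg: float = DEFAULT_LEAN_THRESHOLD_DEG,
) -> PostureDecision:
    """Upright / not-upright decision at one head-upright instant.

    ``uncomputable`` is a value, not an error: it covers missing frames and
    low-confidence landmarks, and its session-level fraction is reported.
    """
    if landmarks is None:
        return PostureDecision(float("nan"), "uncomputable")
    if min(landmarks.conf_head, landmarks.conf_waist) < CONFIDENCE_FLOOR:
        return PostureDecision(landmarks.t, "uncomputable")
    lean = lean_angle_deg(landmarks)
    upright = abs(lean - baseline_lean_deg) <= threshold_deg
    return PostureDecision(landmarks.t, "upright" if upright else "not_upright", lean)


@dataclass
class ClassificationMetrics:
    accuracy: float | None
    precision: float | None
    recall: float | None

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in {
                "accuracy": self.accuracy,
                "precision": self.precision,
                "recall": self.recall,
            }.items()
        }


def classification_metrics(tn: int, fp: int, fn: int, tp: int) -> ClassificationMetrics:
    """Accuracy / precision / recall of a 2x2 confusion matrix.

    Conventional definitions: precision = TP/(TP+FP), recall = TP/(TP+FN).
    A zero denominator yields None for that metric.
    """
    counts = (tn, fp, fn, tp)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return ClassificationMetrics(accuracy, precision, recall)


# ---------------------------------------------------------------------------
# Landmark sources


def landmarks_from_csv(path) -> list[LandmarkPair]:
    """Read a landmark series CSV (t, head_x, head_y, waist_x, waist_y,
    conf_head, conf_waist), bypassing imaging entirely."""
    df = pd.read_csv(path)
    return [
        LandmarkPair(
            float(r.t),
            (float(r.head_x), float(r.head_y)),
            (float(r.waist_x), float(r.waist_y)),
            float(getattr(r, "conf_head", 1.0)),
            float(getattr(r, "conf_waist", 1.0)),
        )
        for r in df.itertuples()
    ]


def make_table_provider(pairs: list[LandmarkPair]) -> Callable:
    """Landmark provider backed by a precomputed table (synthetic backend).

    Returns the pair nearest in time to the frame's timestamp attribute.
    """
    times = np.array([p.t for p in pairs])

    def provider(frame_t: float, mask=None) -> LandmarkPair | None:
        if times.size == 0:
            return None
        i = int(np.argmin(np.abs(times - frame_t)))
        return pairs[i]

    return provider


@dataclass
class PostureReport:
    decisions: list[PostureDecision]

    @property
    def uncomputable_fraction(self) -> float:
        if not self.decisions:
            return 0.0
        bad = sum(1 for d in self.decisions if d.label == "uncomputable")
        return bad / len(self.decisions)


def assess_posture_session(
    head_pitch: EulerSeries,
    frame_times: np.ndarray,
    provider: Callable,
    baseline_lean_deg: float = 0.0,
    threshold_deg: float = DEFAULT_LEAN_THRESHOLD_DEG,
    params: HeadMovementParams | None = None,
    frame_rate: float = 30.0,
) -> PostureReport:
    """Full posture pipeline over a session: peaks -> frames -> landmarks -> labels."""
    peaks = pitch_peak_times(head_pitch, params)
    matches = match_frames(peaks, frame_times, frame_rate)
    matched_times = {tt for tt, _ in matches}
    decisions: list[PostureDecision] = []
    for tt in peaks:
        if tt not in matched_times:
            decisions.append(PostureDecision(tt, "uncomputable"))
            continue
        idx = next(i for t2, i in matches if t2 == tt)
        lm = provider(float(frame_times[idx]))
        d = classify_posture(lm, baseline_lean_deg, threshold_deg)
        decisions.append(PostureDecision(tt, d.label, d.lean_deg))
    return PostureReport(decisions)
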