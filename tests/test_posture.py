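"""Posture pipeline: pitch peaks, frame matching, depth masking, lean
classification and the confusion-matrix metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balancemocap.orientation import EulerSeries
from balancemocap.posture import (
    LandmarkPair,
    PostureReport,
    classification_metrics,
    classify_posture,
    lean_angle_deg,
    match_frames,
    pitch_peak_times,
    remove_background,
)
from balancemocap.simdata import ScenarioSpec, simulate
from balancemocap.posture import make_table_provider
from balancemocap.pipeline import capture_session


def pitch_series(t, pitch):
    z = np.zeros_like(t)
    return EulerSeries("head", t, z, np.asarray(pitch, float), z.copy())


class TestPitchPeaks:
    def test_single_bend_and_return(self):
        # trapezoidal dip with small recovery overshoot at a known apex
        t = np.arange(0, 10, 0.01)
        pitch = -40 * np.clip(np.sin(np.pi * (t - 2) / 3), 0, None) ** 2
        pitch += 8 * np.exp(-((t - 5.6) ** 2) / 0.1)
        peaks = pitch_peak_times(pitch_series(t, pitch))
        assert 1 <= len(peaks) <= 2
        assert min(abs(p - 5.6) for p in peaks) < 0.1

    def test_constant_pitch_no_peaks(self):
        t = np.arange(0, 5, 0.01)
        assert pitch_peak_times(pitch_series(t, np.zeros(t.size))) == []

    def test_five_bends_give_five_peaks(self):
        spec = ScenarioSpec("bend_stand", duration_s=30.0, n_bends=5, seed=1)
        session, truth = simulate(spec)
        res = capture_session(session, landmark_provider=make_table_provider(truth.landmarks))
        peaks = pitch_peak_times(res.head_euler)
        assert abs(len(peaks) - 5) <= 1


class TestMatchFrames:
    frame_times = np.arange(0, 2.0, 1 / 30)

    def test_exact_hit(self):
        out = match_frames([self.frame_times[7]], self.frame_times)
        assert out == [(self.frame_times[7], 7)]

    def test_nearest_and_tie_break_earlier(self):
        mid = (self.frame_times[3] + self.frame_times[4]) / 2
        out = match_frames([mid], self.frame_times)
        assert out[0][1] == 3  # equidistant -> earlier frame
        near4 = self.frame_times[4] - 0.001
        assert match_frames([near4], self.frame_times)[0][1] == 4

    def test_time_beyond_frames_dropped(self):
        out = match_frames([self.frame_times[-1] + 0.5], self.frame_times)
        assert out == []

    def test_empty_frame_index(self):
        assert match_frames([1.0], np.array([])) == []


class TestRemoveBackground:
    def test_person_blob_kept_wall_removed(self):
        depth = np.full((40, 40), 3.0)
        depth[10:30, 15:25] = 1.85  # person at the configured distance
        mask = remove_background(depth, 1.85)
        expected = np.zeros((40, 40), bool)
        expected[10:30, 15:25] = True
        np.testing.assert_array_equal(mask, expected)

    def test_uniform_far_depth_empty(self):
        assert not remove_background(np.full((20, 20), 3.0), 1.85).any()

    def test_largest_of_two_blobs_kept(self):
        depth = np.full((40, 40), 3.0)
        depth[5:10, 5:10] = 1.85
        depth[20:35, 20:35] = 1.85
        mask = remove_background(depth, 1.85)
        assert mask[25, 25] and not mask[7, 7]


class TestClassifyPosture:
    def test_head_above_waist_upright(self):
        lm = LandmarkPair(0.0, (100.0, 50.0), (100.0, 200.0))
        d = classify_posture(lm, baseline_lean_deg=0.0)
        assert d.label == "upright" and d.lean_deg == pytest.approx(0.0)

    def test_45_degree_lean_not_upright(self):
        lm = LandmarkPair(0.0, (250.0, 50.0), (100.0, 200.0))
        d = classify_posture(lm, 0.0, threshold_deg=10.0)
        assert d.label == "not_upright" and d.lean_deg == pytest.approx(45.0)

    def test_low_confidence_uncomputable(self):
        lm = LandmarkPair(0.0, (100.0, 50.0), (100.0, 200.0), conf_waist=0.2)
        assert classify_posture(lm).label == "uncomputable"

    @settings(deadline=None, max_examples=25)
    @given(
        scale=st.floats(min_value=0.1, max_value=10.0),
        dx=st.floats(min_value=-500, max_value=500),
        dy=st.floats(min_value=-500, max_value=500),
    )
    def test_scale_translation_invariance(self, scale, dx, dy):
        head, waist = np.array([120.0, 40.0]), np.array([100.0, 200.0])
        base = lean_angle_deg(LandmarkPair(0, tuple(head), tuple(waist)))
        moved = lean_angle_deg(
            LandmarkPair(0, tuple(head * scale + [dx, dy]), tuple(waist * scale + [dx, dy]))
        )
        assert moved == pytest.approx(base, abs=1e-6)


class TestClassificationMetrics:
    def test_posture_validation_confusion_matrix(self):
        """Counts from the posture validation study: 71 assessable bends."""
        m = classification_metrics(tn=8, fp=5, fn=7, tp=51)
        assert m.rounded()["accuracy"] == 0.83
        assert m.precision == pytest.approx(51 / 56)  # 0.91
        assert m.rounded()["precision"] == 0.91
        assert m.rounded()["recall"] == 0.88  # TP/(TP+FN) = 51/58

    def test_perfect_classifier(self):
        m = classification_metrics(tn=10, fp=0, fn=0, tp=20)
        assert (m.accuracy, m.precision, m.recall) == (1.0, 1.0, 1.0)

    def test_zero_denominator_marker(self):
        m = classification_metrics(tn=5, fp=0, fn=3, tp=0)
        assert m.precision is None
        assert m.recall == 0.0


class TestEndToEnd:
    def test_simulated_bends_label_accuracy(self):
        """With ~2 px landmark noise and lean separation >> threshold, the
        pipeline recovers >= 95 % of ground-truth labels."""
        correct = total = 0
        for seed in (11, 12, 13, 14):
            spec = ScenarioSpec("bend_stand", duration_s=30.0, n_bends=5, seed=seed)
            session, truth = simulate(spec)
            res = capture_session(
                session, landmark_provider=make_table_provider(truth.landmarks)
            )
            labels = [d.label for d in res.posture.decisions if d.label != "uncomputable"]
            expect = ["upright" if r else "not_upright" for r in truth.posture_labels]
            if len(labels) == len(expect):
                correct += sum(a == b for a, b in zip(labels, expect))
                total += len(expect)
        assert total >= 15
        assert correct / total >= 0.95

    def test_uncomputable_fraction_reported(self):
        decisions = [
            classify_posture(LandmarkPair(0, (0, 0), (0, 10), conf_head=c))
            for c in (1.0, 1.0, 0.1, 1.0)
        ]
        report = PostureReport(decisions)
        assert report.uncomputable_fraction == pytest.approx(0.25)
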