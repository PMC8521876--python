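"""Rule engine, motor score and agreement statistics."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balancemocap.assessment import (
    ExerciseScore,
    Rule,
    agreement_stats,
    aggregate_analytic,
    evaluate_online,
    load_rules,
    motor_score,
    score_report,
)
from balancemocap.errors import ConfigurationError, DegenerateTargetError


def sway_rule(threshold=40.0):
    return Rule("sway_hi", "sway_radius_deg_s", ">", threshold, "safety_alert",
                "sway {value:.0f}")


class TestEvaluateOnline:
    def test_threshold_rule_fires_once(self):
        msgs = evaluate_online({"sway_radius_deg_s": 55.0}, [sway_rule()])
        assert len(msgs) == 1
        assert msgs[0].severity == "safety_alert"
        assert "55" in msgs[0].text

    def test_empty_rule_set(self):
        assert evaluate_online({"sway_radius_deg_s": 55.0}, []) == []

    def test_rule_below_threshold_silent(self):
        assert evaluate_online({"sway_radius_deg_s": 10.0}, [sway_rule()]) == []

    def test_safety_ordered_before_advice(self):
        advice = Rule("r2", "head_range_pitch_deg", ">", 15.0, "correction_advice", "pitch")
        msgs = evaluate_online(
            {"sway_radius_deg_s": 50.0, "head_range_pitch_deg": 20.0},
            [advice, sway_rule()],
        )
        assert [m.severity for m in msgs] == ["safety_alert", "correction_advice"]

    def test_baseline_dependent_ratio(self):
        r = Rule("low", "head_range_yaw_deg", "<", 0.8, "correction_advice", "small",
                 category="baseline_dependent", baseline_key="head_range_yaw_deg",
                 baseline_mode="ratio")
        base = {"head_range_yaw_deg": 50.0}
        assert evaluate_online({"head_range_yaw_deg": 30.0}, [r], base)
        assert not evaluate_online({"head_range_yaw_deg": 45.0}, [r], base)

    def test_purity(self):
        wm = {"sway_radius_deg_s": 55.0}
        a = evaluate_online(wm, [sway_rule()], t=3.0)
        b = evaluate_online(wm, [sway_rule()], t=3.0)
        assert [m.to_dict() for m in a] == [m.to_dict() for m in b]

    def test_cross_plane_movement_advice(self):
        """Pitch movement during a yaw exercise triggers correction advice."""
        from balancemocap.pipeline import capture_session
        from balancemocap.simdata import ScenarioSpec, simulate

        session, _ = simulate(ScenarioSpec("head_turns_pitch", duration_s=12.0, seed=3))
        metrics = capture_session(session).metrics_dict()
        advice = Rule("xplane", "head_range_pitch_deg", ">", 15.0,
                      "correction_advice", "keep the movement horizontal")
        msgs = evaluate_online(metrics, [advice])
        assert len(msgs) == 1


class TestRuleLoading:
    def test_unknown_metric_rejected_at_load(self, tmp_path):
        p = tmp_path / "rules.yaml"
        p.write_text(
            "rules:\n"
            "  - {id: r1, metric: bogus, op: '>', threshold: 1, "
            "severity: safety_alert, message: x}\n"
        )
        with pytest.raises(ConfigurationError, match="bogus"):
            load_rules(p, known_metrics={"sway_radius_deg_s"})

    def test_missing_baseline_key_rejected(self, tmp_path):
        p = tmp_path / "rules.yaml"
        p.write_text(
            "rules:\n"
            "  - {id: r1, metric: m, op: '>', threshold: 1, severity: safety_alert,\n"
            "     message: x, category: baseline_dependent, baseline_key: nope}\n"
        )
        with pytest.raises(ConfigurationError, match="nope"):
            load_rules(p, baseline={"other": 1.0})

    def test_shipped_demo_rules_load(self):
        from importlib import resources

        path = resources.files("balancemocap") / "config" / "demo_rules.yaml"
        rules = load_rules(str(path))
        assert len(rules) >= 2


class TestAggregate:
    def test_mean(self):
        assert aggregate_analytic([10, 20, 30]) == 20.0

    def test_single(self):
        assert aggregate_analytic([7]) == 7.0

    def test_permutation_invariant(self):
        assert aggregate_analytic([3, 1, 2]) == aggregate_analytic([1, 2, 3])

    def test_empty_marker(self):
        assert aggregate_analytic([]) is None


class TestMotorScore:
    def test_at_target(self):
        ms, _ = motor_score({"a": 20.0, "b": 1.0}, {"a": 10.0, "b": 0.0}, {"a": 20.0, "b": 1.0})
        assert ms == 1.0

    def test_at_baseline(self):
        ms, _ = motor_score({"a": 10.0}, {"a": 10.0}, {"a": 20.0})
        assert ms == 0.0

    def test_two_analytic_arithmetic(self):
        ms, raw = motor_score(
            {"a": 15.0, "b": 0.25}, {"a": 10.0, "b": 0.0}, {"a": 20.0, "b": 1.0}
        )
        assert ms == pytest.approx(0.375)
        assert raw == {"a": pytest.approx(0.5), "b": pytest.approx(0.25)}

    def test_lower_is_better_analytic(self):
        # sway: baseline 30, target 10, achieved 15 -> progress 0.75
        ms, _ = motor_score({"sway": 15.0}, {"sway": 30.0}, {"sway": 10.0})
        assert ms == pytest.approx(0.75)

    def test_clamping_keeps_score_in_unit_interval(self):
        ms, raw = motor_score({"a": 100.0, "b": -5.0}, {"a": 0.0, "b": 0.0}, {"a": 10.0, "b": 10.0})
        assert ms == pytest.approx(0.5)
        assert raw["a"] == pytest.approx(10.0) and raw["b"] == pytest.approx(-0.5)

    def test_degenerate_target(self):
        with pytest.raises(DegenerateTargetError, match="a"):
            motor_score({"a": 5.0}, {"a": 3.0}, {"a": 3.0})

    @settings(deadline=None, max_examples=30)
    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_affine_invariance_per_analytic(self, a, b):
        M, Mb, T = {"x": 14.0}, {"x": 10.0}, {"x": 20.0}
        ms1, _ = motor_score(M, Mb, T)
        ms2, _ = motor_score(
            {"x": a * 14.0 + b}, {"x": a * 10.0 + b}, {"x": a * 20.0 + b}
        )
        assert ms2 == pytest.approx(ms1, abs=1e-9)

    def test_monotone_in_progress(self):
        prev = -1.0
        for m in np.linspace(10, 20, 11):
            ms, _ = motor_score({"a": float(m), "b": 5.0}, {"a": 10.0, "b": 0.0},
                                {"a": 20.0, "b": 10.0})
            assert ms >= prev
            prev = ms


class TestScoreReport:
    def test_report_structure_and_roundtrip(self, tmp_path):
        score = ExerciseScore(
            analytics={"head_range_yaw_deg": [55.0, 60.0], "sway_radius_deg_s": [12.0]},
            baselines={"head_range_yaw_deg": 40.0, "sway_radius_deg_s": 30.0},
            targets={"head_range_yaw_deg": 60.0, "sway_radius_deg_s": 10.0},
        )
        rep = score_report(score)
        assert set(rep["analytics"]) == {"head_range_yaw_deg", "sway_radius_deg_s"}
        assert 0.0 <= rep["motor_score"] <= 1.0
        assert rep["message_log"] == []
        p = tmp_path / "r.json"
        p.write_text(json.dumps(rep))
        assert json.loads(p.read_text()) == rep


class TestAgreementStats:
    def test_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = agreement_stats(x, x)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["bland_altman"] == {"bias": 0.0, "loa_low": 0.0, "loa_high": 0.0}

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        out = agreement_stats(x, x + 2.0)
        # differences x - y are uniformly -2: bias -2, zero-width limits
        assert out["bland_altman"]["bias"] == pytest.approx(-2.0)
        assert out["bland_altman"]["loa_low"] == pytest.approx(-2.0)
        assert out["bland_altman"]["loa_high"] == pytest.approx(-2.0)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_against_closed_form_ols(self, rng):
        x = rng.uniform(0, 10, 10)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.5, 10)
        out = agreement_stats(x, y)
        # brute-force R^2 from the normal equations
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert out["r_squared"] == pytest.approx(r2, abs=1e-9)

    def test_zero_variance_marker(self):
        out = agreement_stats(np.ones(5), np.arange(5.0))
        assert out["r_squared"] is None
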