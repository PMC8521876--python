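"""Gait pipeline: turn/stop rejection, event detection, temporal
parameters and center of pressure."""

import numpy as np
import pytest

from balancemocap.errors import InsufficientStepsError
from balancemocap.gait import (
    GaitCycle,
    GaitEventTable,
    InsoleLayout,
    cop_trajectory,
    detect_gait_events,
    foot_rotation,
    gait_parameters,
    omit_turns_and_stops,
)
from balancemocap.pipeline import capture_session
from balancemocap.simdata import ScenarioSpec, simulate


@pytest.fixture(scope="module")
def layout():
    return InsoleLayout.from_yaml()


class TestFootRotation:
    def test_zero_gyro(self):
        t = np.arange(0, 5, 0.01)
        np.testing.assert_array_equal(foot_rotation(np.zeros(t.size), t), 0.0)

    def test_constant_rate(self):
        t = np.arange(0, 2 + 1e-9, 0.01)
        yaw = foot_rotation(np.full(t.size, 90.0), t)
        assert yaw[-1] == pytest.approx(180.0, abs=1e-9)

    def test_simulated_turn_profile(self):
        spec = ScenarioSpec("walk_with_turns", duration_s=22.0, seed=5)
        session, truth = simulate(spec)
        ch = session.stream("insole_left").channels
        yaw = foot_rotation(ch["Gz"], session.grid)
        assert yaw[-1] == pytest.approx(180.0, abs=5.0)


class TestOmitTurnsAndStops:
    def test_straight_walk_single_bout(self):
        spec = ScenarioSpec("walk_straight", duration_s=16.0, seed=2)
        session, truth = simulate(spec)
        res = capture_session(session)
        assert len(res.validity.bouts) == 1
        a, b = res.validity.bouts[0]
        assert a < 2.5 and b > 13.5  # spans the walk minus boundary regions

    def test_turn_splits_bouts_and_is_masked(self):
        spec = ScenarioSpec("walk_with_turns", duration_s=22.0, seed=2)
        session, truth = simulate(spec)
        res = capture_session(session)
        assert len(res.validity.bouts) == 2
        (ta, tb) = truth.turn_intervals[0]
        core = (res.validity.t > ta + 0.2) & (res.validity.t < tb - 0.2)
        assert not res.validity.mask[core].any()

    def test_standing_still_no_bouts(self):
        spec = ScenarioSpec("quiet_stance", duration_s=15.0, seed=2)
        session, truth = simulate(spec)
        t = session.grid
        accel = {}
        gyro = {}
        for foot in ("left", "right"):
            ch = session.stream(f"insole_{foot}").channels
            accel[foot] = np.column_stack([ch["Ax"], ch["Ay"], ch["Az"]])
            gyro[foot] = ch["Gz"]
        vm = omit_turns_and_stops(t, accel, gyro)
        assert vm.bouts == []


class TestDetectGaitEvents:
    def test_synthetic_stances_recovered_within_one_sample(self, layout):
        """Noise-free trapezoidal stance profiles: every event within 10 ms
        of its construction-time truth."""
        spec = ScenarioSpec("walk_straight", duration_s=16.0, seed=4, dropout_rate=0.0)
        from balancemocap.simdata import NoiseModel

        session, truth = simulate(spec, NoiseModel.silent())
        res = capture_session(session)
        for foot in ("left", "right"):
            cycles = [c for c in res.event_table.cycles[foot] if c.full_scale]
            assert cycles, foot
            for kind in ("heel_strike", "flat_foot", "heel_rise", "toe_off"):
                true_times = np.array(truth.events[foot][kind])
                for c in cycles:
                    est = getattr(c, kind)
                    assert np.min(np.abs(true_times - est)) < 0.010 + 1e-9

    def test_zero_pressure_empty(self, layout):
        t = np.arange(0, 10, 0.01)
        assert detect_gait_events(t, np.zeros((t.size, 16)), layout, "left") == []

    def test_constant_saturated_pressure_empty(self, layout):
        t = np.arange(0, 10, 0.01)
        assert detect_gait_events(t, np.full((t.size, 16), 20.0), layout, "left") == []


def make_table(hs_left, hs_right, stance=0.7):
    """Hand-built cycle table with the stated stance duration."""

    def cycles(foot, strikes):
        return [
            GaitCycle(foot, 0, h, h + 0.2, h + 0.5, h + stance, full_scale=True)
            for h in strikes
        ]

    return GaitEventTable({"left": cycles("left", hs_left), "right": cycles("right", hs_right)})


class TestGaitParameters:
    def test_hand_computed_example(self):
        """L strikes 0.0/1.2/2.4 s, R 0.6/1.8 s, stances 0.7 s: stride 1.2,
        step 0.6, cadence 100, double support 0.1 s per transition."""
        m = gait_parameters(make_table([0.0, 1.2, 2.4], [0.6, 1.8]))
        assert m.stride_time_mean_sd[0] == pytest.approx(1.2)
        assert m.step_time_mean_sd[0] == pytest.approx(0.6)
        assert m.cadence_steps_per_min == pytest.approx(100.0)
        assert m.double_support_s == pytest.approx([0.1, 0.1, 0.1, 0.1])

    def test_single_stride_insufficient(self):
        with pytest.raises(InsufficientStepsError):
            gait_parameters(make_table([0.0, 1.2], [0.6]))

    def test_periodic_walk_zero_stride_spread(self):
        spec = ScenarioSpec("walk_straight", duration_s=16.0, seed=6)
        session, truth = simulate(spec)
        res = capture_session(session)
        mean, sd = res.gait.stride_time_mean_sd
        assert mean == pytest.approx(truth.stride_time_s, rel=0.02)
        assert sd < 0.01

    def test_time_scaling(self):
        c = 1.25
        m1 = gait_parameters(make_table([0.0, 1.2, 2.4], [0.6, 1.8]))
        m2 = gait_parameters(
            make_table([0.0, 1.2 * c, 2.4 * c], [0.6 * c, 1.8 * c], stance=0.7 * c)
        )
        assert m2.stride_time_mean_sd[0] == pytest.approx(c * m1.stride_time_mean_sd[0])
        assert m2.step_time_mean_sd[0] == pytest.approx(c * m1.step_time_mean_sd[0])
        assert m2.double_support_mean_sd[0] == pytest.approx(c * m1.double_support_mean_sd[0])
        assert m2.cadence_steps_per_min == pytest.approx(m1.cadence_steps_per_min / c)

    def test_stride_equals_sum_of_steps(self):
        m = gait_parameters(make_table([0.0, 1.2, 2.4, 3.6], [0.6, 1.8, 3.0]))
        stride = m.stride_time_mean_sd[0]
        steps = np.asarray(m.step_times_s)
        assert stride == pytest.approx(steps[:-1].reshape(-1)[0] + steps[1], abs=1e-9)

    def test_turn_injection_changes_straight_metrics_little(self):
        base_spec = ScenarioSpec("walk_straight", duration_s=22.0, seed=8)
        turn_spec = ScenarioSpec("walk_with_turns", duration_s=22.0, seed=8)
        m0 = capture_session(simulate(base_spec)[0]).gait
        m1 = capture_session(simulate(turn_spec)[0]).gait
        for attr in ("stride_time_mean_sd", "step_time_mean_sd"):
            v0, v1 = getattr(m0, attr)[0], getattr(m1, attr)[0]
            assert abs(v1 - v0) / v0 < 0.01


class TestCop:
    def test_single_active_sensor(self, layout):
        t = np.array([0.0, 0.01])
        p = np.zeros((2, 16))
        p[:, 4] = 10.0  # p04 at (30, 0) on the left foot
        cop = cop_trajectory(t, p, layout, "left")
        assert cop.x_mm[0] == pytest.approx(30.0)
        assert cop.y_mm[0] == pytest.approx(0.0)

    def test_two_equal_sensors_midpoint(self, layout):
        t = np.array([0.0])
        p = np.zeros((1, 16))
        p[0, 0] = 5.0  # (15, -15)
        p[0, 1] = 5.0  # (15, 15)
        cop = cop_trajectory(t, p, layout, "left")
        assert (cop.x_mm[0], cop.y_mm[0]) == (pytest.approx(15.0), pytest.approx(0.0))

    def test_heel_to_toe_roll_monotone(self, layout):
        # load moves rear -> fore; CoP x must increase monotonically
        t = np.arange(0, 1.0, 0.01)
        w = t / t[-1]
        p = np.zeros((t.size, 16))
        for i in range(5):
            p[:, i] = 10 * (1 - w)
        for i in range(9, 16):
            p[:, i] = 10 * w
        cop = cop_trajectory(t, p, layout, "left")
        good = np.isfinite(cop.x_mm)
        assert np.all(np.diff(cop.x_mm[good]) >= -1e-9)

    def test_cop_inside_sensor_hull_and_gap_when_unloaded(self, layout, rng):
        t = np.arange(0, 2.0, 0.01)
        p = np.abs(rng.normal(2.0, 1.0, (t.size, 16)))
        p[50:60] = 0.0
        cop = cop_trajectory(t, p, layout, "left")
        xs = [xy[0] for xy in layout.coords["left"].values()]
        ys = [xy[1] for xy in layout.coords["left"].values()]
        good = np.isfinite(cop.x_mm)
        assert np.all(cop.x_mm[good] >= min(xs)) and np.all(cop.x_mm[good] <= max(xs))
        assert np.all(cop.y_mm[good] >= min(ys)) and np.all(cop.y_mm[good] <= max(ys))
        assert not np.isfinite(cop.x_mm[55])

    def test_max_pressure_per_step(self, layout):
        t = np.arange(0, 1.0, 0.01)
        p = np.zeros((t.size, 16))
        p[20:40, 3] = 7.0
        cop = cop_trajectory(t, p, layout, "left", stances=[(0.2, 0.4)])
        assert cop.max_pressure_per_step == [7.0]
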