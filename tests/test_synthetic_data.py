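"""Target-trajectory generators and the ground-truth eye simulator."""

import math

import numpy as np
import pytest

from gazecmp.simulate import (
    CalibrationField,
    SimulationConfig,
    apply_calibration_field,
    make_circular,
    make_saccade_task,
    make_step_ramp,
    minimum_jerk_profile,
    minimum_jerk_saccade,
    simulate_trace,
)
from gazecmp.trace import resample


def quiet_config(rate=500.0, **kw):
    """Noise-free deterministic configuration for geometric checks."""
    defaults = dict(rate=rate, fixation_noise_sd=0.0, drift_rate_sd=0.0,
                    blink_rate=0.0, seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSaccadeTask:
    def test_trial_timing(self):
        traj = make_saccade_task(1, 500.0)[0]
        assert traj.time[-1] == pytest.approx(4.0)
        labels = [s.label for s in traj.segments]
        assert labels == ["fixation", "jump", "fixation", "jump", "fixation"]

    def test_eight_trials_cover_all_directions(self):
        trajs = make_saccade_task(8, 500.0, seed=5)
        assert {t.meta["direction"] for t in trajs} == set(range(8))

    def test_eccentric_targets_on_ten_degree_circle(self):
        for traj in make_saccade_task(8, 230.0, seed=1):
            hold = (traj.time >= 1.0) & (traj.time < 3.0)
            r = np.hypot(traj.tx[hold], traj.ty[hold])
            assert np.abs(r - 10.0).max() < 1e-9


class TestStepRamp:
    def test_ramp_reaches_opposite_position(self):
        for traj in make_step_ramp(4, 500.0, seed=0):
            seg = traj.pursuit_segments()[0]
            i1 = np.searchsorted(traj.time, 1.0)
            i3 = np.searchsorted(traj.time, 3.0) - 1
            p_start = np.array([traj.tx[i1], traj.ty[i1]])
            p_end = np.array([traj.tx[i3], traj.ty[i3]])
            assert np.hypot(*p_start) == pytest.approx(10.0)
            # end of the 2-s ramp is (within one sample) at the mirror point
            assert np.allclose(p_end, -p_start, atol=10.0 * 2 / 500 + 1e-9)
            assert seg.params["speed"] == 10.0

    def test_ramp_speed_constant(self):
        traj = make_step_ramp(1, 500.0, seed=2)[0]
        inside = (traj.time > 1.01) & (traj.time < 2.99)
        v = np.hypot(np.gradient(traj.tx, 0.002), np.gradient(traj.ty, 0.002))
        assert np.abs(v[inside] - 10.0).max() < 1e-6

    def test_four_trials_cover_all_directions(self):
        trajs = make_step_ramp(4, 230.0, seed=3)
        assert {t.meta["direction"] for t in trajs} == {"up", "down", "left",
                                                        "right"}


class TestCircular:
    def test_orbit_duration_rounds_to_printed_value(self):
        traj = make_circular(1, 500.0)[0]
        seg = traj.pursuit_segments()[0]
        duration = seg.t1 - seg.t0
        assert duration == pytest.approx(1.25 * 2 * math.pi * 5.0 / 10.0)
        assert round(duration, 1) == 3.9

    def test_orbit_radius_constant(self):
        traj = make_circular(1, 230.0, seed=7)[0]
        seg = traj.pursuit_segments()[0]
        on = (traj.time >= seg.t0) & (traj.time < seg.t1 - 1e-9)
        assert np.abs(np.hypot(traj.tx[on], traj.ty[on]) - 5.0).max() < 1e-6

    def test_tangential_speed(self):
        traj = make_circular(1, 500.0, seed=9)[0]
        seg = traj.pursuit_segments()[0]
        inner = (traj.time > seg.t0 + 0.01) & (traj.time < seg.t1 - 0.01)
        v = np.hypot(np.gradient(traj.tx, 0.002), np.gradient(traj.ty, 0.002))
        assert np.abs(v[inner] - 10.0).max() < 1e-3


class TestMinimumJerk:
    def test_peak_velocity_closed_form(self):
        s = minimum_jerk_saccade(10.0, 0.04)
        assert s.peak_velocity == pytest.approx(468.75)
        t = np.linspace(0, 0.04, 4001)
        v = np.gradient(s(t), t)
        assert v.max() == pytest.approx(468.75, rel=1e-5)

    def test_endpoints(self):
        s = minimum_jerk_saccade(7.5, 0.035)
        assert s(0.0) == 0.0
        assert s(0.035) == pytest.approx(7.5)

    def test_small_saccade_peak_below_run_threshold(self):
        assert minimum_jerk_saccade(1.0, 0.03).peak_velocity == pytest.approx(62.5)
        assert minimum_jerk_saccade(1.0, 0.03).peak_velocity < 100.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            minimum_jerk_saccade(10.0, 0.0)
        with pytest.raises(ValueError):
            minimum_jerk_saccade(0.0, 0.04)

    def test_profile_monotone(self):
        tau = np.linspace(0, 1, 100)
        assert (np.diff(minimum_jerk_profile(tau)) >= 0).all()


class TestSimulateTrace:
    def test_same_seed_is_bit_identical(self):
        traj = make_saccade_task(1, 500.0, seed=4)[0]
        cfg = SimulationConfig(rate=500.0, seed=11)
        a, gta = simulate_trace(traj, cfg)
        b, gtb = simulate_trace(traj, cfg)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.valid, b.valid)
        assert [s.onset_t for s in gta.saccades] == [s.onset_t for s in gtb.saccades]
        assert gta.blinks == gtb.blinks

    def test_primary_saccade_undershoots_ten_percent(self):
        traj = make_saccade_task(1, 500.0, seed=4)[0]
        trace, gt = simulate_trace(traj, quiet_config())
        primary = gt.saccades[0]
        assert primary.kind == "primary"
        assert primary.amplitude == pytest.approx(9.0)
        i = np.searchsorted(trace.time, primary.offset_t)
        assert np.hypot(trace.x[i], trace.y[i]) == pytest.approx(9.0, abs=1e-6)

    def test_corrective_saccade_closes_residual_error(self):
        traj = make_saccade_task(1, 500.0, seed=4)[0]
        _, gt = simulate_trace(traj, quiet_config())
        kinds = [s.kind for s in gt.saccades]
        assert "corrective" in kinds
        corr = gt.saccades[kinds.index("corrective")]
        assert corr.amplitude == pytest.approx(1.0, abs=0.05)
        assert corr.peak_velocity < 100.0

    def test_pursuit_steady_state_speed_matches_gain(self):
        traj = make_step_ramp(1, 500.0, seed=6)[0]
        trace, gt = simulate_trace(traj, quiet_config(pursuit_gain=0.9))
        dt = trace.dt
        vx = np.gradient(trace.x, dt)
        vy = np.gradient(trace.y, dt)
        speed = np.hypot(vx, vy)
        # samples inside the ramp, at least 25 ms away from any true saccade
        keep = (trace.time > 1.0) & (trace.time < 3.0 - dt)
        for s in gt.saccades:
            keep &= (trace.time < s.onset_t - 0.025) | \
                    (trace.time > s.offset_t + 0.025)
        assert keep.sum() > 100
        assert np.abs(speed[keep] - 9.0).max() < 1e-3

    def test_ground_truth_complete(self):
        traj = make_circular(1, 230.0, seed=8)[0]
        trace, gt = simulate_trace(traj, SimulationConfig(rate=230.0, seed=8))
        n_jumps = sum(1 for s in traj.segments if s.label == "jump")
        assert len(gt.saccades) >= n_jumps
        for a, b in gt.blinks:
            assert trace.time[0] <= a <= b <= trace.time[-1] + 1e-9
        for s in gt.saccades:
            assert trace.time[0] <= s.onset_t <= s.offset_t <= trace.time[-1] + 1e-9

    def test_incompatible_rates_rejected(self):
        traj = make_saccade_task(1, 230.0)[0]
        with pytest.raises(ValueError, match="incompatible"):
            simulate_trace(traj, SimulationConfig(rate=500.0))

    def test_downsampling_consistency(self):
        # the same trajectory rendered at 500 Hz then resampled to 230 Hz
        # matches a direct 230 Hz rendering: identical events within one
        # 230-Hz sample period of alignment, and positions within 0.05 deg
        # outside the in-flight saccade samples (where a sub-sample timing
        # offset scales by several hundred deg/s)
        cfg500 = quiet_config(rate=500.0, seed=13)
        cfg230 = quiet_config(rate=230.0, seed=13)
        tr500, gt500 = simulate_trace(make_saccade_task(1, 500.0, seed=13)[0],
                                      cfg500)
        tr230, gt230 = simulate_trace(make_saccade_task(1, 230.0, seed=13)[0],
                                      cfg230)
        dt230 = 1.0 / 230.0
        assert len(gt500.saccades) == len(gt230.saccades)
        for a, b in zip(gt500.saccades, gt230.saccades):
            assert a.kind == b.kind
            # reactive events quantize twice: at their trigger and at their
            # own onset scheduling
            assert abs(a.onset_t - b.onset_t) < 2 * dt230
            assert abs(a.amplitude - b.amplitude) < 0.05
        down = resample(tr500, 230.0)
        n = min(down.n, tr230.n)
        err = np.hypot(down.x[:n] - tr230.x[:n], down.y[:n] - tr230.y[:n])
        outside = np.ones(n, bool)
        for s in gt500.saccades + gt230.saccades:
            outside &= ~((down.time[:n] > s.onset_t - dt230)
                         & (down.time[:n] < s.offset_t + dt230))
        assert outside.sum() > 0.8 * n
        assert err[outside].max() < 0.05


class TestCalibrationField:
    def test_zero_field_is_identity(self):
        traj = make_saccade_task(1, 500.0)[0]
        trace, _ = simulate_trace(traj, quiet_config())
        out = apply_calibration_field(trace, CalibrationField.zero())
        assert np.array_equal(out.x, trace.x)

    def test_linear_vertical_field_example(self):
        f = CalibrationField()
        f.cy[2] = -0.1  # dy = -0.1 * y
        _, dy_low = f.offset(0.0, -10.0)
        _, dy_high = f.offset(0.0, 10.0)
        assert dy_low == pytest.approx(1.0)
        assert dy_high == pytest.approx(-1.0)

    def test_central_offset_term(self):
        f = CalibrationField.constant(0.3, -0.2)
        dx, dy = f.offset(0.0, 0.0)
        assert (dx, dy) == (pytest.approx(0.3), pytest.approx(-0.2))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(undershoot_frac=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(pursuit_gain=0.0)
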