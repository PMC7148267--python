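"""Saccade detectors, blink detection, and event summaries."""

import numpy as np
import pytest

from gazecmp.detect import (
    BlinkEvent,
    DetectorConfig,
    blink_exclusion_windows,
    detect_blinks,
    detect_saccades_run,
    detect_saccades_vel_acc,
    elii_detector_config,
    esc_detector_config,
    summarize_saccade,
)
from gazecmp.simulate import SimulationConfig, make_two_saccade_trace
from gazecmp.trace import compute_velocity

from conftest import make_trace, speed_velocity_trace


def brute_force_runs(mask, min_run):
    """Reference scan: maximal runs of True of length >= min_run."""
    runs, start = [], None
    for i, m in enumerate(list(mask) + [False]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    return runs


class TestRunRule:
    def test_example_sequence(self):
        trace, vel = speed_velocity_trace([0, 50, 120, 130, 120, 40, 0])
        events = detect_saccades_run(trace, vel)
        assert len(events) == 1
        assert (events[0].onset_i, events[0].offset_i) == (2, 4)

    def test_constant_zero_speed_yields_nothing(self):
        trace, vel = speed_velocity_trace(np.zeros(100))
        assert detect_saccades_run(trace, vel) == []

    def test_short_runs_ignored(self):
        trace, vel = speed_velocity_trace([0, 120, 130, 0, 0, 150, 0])
        assert detect_saccades_run(trace, vel) == []

    def test_runs_split_by_invalid_samples(self):
        valid = np.ones(9, bool)
        valid[4] = False
        trace, vel = speed_velocity_trace(
            [0, 120, 120, 120, 120, 120, 120, 120, 0], valid=valid)
        events = detect_saccades_run(trace, vel)
        assert [(e.onset_i, e.offset_i) for e in events] == [(1, 3), (5, 7)]

    def test_threshold_is_strict(self):
        trace, vel = speed_velocity_trace([0, 100.0, 100.0, 100.0, 0])
        assert detect_saccades_run(trace, vel) == []

    def test_small_minimum_jerk_saccade_invisible(self):
        trace, _ = make_two_saccade_trace(corrective_amp=1.0)
        vel = compute_velocity(trace)
        events = detect_saccades_run(trace, vel)
        assert len(events) == 1  # only the 10-deg saccade
        assert events[0].amplitude > 5.0


class TestVelAccRule:
    def test_example_sequence_longer_event(self):
        trace, vel = speed_velocity_trace([0, 50, 120, 130, 120, 40, 0])
        events = detect_saccades_vel_acc(trace, vel)
        assert len(events) == 1
        assert (events[0].onset_i, events[0].offset_i) == (1, 5)
        run_event = detect_saccades_run(trace, vel)[0]
        assert events[0].duration_ms > run_event.duration_ms

    def test_quiet_fixation_yields_nothing(self, rng):
        trace, vel = speed_velocity_trace(np.abs(rng.normal(0, 5, 200)))
        assert detect_saccades_vel_acc(trace, vel) == []

    def test_small_saccade_detected(self):
        trace, _ = make_two_saccade_trace(corrective_amp=1.0)
        vel = compute_velocity(trace)
        events = detect_saccades_vel_acc(trace, vel)
        assert len(events) == 2
        assert min(e.amplitude for e in events) < 1.5

    def test_acceleration_criterion_alone_triggers(self):
        accel = np.zeros(7)
        accel[3] = 9000.0
        trace, vel = speed_velocity_trace([0, 0, 0, 10, 0, 0, 0], accel=accel)
        events = detect_saccades_vel_acc(trace, vel)
        assert [(e.onset_i, e.offset_i) for e in events] == [(3, 3)]

    def test_and_combinator_requires_both(self):
        accel = np.zeros(7)
        accel[3] = 9000.0
        trace, vel = speed_velocity_trace([0, 0, 0, 10, 0, 0, 0], accel=accel)
        cfg = DetectorConfig(rule="velocity_or_acceleration", v_threshold=30.0,
                             min_run=1, a_threshold=8000.0, combine="and")
        assert detect_saccades_vel_acc(trace, vel, cfg) == []


class TestOracleEquivalence:
    def test_both_detectors_match_brute_force(self, rng):
        """1,000 random speed/validity sequences against a reference scan."""
        run_cfg = esc_detector_config()
        va_cfg = elii_detector_config()
        for _ in range(1000):
            n = int(rng.integers(5, 200))
            speeds = rng.uniform(0, 150, n)
            accel = rng.uniform(-10000, 10000, n)
            valid = rng.random(n) > 0.05
            trace, vel = speed_velocity_trace(speeds, valid=valid, accel=accel)
            run_mask = valid & (speeds > run_cfg.v_threshold)
            got = [(e.onset_i, e.offset_i)
                   for e in detect_saccades_run(trace, vel, run_cfg)]
            assert got == brute_force_runs(run_mask, run_cfg.min_run)
            va_mask = valid & ((speeds > va_cfg.v_threshold)
                               | (np.abs(accel) > va_cfg.a_threshold))
            got = [(e.onset_i, e.offset_i)
                   for e in detect_saccades_vel_acc(trace, vel, va_cfg)]
            assert got == brute_force_runs(va_mask, va_cfg.min_run)


class TestThresholdMonotonicity:
    def test_higher_threshold_shrinks_events(self, rng):
        lo = DetectorConfig(rule="velocity_run", v_threshold=30.0, min_run=1)
        hi = DetectorConfig(rule="velocity_run", v_threshold=100.0, min_run=1)
        for _ in range(50):
            speeds = rng.uniform(0, 150, 150)
            trace, vel = speed_velocity_trace(speeds)
            lo_events = detect_saccades_run(trace, vel, lo)
            hi_events = detect_saccades_run(trace, vel, hi)
            # every high-threshold event lies inside some low-threshold event
            for h in hi_events:
                assert any(l.onset_i <= h.onset_i and h.offset_i <= l.offset_i
                           for l in lo_events)
                assert h.duration_ms <= max(
                    (l.duration_ms for l in lo_events
                     if l.onset_i <= h.onset_i <= l.offset_i), default=0.0)

    def test_mean_velocity_ordering_on_shared_saccade(self):
        trace, _ = make_two_saccade_trace()
        vel = compute_velocity(trace)
        run_e = detect_saccades_run(trace, vel)[0]
        va_e = max(detect_saccades_vel_acc(trace, vel), key=lambda e: e.amplitude)
        assert run_e.mean_velocity > va_e.mean_velocity
        assert run_e.duration_ms < va_e.duration_ms
        assert run_e.peak_velocity == pytest.approx(va_e.peak_velocity)

    def test_small_saccades_only_found_by_liberal_rule(self):
        for amp in (0.5, 1.0, 1.25):
            trace, gt = make_two_saccade_trace(corrective_amp=amp)
            assert gt.saccades[1].peak_velocity < 100.0
            vel = compute_velocity(trace)
            assert len(detect_saccades_run(trace, vel)) == 1
            assert len(detect_saccades_vel_acc(trace, vel)) == 2


class TestSummarize:
    def test_horizontal_displacement(self):
        trace, vel = speed_velocity_trace([0, 100, 100, 100, 0], rate=100.0)
        trace.x = np.array([0.0, 2.0, 5.0, 8.0, 10.0])
        e = summarize_saccade(trace, vel, 0, 4)
        assert e.amplitude == pytest.approx(10.0)
        assert e.direction_deg == pytest.approx(0.0)
        assert e.duration_ms == pytest.approx(40.0)

    def test_single_sample_event(self):
        trace, vel = speed_velocity_trace([0, 120, 0])
        e = summarize_saccade(trace, vel, 1, 1)
        assert e.duration_ms == 0.0
        assert e.mean_velocity == e.peak_velocity == pytest.approx(120.0)

    def test_invalid_sample_inside_event_rejected(self):
        valid = np.ones(5, bool)
        valid[2] = False
        trace, vel = speed_velocity_trace([0, 120, 120, 120, 0], valid=valid)
        with pytest.raises(ValueError, match="invalid sample"):
            summarize_saccade(trace, vel, 1, 3)


class TestBlinks:
    def test_fully_valid_trace(self):
        assert detect_blinks(make_trace(np.zeros(100))) == []

    def test_injected_run_duration(self):
        valid = np.ones(1000, bool)
        valid[200:275] = False  # 150 ms at 500 Hz
        blinks = detect_blinks(make_trace(np.zeros(1000), valid=valid))
        assert len(blinks) == 1
        dur = blinks[0].offset_t - blinks[0].onset_t
        assert abs(dur - 0.150) <= 1.0 / 500.0 + 1e-12

    def test_two_runs_separated_by_one_valid_sample(self):
        valid = np.ones(200, bool)
        valid[50:80] = False
        valid[81:111] = False
        assert len(detect_blinks(make_trace(np.zeros(200), valid=valid))) == 2

    def test_short_dropouts_ignored(self):
        valid = np.ones(200, bool)
        valid[50:55] = False  # 8 ms < 20 ms minimum
        assert detect_blinks(make_trace(np.zeros(200), valid=valid)) == []


class TestBlinkExclusionWindows:
    def test_padding_arithmetic(self):
        ws = blink_exclusion_windows([BlinkEvent(1.000, 1.150)])
        assert ws == [(pytest.approx(0.960), pytest.approx(1.210))]

    def test_empty_input(self):
        assert blink_exclusion_windows([]) == []

    def test_overlapping_windows_merge(self):
        ws = blink_exclusion_windows(
            [BlinkEvent(1.00, 1.10), BlinkEvent(1.12, 1.30)])
        assert len(ws) == 1
        assert ws[0] == (pytest.approx(0.96), pytest.approx(1.36))

    def test_clipping_to_trace_range(self):
        ws = blink_exclusion_windows([BlinkEvent(0.01, 3.99)], t_range=(0.0, 4.0))
        assert ws[0] == (pytest.approx(0.0), pytest.approx(4.0))


class TestDetectorConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(v_threshold=0.0)
        with pytest.raises(ValueError):
            DetectorConfig(min_run=0)
        with pytest.raises(ValueError):
            DetectorConfig(rule="nonsense")

    def test_empty_velocity_trace_yields_nothing(self):
        trace, vel = speed_velocity_trace(np.zeros(0))
        assert detect_saccades_run(trace, vel) == []
        assert detect_saccades_vel_acc(trace, vel) == []
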