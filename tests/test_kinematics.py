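"""Filtering, differentiation, movement segmentation and compliance rules."""

import numpy as np
import pytest

from soundloc3d import kinematics as kin


def bell_speed_positions(fs=100.0, duration=3.0, onset=1.0, offset=1.4, peak_mm_s=300.0):
    """1-D positions whose speed is a raised-cosine bell >= 80 mm/s on [onset, offset].

    Built by integrating the target speed profile, so the segmentation oracle
    is the construction itself.
    """
    t = np.arange(int(duration * fs) + 1) / fs
    # raised cosine peaking at the midpoint, crossing `thr` exactly at onset/offset
    thr = 80.0
    mid = (onset + offset) / 2
    p0 = np.arccos(1 - 2 * thr / peak_mm_s) / (2 * np.pi)  # phase where speed = thr
    support = ((offset - onset) / 2) / (0.5 - p0)
    phase = np.clip((t - mid) / support + 0.5, 0, 1)
    speed = peak_mm_s * 0.5 * (1 - np.cos(2 * np.pi * phase))
    pos_mm = np.cumsum(speed) / fs
    return t, pos_mm / 1000.0, speed


class TestLowpassFilter:
    def test_constant_unchanged(self):
        x = np.full((300, 3), 1.234)
        np.testing.assert_allclose(kin.lowpass_filter(x, 100.0, 30.0), x, atol=1e-9)

    def test_passband_sinusoid_amplitude_preserved(self):
        # 2 Hz sinusoid at 100 Hz with 45 Hz effective cutoff: amplitude within 1%
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t)
        y = kin.lowpass_filter(x, 100.0, 45.0)
        core = slice(100, 900)
        assert np.abs(y[core]).max() == pytest.approx(np.abs(x[core]).max(), rel=0.01)

    def test_noise_variance_strictly_reduced(self, rng):
        x = rng.normal(0, 1, 2000)
        y = kin.lowpass_filter(x, 100.0, 30.0)
        assert y.var() < x.var()

    def test_cutoff_at_nyquist_clamped_with_warning(self):
        x = np.zeros(500)
        with pytest.warns(RuntimeWarning, match="clamping"):
            kin.lowpass_filter(x, 100.0, 50.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            kin.lowpass_filter(np.zeros(10), 100.0, 30.0)


class TestVelocity:
    def test_linear_motion_constant_speed(self):
        t = np.arange(100) / 100.0
        pos = np.column_stack([0.1 * t, np.zeros_like(t), np.zeros_like(t)])
        v = kin.velocity(pos, 100.0)
        np.testing.assert_allclose(v.speed, 100.0, atol=1e-9)  # 0.1 m/s = 100 mm/s

    def test_stationary_track_zero(self):
        v = kin.velocity(np.ones((50, 3)), 100.0)
        np.testing.assert_array_equal(v.speed, 0.0)

    def test_central_difference_exact_for_quadratic(self):
        # p(t) = t^2 -> central difference = 2t exactly at interior samples
        t = np.arange(200) / 100.0
        v = kin.velocity(t**2, 100.0)
        np.testing.assert_allclose(v.speed[1:-1], 2 * t[1:-1] * 1000.0, atol=1e-6)

    def test_filter_then_differentiate_linear_track(self):
        t = np.arange(500) / 100.0
        pos = np.column_stack([0.05 * t, -0.02 * t, np.zeros_like(t)])
        v = kin.velocity(kin.lowpass_filter(pos, 100.0, 30.0), 100.0)
        expected = np.hypot(50.0, 20.0)
        np.testing.assert_allclose(v.speed[1:-1], expected, atol=1e-6)

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            kin.velocity(np.zeros((2, 3)), 100.0)


class TestSegmentation:
    def test_below_threshold_empty(self):
        s = kin.SpeedSeries(np.arange(100) / 100.0, np.full(100, 50.0))
        assert kin.segment_movements(s) == []

    def test_single_bell(self):
        t, pos, speed = bell_speed_positions(onset=1.00, offset=1.40)
        segs = kin.segment_movements(kin.SpeedSeries(t, speed))
        assert len(segs) == 1
        assert segs[0].onset == pytest.approx(1.00, abs=0.011)
        assert segs[0].offset == pytest.approx(1.40, abs=0.011)
        assert segs[0].peak_speed == pytest.approx(300.0, rel=1e-3)

    def test_two_separated_bells_in_order(self):
        t1, _, sp1 = bell_speed_positions(onset=0.5, offset=0.8)
        t2, _, sp2 = bell_speed_positions(onset=2.0, offset=2.3)
        speed = np.maximum(sp1, sp2)
        segs = kin.segment_movements(kin.SpeedSeries(t1, speed))
        assert len(segs) == 2
        assert segs[0].onset < segs[1].onset

    def test_detected_speed_from_positions_matches_construction(self):
        t, pos, speed = bell_speed_positions()
        v = kin.velocity(pos, 100.0)
        segs = kin.segment_movements(v)
        assert len(segs) == 1
        assert segs[0].onset == pytest.approx(1.0, abs=0.03)

    def test_min_duration_suppresses_spikes(self):
        speed = np.zeros(200)
        speed[50] = 500.0  # single-sample spike
        segs = kin.segment_movements(kin.SpeedSeries(np.arange(200) / 100.0, speed))
        assert segs == []

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_count_matches_injected_crossings(self, k):
        t = np.arange(1000) / 100.0
        speed = np.zeros_like(t)
        for i in range(k):
            _, _, sp = bell_speed_positions(duration=9.99, onset=1.0 + 2 * i, offset=1.5 + 2 * i)
            speed = np.maximum(speed, sp)
        segs = kin.segment_movements(kin.SpeedSeries(t, speed))
        assert len(segs) == k

    def test_raising_threshold_never_adds_segments(self, rng):
        t = np.arange(600) / 100.0
        speed = np.abs(rng.normal(0, 60, 600))
        counts = [
            len(kin.segment_movements(kin.SpeedSeries(t, speed), thr, min_duration_s=0.0))
            for thr in (40.0, 80.0, 120.0, 200.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestHeadMovementMetrics:
    def _seg(self, onset, offset=None):
        return kin.MovementSegment(onset, offset or onset + 0.3, 200.0)

    def test_after_window_movements_removed(self):
        m = kin.head_movement_metrics([self._seg(1.1), self._seg(3.1)])
        assert m["n_movements"] == 1
        assert m["first_onset"] == pytest.approx(1.1)

    def test_no_segments_flagged(self):
        m = kin.head_movement_metrics([])
        assert m["n_movements"] == 0 and not m["moved"]
        assert m["first_onset"] is None and m["first_end_azimuth"] is None

    def test_end_azimuth_interpolated_from_facing_series(self):
        t = np.arange(0, 4, 0.01)
        facing = np.interp(t, [0, 1.0, 1.4, 4.0], [0, 0, 30.0, 30.0])
        m = kin.head_movement_metrics([self._seg(1.0, 1.4)], facing_azimuth=(t, facing))
        assert m["first_end_azimuth"] == pytest.approx(30.0, abs=0.5)


class TestCompliance:
    def _seg(self, onset):
        return kin.MovementSegment(onset, onset + 0.3, 200.0)

    def test_static_hand_after_sound_accepted(self):
        rep = kin.check_compliance(1, "static", [], [self._seg(3.4)])
        assert not rep.rejected and rep.reason == "none"

    def test_static_head_movement_rejected(self):
        rep = kin.check_compliance(2, "static", [self._seg(1.5)], [self._seg(3.4)])
        assert rep.rejected and rep.reason == "head_move_in_static"

    def test_active_anticipatory_hand_rejected(self):
        rep = kin.check_compliance(3, "active", [self._seg(1.2)], [self._seg(2.0)])
        assert rep.rejected and rep.reason == "anticipatory_hand"

    def test_active_head_movement_allowed(self):
        rep = kin.check_compliance(4, "active", [self._seg(1.2)], [self._seg(3.5)])
        assert not rep.rejected

    def test_missing_track_rejected(self):
        with pytest.raises(ValueError):
            kin.check_compliance(5, "static", None, [])


class TestMovementOutliers:
    def test_quartile_oracle(self):
        vals = np.array([70, 75, 80, 72, 74, 0.0])
        q1, q3 = np.percentile(vals, [25, 75])  # linear-interpolation oracle
        lo = q1 - 1.5 * (q3 - q1)
        flagged = kin.detect_movement_outliers(vals)
        assert list(flagged) == [5] and vals[5] < lo

    def test_all_equal_none_flagged(self):
        assert len(kin.detect_movement_outliers(np.full(6, 80.0))) == 0

    def test_low_mover_among_typical_cohort(self):
        # one participant moving in 6.3% of trials among ~70-100% movers
        vals = np.array([73.0, 85.0, 96.0, 70.0, 88.0, 100.0, 6.3])
        flagged = kin.detect_movement_outliers(vals)
        assert list(flagged) == [6]

    def test_needs_four_values(self):
        with pytest.raises(ValueError):
            kin.detect_movement_outliers([1.0, 2.0, 3.0])
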