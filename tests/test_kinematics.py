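import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import infantmotion as im
from infantmotion.kinematics import (
    KinematicsConfig,
    PreprocessedTrajectory,
    butterworth_lowpass,
    mean_crossing_intervals,
    speed_series,
)
from infantmotion.tracking import Trajectory

from .oracles import area_ma, pearson_cc, periodicity_P


def _pre(points, fps=12.5, missing=None, limb="right_hand"):
    points = np.asarray(points, dtype=float)
    if missing is None:
        missing = np.isnan(points).any(axis=1)
    return PreprocessedTrajectory(points=points, missing=missing, fps=fps, limb=limb)


class TestInterpolateGaps:
    def test_linear_midpoint(self):
        pts = np.array([[0.0, 0.0], [np.nan, np.nan], [2.0, 4.0]])
        out, miss = im.interpolate_gaps(pts, np.array([False, True, False]))
        np.testing.assert_allclose(out[1], [1.0, 2.0])
        assert not miss.any()

    @pytest.mark.parametrize("gap,filled", [(5, True), (6, False)])
    def test_five_sample_limit(self, gap, filled):
        n = gap + 2
        pts = np.full((n, 2), np.nan)
        pts[0] = [0, 0]
        pts[-1] = [n - 1.0, 0]
        miss = np.isnan(pts[:, 0])
        out, new_miss = im.interpolate_gaps(pts, miss, max_gap=5)
        assert (not new_miss[1:-1].any()) == filled
        if filled:
            np.testing.assert_allclose(out[:, 0], np.arange(n, dtype=float))

    def test_max_filled_gap_spans_400ms_at_12p5hz(self):
        # longest interpolatable run = 5 samples -> 5 / 12.5 Hz = 0.4 s
        fps = 12.5
        assert KinematicsConfig().max_gap / fps == pytest.approx(0.400)

    def test_boundary_runs_never_extrapolated(self):
        pts = np.full((8, 2), np.nan)
        pts[3] = [1, 1]
        pts[4] = [2, 2]
        out, miss = im.interpolate_gaps(pts, np.isnan(pts[:, 0]))
        assert miss[:3].all() and miss[5:].all()
        assert np.isnan(out[0, 0]) and np.isnan(out[-1, 0])

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_valid_samples_never_modified(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        pts = rng.normal(0, 1, (n, 2))
        miss = rng.random(n) < 0.3
        pts[miss] = np.nan
        out, new_miss = im.interpolate_gaps(pts, miss)
        np.testing.assert_array_equal(out[~miss], pts[~miss])
        assert not (new_miss & ~miss).any()


class TestVelocityAcceleration:
    def test_constant_trajectory_zero_speed(self):
        tr = _pre(np.full((60, 2), 3.0))
        v = im.velocity(tr)
        assert v["mean"] == 0.0
        assert np.nanmax(np.abs(v["filtered"])) < 1e-9

    def test_uniform_motion_dc_gain_one(self):
        pts = np.column_stack([np.arange(100) * 0.25, np.zeros(100)])
        v = im.velocity(_pre(pts))
        assert v["mean"] == pytest.approx(0.25, abs=1e-9)

    def test_filter_barely_attenuates_smooth_speeds(self):
        t = np.arange(400) / 12.5
        pts = np.column_stack([np.sin(2 * np.pi * t / 4.0), np.zeros_like(t)])
        tr = _pre(pts)
        raw = speed_series(tr.points)
        filt = im.velocity(tr)["filtered"]
        assert np.nanmean(filt) == pytest.approx(np.nanmean(raw), rel=0.02)

    def test_mean_per_s_scales_with_fps(self):
        pts = np.column_stack([np.arange(50) * 0.1, np.zeros(50)])
        v = im.velocity(_pre(pts, fps=12.5))
        assert v["mean_per_s"] == pytest.approx(v["mean"] * 12.5)

    def test_acceleration_is_one_lag_diff(self, rng):
        v = rng.normal(1.0, 0.2, 200)
        acc = im.acceleration(v)["series"]
        np.testing.assert_allclose(acc[1:], np.diff(v), atol=1e-12)

    def test_linear_speed_gives_constant_acceleration(self):
        acc = im.acceleration(np.arange(50) * 0.01)
        assert acc["mean"] == pytest.approx(0.01)

    def test_undefined_when_no_consecutive_samples(self):
        pts = np.full((10, 2), np.nan)
        pts[::2] = 1.0
        tr = _pre(pts)
        assert im.velocity(tr)["mean"] is None

    def test_short_segments_left_unfiltered(self):
        series = np.full(8, np.nan)
        series[:5] = [1, 2, 3, 2, 1]
        out = butterworth_lowpass(series)
        np.testing.assert_array_equal(out[:5], [1, 2, 3, 2, 1])


class TestCrossCorrelation:
    def test_identical_series(self, rng):
        v = rng.normal(0, 1, 100)
        assert im.cross_correlation(v, v) == pytest.approx(1.0)

    def test_negated_series(self, rng):
        v = rng.normal(0, 1, 100)
        assert im.cross_correlation(v, -v) == pytest.approx(-1.0)

    def test_hand_worked_example(self):
        # cov = 1, both variances 1.25 -> CC = 0.8
        assert im.cross_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_series_undefined(self, rng):
        assert im.cross_correlation(np.ones(50), rng.normal(0, 1, 50)) is None

    def test_symmetry_and_bounds(self, rng):
        for _ in range(20):
            a, b = rng.normal(0, 1, (2, 64))
            cc = im.cross_correlation(a, b)
            assert cc == pytest.approx(im.cross_correlation(b, a))
            assert -1 <= cc <= 1

    def test_nan_overlap_handling(self, rng):
        a, b = rng.normal(0, 1, (2, 100))
        a[:30] = np.nan
        b[70:] = np.nan
        assert im.cross_correlation(a, b) == pytest.approx(pearson_cc(a[30:70], b[30:70]))


class TestAreaFromMovingAverage:
    def test_constant_is_zero(self):
        assert im.area_from_moving_average(np.full(100, 7.0)) == pytest.approx(0.0)

    def test_linear_ramp_is_zero(self):
        assert im.area_from_moving_average(np.arange(100, dtype=float)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_too_short_series_undefined(self):
        assert im.area_from_moving_average(np.ones(30), k=30) is None

    def test_sinusoid_matches_brute_force(self):
        x = np.sin(2 * np.pi * np.arange(200) / 10.0)
        assert im.area_from_moving_average(x, k=30) == pytest.approx(
            area_ma(x, k=30), abs=1e-9
        )

    def test_literal_divisor_variant(self, rng):
        x = rng.normal(0, 1, 150)
        got = im.area_from_moving_average(x, k=30, literal_divisor=True)
        assert got == pytest.approx(area_ma(x, k=30, literal=True), abs=1e-9)
        # the printed 1/k form does NOT vanish on a constant series
        const = im.area_from_moving_average(np.full(100, 5.0), k=30, literal_divisor=True)
        assert const > 1.0

    def test_amplitude_linearity(self, rng):
        x = rng.normal(0, 1, 120)
        a1 = im.area_from_moving_average(x)
        a3 = im.area_from_moving_average(3 * x)
        assert a3 == pytest.approx(3 * a1, rel=1e-12)


class TestPeriodicity:
    def test_constant_series_undefined(self):
        p = im.periodicity(np.full(600, 2.0))
        assert p["tin"] == 0 and p["P"] is None

    def test_sinusoid_t50_quarter_phase(self):
        # period 50 samples -> crossings every 25 samples
        x = np.sin(2 * np.pi * (np.arange(500) + 0.5) / 50.0)
        p = im.periodicity(x, window=500)
        assert p["d_mean"] == pytest.approx(25.0)
        assert p["d_sd"] == pytest.approx(0.0, abs=1e-12)
        assert p["P"] == pytest.approx(0.04)

    def test_window_spans_40s_at_12p5hz(self):
        assert KinematicsConfig().periodicity_window / 12.5 == pytest.approx(40.0)

    def test_trailing_partial_window_discarded(self):
        x = np.sin(2 * np.pi * np.arange(740) / 50.0)
        tin_740, _ = mean_crossing_intervals(x, window=500)
        tin_500, _ = mean_crossing_intervals(x[:500], window=500)
        assert tin_740 == tin_500

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(10):
            x = np.cumsum(rng.normal(0, 1, 1000))
            got = im.periodicity(x, window=500)
            tin, dbar, sd, P = periodicity_P(x, window=500)
            assert got["tin"] == tin
            assert got["d_mean"] == pytest.approx(dbar, abs=1e-9)
            assert got["d_sd"] == pytest.approx(sd, abs=1e-9)
            assert got["P"] == pytest.approx(P, abs=1e-9)

    def test_on_mean_samples_tie_leftward(self):
        # a plateau lying exactly on the window mean adopts the sign of the
        # previous off-mean sample, so the crossing registers at the plateau
        # END; with rightward ties the first distance would be 250, not 150
        x = np.concatenate([np.ones(100), np.zeros(100), -np.ones(150), np.ones(50)])
        assert x.mean() == 0.0  # the zeros sit exactly on the mean
        tin, dists = mean_crossing_intervals(x, window=400)
        assert tin == 2
        np.testing.assert_array_equal(dists, [150.0])

    def test_monotone_in_spread_at_fixed_mean(self):
        # same d_mean, larger sigma_d -> smaller P
        tight = 1.0 / (25.0 + 0.0)
        loose = 1.0 / (25.0 + 5.0)
        assert loose < tight


class TestFullBattery:
    def test_constant_limbs(self):
        trajs = {l: _pre(np.full((600, 2), 1.0), limb=l) for l in im.LIMBS}
        out = im.compute_kinematic_features(trajs, 12.5)
        for limb in im.LIMBS:
            d = out["limbs"][limb]
            assert d["mean_velocity"] == 0.0
            assert d["mean_acceleration"] == 0.0
            assert all(v == pytest.approx(0.0, abs=1e-9) for v in d["a_ma"].values())
            assert d["periodicity"]["P"] is None
        assert all(v is None for v in out["cross_correlation"].values())
        assert out["a_ma_total_upper"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_limb_flagged_not_zero(self):
        trajs = {"right_hand": _pre(np.random.default_rng(0).normal(0, 1, (600, 2)))}
        out = im.compute_kinematic_features(trajs, 12.5)
        assert out["limbs"]["left_hand"]["mean_velocity"] is None
        assert out["cross_correlation"]["right_hand|left_hand"] is None

    def test_cc_matrix_against_analytic_speeds(self):
        # limbs moving with known phase relations; CC of the package's
        # filtered speeds must match a direct evaluation on the same series
        rng = np.random.default_rng(5)
        t = np.arange(700)
        trajs = {}
        for i, limb in enumerate(im.LIMBS):
            x = 2.0 * np.sin(2 * np.pi * t / 40.0 + i * 0.7) + 0.05 * rng.normal(size=t.size)
            y = 1.5 * np.cos(2 * np.pi * t / 33.0 + i * 1.3)
            trajs[limb] = _pre(np.column_stack([x, y]), limb=limb)
        out = im.compute_kinematic_features(trajs, 12.5)
        speeds = {l: im.velocity(trajs[l])["filtered"] for l in im.LIMBS}
        for pair, got in out["cross_correlation"].items():
            l1, l2 = pair.split("|")
            v1, v2 = speeds[l1][1:], speeds[l2][1:]
            assert got == pytest.approx(pearson_cc(v1, v2), abs=1e-9)

    def test_head_length_scale_equivariance(self):
        # doubling the head length halves velocity and A_ma, leaves CC and
        # periodicity untouched
        rng = np.random.default_rng(8)
        base = {l: rng.normal(0, 5, (600, 2)).cumsum(axis=0) for l in im.LIMBS}
        trajs1 = {l: _pre(base[l], limb=l) for l in im.LIMBS}
        trajs2 = {l: _pre(base[l] / 2.0, limb=l) for l in im.LIMBS}
        out1 = im.compute_kinematic_features(trajs1, 12.5)
        out2 = im.compute_kinematic_features(trajs2, 12.5)
        for limb in im.LIMBS:
            d1, d2 = out1["limbs"][limb], out2["limbs"][limb]
            assert d2["mean_velocity"] == pytest.approx(d1["mean_velocity"] / 2, rel=1e-9)
            for ax in ("x", "y"):
                assert d2["a_ma"][ax] == pytest.approx(d1["a_ma"][ax] / 2, rel=1e-9)
            assert d2["periodicity"]["tin"] == d1["periodicity"]["tin"]
            assert d2["periodicity"]["P"] == pytest.approx(d1["periodicity"]["P"], rel=1e-9)
        for pair in out1["cross_correlation"]:
            assert out2["cross_correlation"][pair] == pytest.approx(
                out1["cross_correlation"][pair], rel=1e-9
            )


class TestPreprocess:
    def test_pixel_to_body_frame_pipeline(self):
        cal = im.Calibration(
            head_line=((0, 0), (0, 100)), symmetry_line=((50, 20), (50, 120))
        )
        pts = np.array([[60.0, 30.0], [np.nan, np.nan], [70.0, 40.0]])
        traj = Trajectory("right_hand", pts, np.array([False, True, False]))
        pre = im.preprocess(traj, cal, fps=12.5)
        assert pre.points.shape == (3, 2)
        assert not pre.missing.any()  # 1-sample gap interpolated
        # vertical symmetry line -> reorientation is identity; check units
        np.testing.assert_allclose(pre.points[0], [0.6, 0.3])
        np.testing.assert_allclose(pre.points[1], [0.65, 0.35])
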