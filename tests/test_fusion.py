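import numpy as np
import pytest

from aosize.echogram import Trace
from aosize.fusion import (
    AmbiguousCorrespondenceError,
    BeamProjectionModel,
    CameraIntrinsics,
    FusionConfig,
    MeasurementSeries,
    NoMeasurementError,
    SFLRelation,
    check_spatial_correspondence,
    map_to_3d,
    ml_to_sfl,
    project_beam,
    rectify_size,
    size_fish,
    temporal_window,
    trimmed_mean_size,
    undistort_point,
)
from aosize.geometry import render_silhouette
from aosize.vision import ModelFit, Track

from conftest import make_params


def _intr(f=1000.0, cx=320.0, cy=240.0, dist=(0.0, 0.0)):
    return CameraIntrinsics(f_px=f, cx=cx, cy=cy, distortion=np.array(dist))


def _series(values, p=0, z=1.0, f=1.0):
    return MeasurementSeries([(v * f / z, z, i, i)
                              for i, v in enumerate(values)], p=p)


class TestTemporalWindow:
    def test_published_window(self):
        t = Trace(trace_id=0, cells=np.zeros((1, 2), int))
        t.t_center_s = 10.0
        assert temporal_window(t) == (9.5, 10.5)

    def test_window_length_one_second(self):
        t = Trace(trace_id=0, cells=np.zeros((1, 2), int))
        for c in (0.0, 3.7, 1e4):
            t.t_center_s = c
            lo, hi = temporal_window(t)
            assert hi - lo == pytest.approx(1.0)

    def test_frame_count_at_35_fps(self):
        t = Trace(trace_id=0, cells=np.zeros((1, 2), int))
        t.t_center_s = 5.0
        lo, hi = temporal_window(t)
        ts = np.arange(0, 10, 1 / 35.0)
        n = ((ts >= lo) & (ts <= hi)).sum()
        assert abs(n - 35) <= 1


class TestBeamProjection:
    def test_closed_form_radius(self):
        bpm = BeamProjectionModel(half_angle_deg=3.5)
        _, radius = project_beam(bpm, _intr(f=1000.0), 4.0)
        assert radius == pytest.approx(1000.0 * np.tan(np.radians(3.5)))
        assert radius == pytest.approx(61.16, abs=0.05)

    def test_narrowing_halves_radius(self):
        bpm = BeamProjectionModel(half_angle_deg=3.5)
        narrow = BeamProjectionModel(half_angle_deg=3.5, narrowing_factor=0.5)
        intr = _intr()
        _, r1 = project_beam(bpm, intr, 4.0)
        _, r2 = project_beam(narrow, intr, 4.0)
        assert r2 == pytest.approx(r1 / 2)

    def test_coaxial_center_at_principal_point(self):
        intr = _intr(cx=320.0, cy=240.0)
        bpm = BeamProjectionModel(
            axis_ranges_m=np.array([1.0, 8.0]),
            axis_points_px=np.array([[320.0, 240.0], [320.0, 240.0]]))
        for r in (1.5, 4.0, 7.9):
            center, _ = project_beam(bpm, intr, r)
            np.testing.assert_allclose(center, [320.0, 240.0])

    def test_nonpositive_range_error(self):
        with pytest.raises(ValueError):
            project_beam(BeamProjectionModel(), _intr(), 0.0)

    def test_extrapolation_warns(self):
        bpm = BeamProjectionModel(axis_ranges_m=np.array([2.0, 6.0]),
                                  axis_points_px=np.zeros((2, 2)))
        with pytest.warns(UserWarning):
            project_beam(bpm, _intr(), 7.5)


class TestSpatialCorrespondence:
    def _fit(self, **over):
        return ModelFit(params=make_params(**over), fei=0.0, frame_index=0,
                        accepted=True)

    def test_centered_silhouette_intersects(self):
        fit = self._fit(sx=300.0, sy=240.0, alpha_deg=0.0)
        assert check_spatial_correspondence(fit, (np.array([350.0, 240.0]), 50.0))

    def test_far_silhouette_misses(self):
        fit = self._fit(sx=50.0, sy=50.0, alpha_deg=0.0)
        assert not check_spatial_correspondence(fit, (np.array([500.0, 400.0]), 40.0))

    def test_grazing_matches_pixel_oracle(self):
        # slide the disk away from the silhouette; the vector predicate must
        # agree with a brute-force pixel-level intersection test
        p = make_params(sx=200.0, sy=240.0, alpha_deg=0.0, theta_b_deg=0.0)
        mask, _ = render_silhouette(p, (480, 640))
        fit = ModelFit(params=p, fei=0.0, frame_index=0, accepted=True)
        yy, xx = np.mgrid[0:480, 0:640]
        radius = 40.0
        for cx in np.arange(330.0, 450.0, 7.0):
            center = np.array([cx, 150.0])
            disk = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2
            pixel_hit = bool((mask & disk).any())
            vector_hit = check_spatial_correspondence(fit, (center, radius))
            # allow disagreement only within one pixel of the boundary
            if pixel_hit != vector_hit:
                d_in = np.abs(np.sqrt(
                    (xx[mask] - center[0]) ** 2 + (yy[mask] - center[1]) ** 2
                ) - radius).min()
                assert d_in <= 1.5
            else:
                assert pixel_hit == vector_hit


class TestRectify:
    def test_zero_distortion_identity(self):
        assert rectify_size(123.4, _intr()) == 123.4
        eps = np.array([[100.0, 240.0], [300.0, 240.0]])
        assert rectify_size(200.0, _intr(), eps) == 200.0

    def test_radial_closed_form_through_principal_point(self):
        k1 = -0.1
        intr = _intr(f=1000.0, cx=320.0, cy=240.0, dist=(k1, 0.0))
        # distorted endpoint on the x axis through the principal point:
        # xd = xu (1 + k1 xu^2)  (normalized); invert analytically for the test
        xu = 0.2
        xd = xu * (1 + k1 * xu ** 2)
        eps = np.array([[320.0, 240.0], [320.0 + xd * 1000.0, 240.0]])
        expected = xu * 1000.0
        got = rectify_size(xd * 1000.0, intr, eps)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_monotone_in_size(self):
        intr = _intr(dist=(-0.05, 0.01))
        sizes = []
        for half in (50.0, 100.0, 150.0, 200.0):
            eps = np.array([[320.0 - half, 240.0], [320.0 + half, 240.0]])
            sizes.append(rectify_size(2 * half, intr, eps))
        assert np.all(np.diff(sizes) > 0)

    def test_undistort_inverts_distortion(self):
        intr = _intr(dist=(-0.08, 0.02))
        xu = np.array([0.15, -0.1])
        r2 = np.sum(xu ** 2)
        factor = 1 + intr.distortion[0] * r2 + intr.distortion[1] * r2 ** 2
        pd = xu * factor * intr.f_px + [intr.cx, intr.cy]
        pu = undistort_point(pd, intr)
        np.testing.assert_allclose(
            pu, xu * intr.f_px + [intr.cx, intr.cy], atol=1e-6)


class TestMapTo3D:
    def test_direct_substitution(self):
        assert map_to_3d(100.0, _intr(f=1000.0), 3.0) == pytest.approx(0.3)

    def test_proportional_in_range(self):
        intr = _intr()
        assert map_to_3d(50.0, intr, 6.0) == pytest.approx(
            2 * map_to_3d(50.0, intr, 3.0))

    def test_nonpositive_range_error(self):
        with pytest.raises(ValueError):
            map_to_3d(10.0, _intr(), 0.0)


class TestTrimmedMean:
    def test_all_equal_any_p(self):
        for p in (0, 1, 2):
            s = _series([0.7] * 7, p=p)
            assert trimmed_mean_size(s, _intr(f=1.0)) == pytest.approx(0.7)

    def test_p_zero_is_plain_mean(self, rng):
        vals = rng.uniform(0.4, 1.2, size=9)
        s = _series(vals, p=0)
        assert trimmed_mean_size(s, _intr(f=1.0)) == pytest.approx(vals.mean())

    def test_hand_computed_outlier_trim(self):
        s = _series([1.0, 1.1, 1.2, 5.0, 0.1], p=1)
        assert trimmed_mean_size(s, _intr(f=1.0)) == pytest.approx(1.1)

    def test_permutation_invariant_and_bounded(self, rng):
        vals = rng.uniform(0.3, 1.5, size=11)
        s1 = _series(vals, p=2)
        s2 = _series(vals[rng.permutation(11)], p=2)
        intr = _intr(f=1.0)
        m1 = trimmed_mean_size(s1, intr)
        assert m1 == pytest.approx(trimmed_mean_size(s2, intr))
        assert vals.min() <= m1 <= vals.max()

    def test_eq2_with_p0_equals_mean_of_eq1(self, rng):
        intr = _intr(f=850.0)
        entries = [(rng.uniform(50, 200), rng.uniform(2, 6), i, i)
                   for i in range(8)]
        s = MeasurementSeries(entries, p=0)
        per_frame = [map_to_3d(y, intr, z) for y, z, *_ in entries]
        assert trimmed_mean_size(s, intr) == pytest.approx(np.mean(per_frame))

    def test_overtrimming_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean_size(_series([1.0, 2.0], p=1), _intr())


class TestSFLRelation:
    def test_intercept(self):
        assert ml_to_sfl(0.0) == pytest.approx(0.065641)

    def test_slope_by_finite_difference(self):
        assert ml_to_sfl(1.0) - ml_to_sfl(0.0) == pytest.approx(1.0312)

    def test_strictly_increasing(self):
        mls = np.linspace(0.1, 1.5, 30)
        sfls = [ml_to_sfl(m) for m in mls]
        assert np.all(np.diff(sfls) > 0)

    def test_override(self):
        rel = SFLRelation(slope=1.0, intercept_m=0.0)
        assert ml_to_sfl(0.6, rel) == pytest.approx(0.6)


def _trace_for_sizing(t_center=5.0, z=4.0):
    t = Trace(trace_id=1, cells=np.zeros((1, 2), int))
    t.t_center_s = t_center
    pings = np.arange(95, 106)
    t.per_ping_max = np.column_stack(
        [pings, np.full(11, -40.0), np.full(11, z)])
    t.ping_times = pings * 0.05
    t.sti, t.sti_intercept_m = 0.0, z
    t.sti_per_s = 0.0
    return t


def _track_through_beam(track_id=0, n=5, t_center=5.0):
    fits = []
    for k in range(n):
        p = make_params(sx=260.0 + 5 * k, sy=240.0, alpha_deg=0.0,
                        theta_b_deg=0.0)
        f = ModelFit(params=p, fei=0.0, frame_index=k, accepted=True)
        f.t_s = t_center - 0.2 + 0.1 * k
        fits.append(f)
    return Track(track_id=track_id, fits=fits)


class TestSizeFish:
    def _setup(self):
        intr = _intr(f=700.0)
        bpm = BeamProjectionModel(
            half_angle_deg=3.5,
            axis_ranges_m=np.array([1.0, 8.0]),
            axis_points_px=np.array([[320.0, 240.0], [320.0, 240.0]]))
        return intr, bpm

    def test_sizes_single_track(self):
        intr, bpm = self._setup()
        trace = _trace_for_sizing(z=4.0)
        track = _track_through_beam()
        res = size_fish(track, trace, intr, bpm)
        # l = 150 px at z = 4 m, f = 700: ml = 150*4/700
        assert res.ml_m == pytest.approx(150.0 * 4.0 / 700.0, rel=1e-6)
        assert res.sfl_m == pytest.approx(1.0312 * res.ml_m + 0.065641)
        assert res.width_m == pytest.approx(30.0 * 4.0 / 700.0, rel=1e-6)
        assert res.n_measurements == 5

    def test_ambiguous_two_tracks(self):
        intr, bpm = self._setup()
        trace = _trace_for_sizing()
        t1 = _track_through_beam(0)
        t2 = _track_through_beam(1)
        with pytest.raises(AmbiguousCorrespondenceError):
            size_fish(t1, trace, intr, bpm, competing_tracks=(t2,))

    def test_no_frames_in_window(self):
        intr, bpm = self._setup()
        trace = _trace_for_sizing(t_center=50.0)
        track = _track_through_beam(t_center=5.0)
        with pytest.raises(NoMeasurementError):
            size_fish(track, trace, intr, bpm)

    def test_trim_count_rule(self):
        cfg = FusionConfig(trim_fraction=0.1)
        assert cfg.trim_count(24) == 2   # 24 entries -> trim 2 each tail
        assert cfg.trim_count(5) == 0
        assert cfg.trim_count(3) == 0
        assert cfg.trim_count(30) == 3
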