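"""Mitral-plane quantification: reformatting, motion correction,
segmentation, filtering, curves and E/A peak detection."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import mitralflow as mf
from mitralflow.datatypes import PlanePose

from oracles import auto_window_oracle, detect_ea_oracle


def uniform_field(vector, shape=(12, 12, 12), n_frames=4, voxel=2.8):
    data = np.zeros((3, *shape, n_frames))
    for c in range(3):
        data[c] = vector[c]
    return mf.VelocityField(
        data=data,
        affine=np.diag([voxel, voxel, voxel, 1.0]),
        frame_times=np.arange(n_frames, dtype=float) * 40.0,
        venc=120.0,
    )


def static_plane(origin, normal, basis, n_frames=4, plane_vel=0.0):
    poses = [
        PlanePose(
            origin=np.asarray(origin, float),
            normal=np.asarray(normal, float),
            basis=np.asarray(basis, float),
            frame_index=t,
        )
        for t in range(n_frames)
    ]
    tracks = np.zeros((2, n_frames, 3))
    tracks[0, :] = np.asarray(origin) - 5.0 * np.asarray(basis)[0]
    tracks[1, :] = np.asarray(origin) + 5.0 * np.asarray(basis)[0]
    return mf.TrackedPlane(
        poses=poses,
        landmark_tracks=tracks,
        plane_velocity=np.full(n_frames, plane_vel),
        frame_times=np.arange(n_frames, dtype=float) * 40.0,
    )


XY_BASIS = [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]


class TestReformat:
    def test_uniform_through_plane_velocity(self):
        field = uniform_field((0.0, 0.0, 10.0))
        plane = static_plane([15.0, 15.0, 15.0], [0.0, 0.0, 1.0], XY_BASIS)
        vmap = mf.reformat_velocity(field, plane, grid_extent=20.0)
        assert np.allclose(vmap.values[vmap.valid], 10.0)

    def test_in_plane_velocity_projects_to_zero(self):
        field = uniform_field((10.0, 0.0, 0.0))
        plane = static_plane([15.0, 15.0, 15.0], [0.0, 0.0, 1.0], XY_BASIS)
        vmap = mf.reformat_velocity(field, plane, grid_extent=20.0)
        assert np.allclose(vmap.values, 0.0, atol=1e-12)

    def test_out_of_volume_samples_invalid_and_zero(self):
        field = uniform_field((0.0, 0.0, 10.0))
        plane = static_plane([15.0, 15.0, 15.0], [0.0, 0.0, 1.0], XY_BASIS)
        vmap = mf.reformat_velocity(field, plane, grid_extent=100.0)
        assert not vmap.valid.all()
        assert np.allclose(vmap.values[~vmap.valid], 0.0)

    def test_frame_count_mismatch_rejected(self):
        field = uniform_field((0.0, 0.0, 10.0), n_frames=4)
        plane = static_plane([15.0, 15.0, 15.0], [0.0, 0.0, 1.0], XY_BASIS, n_frames=5)
        with pytest.raises(ValueError):
            mf.reformat_velocity(field, plane)

    def test_phantom_map_max_matches_attenuated_envelope(self, static_phantom):
        """At the E and A peak frames the plane-map maximum equals the
        envelope attenuated by the jet's axial profile at the plane."""
        ph = static_phantom
        plane = static_plane(
            [ph.params.axis_xy[0], ph.params.axis_xy[1], ph.params.annulus_z0],
            [0.0, 0.0, 1.0],
            XY_BASIS,
            n_frames=ph.params.n_frames,
        )
        vmap = mf.reformat_velocity(ph.velocity, plane)
        alpha = ph.truth.axial_attenuation_at_plane
        for t, peak in ((13, 60.0), (26, 50.0)):
            assert vmap.values[t].max() == pytest.approx(alpha * peak, rel=0.03)


class TestPlaneMotionCorrection:
    def test_static_plane_identity(self):
        field = uniform_field((0.0, 0.0, 10.0))
        plane = static_plane([15.0, 15.0, 15.0], [0.0, 0.0, 1.0], XY_BASIS)
        vmap = mf.reformat_velocity(field, plane, grid_extent=20.0)
        out = mf.correct_for_plane_motion(vmap)
        assert np.allclose(out.values, vmap.values)

    def test_comoving_fluid_and_plane_cancel(self):
        field = uniform_field((0.0, 0.0, 5.0))
        plane = static_plane(
            [15.0, 15.0, 15.0], [0.0, 0.0, 1.0], XY_BASIS, plane_vel=5.0
        )
        vmap = mf.reformat_velocity(field, plane, grid_extent=20.0)
        out = mf.correct_for_plane_motion(vmap)
        assert np.allclose(out.values[out.valid], 0.0, atol=1e-9)

    def test_phantom_correction_removes_annulus_motion_bias(self, default_phantom, tracked_plane):
        """Corrected peak E sits within 3% of the attenuated envelope; the
        uncorrected peak is offset by roughly the plane speed at peak E."""
        ph = default_phantom
        corrected = mf.mvvel_ea(ph.velocity, tracked_plane)
        uncorrected = mf.mvvel_ea(ph.velocity, tracked_plane, correct_motion=False)
        alpha = ph.truth.axial_attenuation_at_plane
        assert corrected.peaks.e_value == pytest.approx(alpha * 60.0, rel=0.03)
        bias = uncorrected.peaks.e_value - corrected.peaks.e_value
        plane_speed_at_e = ph.truth.plane_speed_at_frames[13]
        assert bias == pytest.approx(plane_speed_at_e, rel=0.5)
        assert abs(bias) > 0.5  # the uncorrected estimate is measurably biased

    def test_length_mismatch_rejected(self):
        field = uniform_field((0.0, 0.0, 10.0))
        plane = static_plane([15.0, 15.0, 15.0], [0.0, 0.0, 1.0], XY_BASIS)
        vmap = mf.reformat_velocity(field, plane, grid_extent=20.0)
        with pytest.raises(ValueError):
            mf.correct_for_plane_motion(vmap, np.zeros(3))


def make_map(frames, spacing=2.0):
    """PlaneVelocityMap from a list/array of 2D frames (all valid)."""
    values = np.asarray(frames, dtype=float)
    nt, n, _ = values.shape
    plane = static_plane([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], XY_BASIS, n_frames=nt)
    return mf.PlaneVelocityMap(
        values=values,
        valid=np.ones_like(values, dtype=bool),
        grid_spacing=spacing,
        grid_extent=spacing * (n - 1),
        plane=plane,
        frame_times=np.arange(nt, dtype=float) * 40.0,
    )


def disk(n, center, radius, value):
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    frame = np.zeros((n, n))
    frame[(ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2] = value
    return frame


class TestSegmentation:
    def test_zero_frame_gives_empty_mask(self):
        vmap = make_map(np.zeros((4, 21, 21)))
        masks = mf.segment_inflow_area(vmap)
        assert not masks.any()

    def test_central_jet_segmented_as_one_component(self):
        frame = disk(21, (10, 10), 5, 60.0)
        vmap = make_map([frame])
        masks = mf.segment_inflow_area(vmap)
        assert np.array_equal(masks[0], frame >= 9.0)  # 15% of 60

    def test_center_component_preferred_over_brighter_corner(self):
        frame = disk(21, (10, 10), 4, 60.0) + disk(21, (2, 2), 2, 80.0)
        vmap = make_map([frame])
        masks = mf.segment_inflow_area(vmap)
        assert masks[0, 10, 10]
        assert not masks[0, 2, 2]

    def test_nearest_component_used_when_center_empty(self):
        frame = disk(21, (4, 10), 3, 60.0) + disk(21, (17, 17), 1, 60.0)
        vmap = make_map([frame])
        masks = mf.segment_inflow_area(vmap)
        assert masks[0, 4, 10]
        assert not masks[0, 17, 17]

    def test_holes_filled(self):
        frame = disk(21, (10, 10), 6, 60.0)
        frame[10, 10] = 0.0
        vmap = make_map([frame])
        masks = mf.segment_inflow_area(vmap)
        assert masks[0, 10, 10]

    def test_velocity_floor_respected(self):
        vmap = make_map([np.full((21, 21), 3.0)])  # below the 5 cm/s floor
        masks = mf.segment_inflow_area(vmap)
        assert not masks.any()


class TestMedianFilterMap:
    def test_constant_frame_unchanged(self):
        vmap = make_map([np.full((15, 15), 7.0)])
        out = mf.median_filter_map(vmap)
        assert np.allclose(out.values, 7.0)

    def test_isolated_spike_removed(self):
        frame = np.zeros((15, 15))
        frame[7, 7] = 1000.0
        out = mf.median_filter_map(make_map([frame]))
        assert out.values[0, 7, 7] == 0.0

    def test_output_bounded_by_local_extrema(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(0, 20, size=(3, 17, 17))
        vmap = make_map(frames)
        out = mf.median_filter_map(vmap)
        from scipy import ndimage

        for t in range(3):
            lo = ndimage.minimum_filter(frames[t], size=3, mode="nearest")
            hi = ndimage.maximum_filter(frames[t], size=3, mode="nearest")
            assert np.all(out.values[t] >= lo - 1e-12)
            assert np.all(out.values[t] <= hi + 1e-12)


class TestCurves:
    def test_max_velocity_constant_inside_mask(self):
        vmap = make_map([np.full((11, 11), 10.0)] * 3)
        vmap.inflow_masks = np.ones_like(vmap.values, dtype=bool)
        curve = mf.max_velocity_curve(vmap)
        assert curve.kind == "max_velocity"
        assert np.allclose(curve.values, 10.0)

    def test_empty_masks_give_zero_curve(self):
        vmap = make_map([np.full((11, 11), 10.0)] * 3)
        vmap.inflow_masks = np.zeros_like(vmap.values, dtype=bool)
        assert np.allclose(mf.max_velocity_curve(vmap).values, 0.0)

    def test_flow_rate_velocity_times_area(self):
        """10 cm/s over a 4 cm^2 inflow area integrates to 40 mL/s."""
        vmap = make_map([np.full((11, 11), 10.0)], spacing=2.0)  # 2 mm pixels
        mask = np.zeros((1, 11, 11), dtype=bool)
        mask[0, :10, :10] = True  # 100 px * 4 mm^2 = 4 cm^2
        vmap.inflow_masks = mask
        curve = mf.flow_rate_curve(vmap)
        assert curve.kind == "flow_rate"
        assert curve.values[0] == pytest.approx(40.0)

    def test_curves_require_segmentation(self):
        vmap = make_map([np.zeros((11, 11))])
        with pytest.raises(ValueError):
            mf.max_velocity_curve(vmap)


def curve_of(values, dt=33.0):
    values = np.asarray(values, dtype=float)
    return mf.InflowCurve(
        times=np.arange(len(values)) * dt, values=values, kind="max_velocity"
    )


class TestDetectEA:
    def test_two_highest_peaks_selected_in_time_order(self):
        curve = curve_of([0, 0, 60, 10, 50, 5])
        pp = mf.detect_ea_peaks(curve, (0.0, 200.0))
        assert (pp.e_value, pp.a_value) == (60.0, 50.0)
        assert pp.ea_ratio == pytest.approx(1.2)
        assert not pp.fused

    def test_single_bump_flags_fused(self):
        t = np.arange(20) * 33.0
        bump = 50 * np.cos(np.pi * (t - 330) / 400) ** 2 * (np.abs(t - 330) < 200)
        with pytest.warns(RuntimeWarning):
            pp = mf.detect_ea_peaks(curve_of(bump), (0.0, 700.0))
        assert pp.fused
        assert pp.e_value is None

    def test_flat_window_flags_fused_not_error(self):
        with pytest.warns(RuntimeWarning):
            pp = mf.detect_ea_peaks(curve_of([5.0] * 10), (0.0, 400.0))
        assert pp.fused

    def test_low_prominence_maxima_discarded(self):
        # second bump prominence 4 < 10% of 60
        curve = curve_of([0, 0, 60, 30, 34, 30, 0, 50, 0])
        pp = mf.detect_ea_peaks(curve, (0.0, 400.0))
        assert (pp.e_value, pp.a_value) == (60.0, 50.0)

    def test_plateau_collapses_to_first_sample(self):
        curve = curve_of([0, 10, 50, 50, 50, 10, 40, 0, 0])
        pp = mf.detect_ea_peaks(curve, (0.0, 400.0))
        assert pp.e_value == 50.0
        assert pp.e_time == 2 * 33.0

    def test_equal_peaks_tie_broken_by_prominence_then_time(self):
        # three equal 50s: prominences 30, 20, 20 -> the most prominent wins,
        # then the earlier of the remaining equally prominent pair
        curve = curve_of([20, 50, 0, 50, 45, 50, 30])
        pp = mf.detect_ea_peaks(curve, (0.0, 250.0))
        assert pp.e_time == 1 * 33.0
        assert pp.a_time == 3 * 33.0
        assert pp.ea_ratio == pytest.approx(1.0)

    def test_too_few_window_samples_rejected(self):
        with pytest.raises(ValueError):
            mf.detect_ea_peaks(curve_of([0, 10, 0, 10, 0, 0]), (0.0, 100.0))

    def test_auto_window_starts_after_systole_at_first_positive(self):
        values = np.zeros(30)
        values[5] = 40.0  # systolic activity before cycle fraction 0.35 ignored
        values[13:16] = (30.0, 60.0, 10.0)
        values[24:27] = (20.0, 50.0, 5.0)
        pp = mf.detect_ea_peaks(curve_of(values), "auto")
        assert pp.diastole_window[0] == pytest.approx(13 * 33.0)
        assert pp.e_time == pytest.approx(14 * 33.0)
        assert pp.a_time == pytest.approx(25 * 33.0)

    def test_matches_brute_force_oracle_on_random_curves(self):
        rng = np.random.default_rng(12)
        for trial in range(300):
            n = rng.integers(8, 40)
            if trial % 2:
                values = rng.normal(20, 15, size=n)
            else:  # quantized curves exercise plateaus and ties
                values = rng.integers(0, 8, size=n).astype(float) * 10
            curve = curve_of(values)
            window = (0.0, float(curve.times[-1]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pp = mf.detect_ea_peaks(curve, window)
            expected = detect_ea_oracle(curve.times, values, window)
            if expected is None:
                assert pp.fused, f"trial {trial}"
            else:
                assert not pp.fused, f"trial {trial}"
                assert (pp.e_time, pp.e_value, pp.a_time, pp.a_value) == expected


class TestPipelines:
    def test_mvvel_deterministic(self, default_phantom, tracked_plane):
        a = mf.mvvel_ea(default_phantom.velocity, tracked_plane)
        b = mf.mvvel_ea(default_phantom.velocity, tracked_plane)
        assert np.array_equal(a.curve.values, b.curve.values)
        assert a.peaks == b.peaks

    def test_mvvel_recovers_truth_ratio(self, default_phantom, mvvel_result):
        truth = default_phantom.truth
        assert mvvel_result.peaks.ea_ratio == pytest.approx(truth.true_ea_ratio, rel=0.05)
        assert mvvel_result.peaks.e_value <= truth.true_peak_e
        assert mvvel_result.peaks.a_value <= truth.true_peak_a

    def test_mvflow_recovers_flow_ratio(self, default_phantom, mvflow_result):
        truth = default_phantom.truth
        expected = truth.true_peak_flow_e / truth.true_peak_flow_a
        assert mvflow_result.peaks.ea_ratio == pytest.approx(expected, rel=0.10)

    def test_auto_window_matches_oracle_on_phantom(self, default_phantom, mvvel_result):
        p = default_phantom.params
        window = auto_window_oracle(
            mvvel_result.curve.times, mvvel_result.curve.values, p.cycle_length
        )
        assert mvvel_result.peaks.diastole_window == pytest.approx(window)
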