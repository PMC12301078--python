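"""Localisation: FWHM profiles, plug detection, pose estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fourdqa.dicomio import CTVolume
from fourdqa.localize import (
    DetectionError,
    PhantomPose,
    ProfileTruncationError,
    detect_plug,
    fwhm_profile,
    locate_phantom,
    measure_plug_dimensions,
)
from fourdqa.synth import AcquisitionSpec, Renderer, render_phantom


class TestFWHMProfile:
    def test_plateau_profile(self):
        values = [0, 0, 500, 1000, 1000, 1000, 500, 0, 0]
        positions = np.arange(9.0)
        assert fwhm_profile(values, positions, 0, 1000) == pytest.approx(4.0)

    def test_single_peak_interpolation(self):
        assert fwhm_profile([0, 1000, 0], [0.0, 1.0, 2.0], 0, 1000) \
            == pytest.approx(1.0)

    def test_inverted_profile_same_width(self):
        values = np.array([0, 0, 500, 1000, 1000, 1000, 500, 0, 0], float)
        pos = np.arange(9.0)
        w_pos = fwhm_profile(values, pos, 0, 1000)
        w_neg = fwhm_profile(-values, pos, 0, -1000)
        assert w_neg == pytest.approx(w_pos)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_width_scales_with_positions(self, scale):
        values = [0, 100, 800, 1000, 750, 50, 0]
        pos = np.arange(7.0)
        w1 = fwhm_profile(values, pos, 0, 1000)
        w2 = fwhm_profile(values, pos * scale, 0, 1000)
        assert w2 == pytest.approx(w1 * scale, rel=1e-9)

    def test_truncated_profile_raises(self):
        with pytest.raises(ProfileTruncationError):
            fwhm_profile([0, 500, 1000], [0.0, 1.0, 2.0], 0, 1000)

    def test_never_attains_half_level(self):
        with pytest.raises(ProfileTruncationError):
            fwhm_profile([0, 100, 0], [0.0, 1.0, 2.0], 0, 1000)

    def test_positions_must_increase(self):
        with pytest.raises(ValueError):
            fwhm_profile([0, 1, 0], [0.0, 0.0, 1.0], 0, 1)


class TestLocatePhantom:
    def test_centre_recovered_at_grid_centre(self, small_geometry, small_acq):
        vol = render_phantom(small_geometry, (0, 0, 0), small_acq)
        pose = locate_phantom(vol, small_geometry)
        assert np.allclose(pose.center_mm, 0.0, atol=0.5)
        assert abs(pose.rotation_deg) < 2.0

    def test_shift_equivariance(self, small_geometry, small_acq):
        r = Renderer(small_geometry, small_acq)
        p0 = locate_phantom(r.render((0, 0, 0)), small_geometry)
        p1 = locate_phantom(r.render((3.0, 0, 0)), small_geometry)
        assert p1.center_mm[0] - p0.center_mm[0] == pytest.approx(3.0, abs=0.25)

    def test_air_only_volume_raises(self, small_geometry):
        vol = CTVolume(voxels=np.full((20, 20, 10), -1000.0, np.float32),
                       spacing_mm=(1, 1, 2))
        with pytest.raises(DetectionError):
            locate_phantom(vol, small_geometry)


class TestDetectPlug:
    def test_noiseless_centroid_subvoxel(self, small_geometry, small_acq):
        vol = render_phantom(small_geometry, (0, 0, 0), small_acq)
        pose = locate_phantom(vol, small_geometry)
        for pid in ("teflon", "air"):
            meas = detect_plug(vol, pose, small_geometry.plug(pid), small_geometry)
            truth = small_geometry.plug_center(pid)
            err = np.abs(np.array(meas.centroid_mm) - np.array(truth))
            assert np.all(err <= 0.5 * np.array(small_acq.voxel_spacing_mm))

    def test_centroid_tracks_displacement(self, small_geometry, small_acq):
        r = Renderer(small_geometry, small_acq)
        pose0 = locate_phantom(r.render((0, 0, 0)), small_geometry)
        v = r.render((0, 0, 2.5))
        pose = locate_phantom(v, small_geometry)
        m = detect_plug(v, pose, small_geometry.plug("teflon"), small_geometry)
        truth_z = small_geometry.plug_center("teflon")[2] + 2.5
        assert m.centroid_mm[2] == pytest.approx(truth_z, abs=1.0)

    def test_air_plug_uses_below_threshold_rule(self, small_geometry):
        acq = AcquisitionSpec(grid_shape=(72, 72, 36), psf_sigma_mm=0.0,
                              noise_sigma_hu=0.0)
        vol = render_phantom(small_geometry, (0, 0, 0), acq)
        pose = locate_phantom(vol, small_geometry)
        meas = detect_plug(vol, pose, small_geometry.plug("air"), small_geometry)
        assert meas.threshold_hu == pytest.approx(-500.0)
        assert meas.mean_hu == pytest.approx(-1000.0, abs=2.0)

    def test_plug_over_uniform_background_raises(self, small_geometry, small_acq):
        vol = render_phantom(small_geometry, (0, 0, 0), small_acq)
        pose = locate_phantom(vol, small_geometry)
        import dataclasses

        ghost = dataclasses.replace(small_geometry.plug("teflon"),
                                    theta_deg=150.0)  # unoccupied ring slot
        with pytest.raises(DetectionError):
            detect_plug(vol, pose, ghost, small_geometry)


class TestMeasurePlugDimensions:
    def test_noiseless_dimensions_match_geometry(self, small_geometry, small_acq):
        vol = render_phantom(small_geometry, (0, 0, 0), small_acq)
        pose = locate_phantom(vol, small_geometry)
        for pid in ("teflon", "air"):
            plug = small_geometry.plug(pid)
            m = measure_plug_dimensions(vol, pose, plug, small_geometry)
            assert m.fwhm_mm[0] == pytest.approx(plug.diameter_mm, abs=0.5)
            assert m.fwhm_mm[1] == pytest.approx(plug.diameter_mm, abs=0.5)
            assert m.fwhm_mm[2] == pytest.approx(plug.length_mm, abs=1.0)

    def test_motion_blur_never_narrows_z_fwhm(self, small_geometry, small_acq,
                                              small_sim_noiseless):
        stationary, series, _ = small_sim_noiseless
        pose_st = locate_phantom(stationary, small_geometry)
        plug = small_geometry.plug("teflon")
        m_st = measure_plug_dimensions(stationary, pose_st, plug, small_geometry)
        for vol in series:
            pose = locate_phantom(vol, small_geometry)
            m = measure_plug_dimensions(vol, pose, plug, small_geometry)
            assert m.fwhm_mm[2] >= m_st.fwhm_mm[2] - 0.35
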