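"""Image-quality metrics: oracles, invariances, error contracts."""

import dataclasses
import math

import numpy as np
import pytest

from fourdqa.dicomio import CTVolume
from fourdqa.geometry import (
    BeadSpec,
    MaterialSpec,
    ModuleSpec,
    PhantomGeometry,
)
from fourdqa.localize import PhantomPose, PlugMeasurement, locate_phantom
from fourdqa.quality import (
    ConfigurationError,
    cnr_low_contrast,
    geometric_distortion,
    hu_constancy,
    hu_consistency_per_plug,
    iq_suite,
    low_contrast_detectability,
    mtf_from_bead,
    noise,
    uniformity,
)
from fourdqa.synth import AcquisitionSpec, render_phantom


def _bead_only_geometry(bead_diameter_mm=1e-3):
    """Minimal valid geometry whose only purpose is to carry a bead spec."""
    return PhantomGeometry(
        model=504, outer_diameter_mm=200.0,
        background=MaterialSpec("water", 0), air=MaterialSpec("air", -1000),
        modules=(
            ModuleSpec("sensitometry", -60.0, 40.0),
            ModuleSpec("spatial_resolution", 0.0, 30.0,
                       bead=BeadSpec(0.0, 0.0, 0.0, bead_diameter_mm,
                                     MaterialSpec("bead", 3000))),
            ModuleSpec("uniformity", 65.0, 50.0),
        ))


def gaussian_psf_volume(sigma_mm, px_mm=0.25, n=161, nz=5):
    """Synthetic point-spread sample: an in-plane Gaussian blob on one slice."""
    xs = (np.arange(n) - n // 2) * px_mm
    blob = np.exp(-(xs[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_mm ** 2))
    vox = np.zeros((n, n, nz), dtype=np.float32)
    vox[:, :, nz // 2] = 1000.0 * blob
    return CTVolume(voxels=vox, spacing_mm=(px_mm, px_mm, 1.0),
                    origin_mm=(-(n // 2) * px_mm, -(n // 2) * px_mm, -(nz // 2)))


def analytic_gaussian_mtf10(sigma_mm):
    """Closed form: exp(-2 pi^2 s^2 f^2) = 0.10  =>  f10 in cycles/mm."""
    return math.sqrt(math.log(10.0) / (2.0 * math.pi ** 2 * sigma_mm ** 2))


ORIGIN_POSE = PhantomPose((0.0, 0.0, 0.0))


class TestMTF:
    @pytest.mark.parametrize("sigma", [0.3, 0.5, 0.9, 1.5])
    def test_gaussian_closed_form(self, sigma):
        curve, f10 = mtf_from_bead(gaussian_psf_volume(sigma), ORIGIN_POSE,
                                   _bead_only_geometry())
        assert not curve.saturated
        assert f10 / 10.0 == pytest.approx(analytic_gaussian_mtf10(sigma),
                                           rel=0.02)

    def test_doubling_sigma_halves_mtf10(self):
        _, f_a = mtf_from_bead(gaussian_psf_volume(0.5), ORIGIN_POSE,
                               _bead_only_geometry())
        _, f_b = mtf_from_bead(gaussian_psf_volume(1.0), ORIGIN_POSE,
                               _bead_only_geometry())
        assert f_b == pytest.approx(f_a / 2.0, rel=0.02)

    def test_zero_frequency_modulation_is_one(self):
        curve, _ = mtf_from_bead(gaussian_psf_volume(0.7), ORIGIN_POSE,
                                 _bead_only_geometry())
        assert curve.frequency_lp_per_cm[0] == 0.0
        assert curve.modulation[0] == pytest.approx(1.0)

    def test_unresolvable_psf_flags_saturation(self):
        # sigma far below what the sampling can resolve: the 10% crossing
        # lies beyond the capped band and must be flagged, not invented
        curve, f10 = mtf_from_bead(gaussian_psf_volume(0.3, px_mm=1.0, n=41),
                                   ORIGIN_POSE, _bead_only_geometry())
        assert curve.saturated
        assert f10 == pytest.approx(curve.frequency_lp_per_cm[-1])

    def test_no_bead_in_geometry(self, small_geometry):
        geom = dataclasses.replace(
            small_geometry,
            modules=tuple(dataclasses.replace(m, bead=None)
                          for m in small_geometry.modules))
        with pytest.raises(ConfigurationError):
            mtf_from_bead(gaussian_psf_volume(0.5), ORIGIN_POSE, geom)


class TestUniformityAndNoise:
    def test_constant_volume_zero(self, small_geometry):
        vol = CTVolume(voxels=np.zeros((72, 72, 36), np.float32),
                       spacing_mm=(1, 1, 2),
                       origin_mm=(-35.5, -35.5, -35.0))
        assert uniformity(vol, ORIGIN_POSE, small_geometry) == pytest.approx(0.0)
        assert noise(vol, ORIGIN_POSE, small_geometry) == pytest.approx(0.0)

    def test_linear_shading_matches_analytic_roi_difference(self, small_geometry):
        # 5 HU per 100 mm gradient along x: ROI means differ by the
        # gradient times the peripheral ROI offset; the ROI discs are
        # symmetric so their means sit exactly at their centres
        nx, ny, nz = 72, 72, 36
        xs = (np.arange(nx) - (nx - 1) / 2) * 1.0
        vox = np.broadcast_to(0.05 * xs[:, None, None], (nx, ny, nz))
        vol = CTVolume(voxels=np.ascontiguousarray(vox, dtype=np.float32),
                       spacing_mm=(1, 1, 2),
                       origin_mm=(-(nx - 1) / 2, -(ny - 1) / 2, -(nz - 1)))
        offset = 0.80 * small_geometry.outer_diameter_mm / 2.0
        expected = 0.05 * offset
        assert uniformity(vol, ORIGIN_POSE, small_geometry) \
            == pytest.approx(expected, abs=0.02)

    def test_seeded_noise_recovered(self, small_geometry, small_sim):
        stationary, _, _ = small_sim
        pose = locate_phantom(stationary, small_geometry)
        assert noise(stationary, pose, small_geometry) \
            == pytest.approx(10.0, rel=0.10)


class TestHUMetrics:
    def test_constancy_zero_on_exact_render(self, small_geometry):
        acq = AcquisitionSpec(grid_shape=(72, 72, 36), psf_sigma_mm=0.0,
                              noise_sigma_hu=0.0)
        vol = render_phantom(small_geometry, (0, 0, 0), acq)
        pose = locate_phantom(vol, small_geometry)
        assert hu_constancy(vol, pose, small_geometry) == pytest.approx(0.0,
                                                                        abs=0.5)

    def test_constancy_arithmetic(self):
        # measured (-998, -95, 126) against (-1000, -100, 120) -> max dev 6
        devs = [abs(-998 - (-1000)), abs(-95 - (-100)), abs(126 - 120)]
        assert max(devs) == 6

    def test_consistency_zero_for_identical_inputs(self):
        stat = {"ldpe": _pm("ldpe", -100.0)}
        bins = {"ldpe": [_pm("ldpe", -100.0)] * 3}
        assert hu_consistency_per_plug(bins, stat)["ldpe"] == pytest.approx(0.0)

    def test_consistency_mean_arithmetic(self):
        stat = {"acrylic": _pm("acrylic", 100.0)}
        bins = {"acrylic": [_pm("acrylic", v) for v in (100.0, 102.0, 98.0)]}
        assert hu_consistency_per_plug(bins, stat)["acrylic"] \
            == pytest.approx(0.0)

    def test_consistency_plug_set_mismatch(self):
        with pytest.raises(ValueError):
            hu_consistency_per_plug({"a": [_pm("a", 0)]}, {"b": _pm("b", 0)})


def _pm(pid, mean):
    return PlugMeasurement(plug_id=pid, bin_label="x", centroid_mm=(0, 0, 0),
                           fwhm_mm=(1, 1, 1), mean_hu=mean, std_hu=1.0,
                           threshold_hu=0.0, voxel_count=10)


class TestCNR:
    def test_formula_on_noisy_render(self, small_geometry, small_sim):
        stationary, _, _ = small_sim
        pose = locate_phantom(stationary, small_geometry)
        cnr = cnr_low_contrast(stationary, pose, small_geometry)
        # polystyrene (-35) vs LDPE (-100) at 10 HU noise: 65 / sqrt(200)
        assert cnr == pytest.approx(65.0 / math.sqrt(200.0), rel=0.30)

    def test_noiseless_render_gives_infinite_sentinel(self, small_geometry):
        acq = AcquisitionSpec(grid_shape=(72, 72, 36), psf_sigma_mm=0.0,
                              noise_sigma_hu=0.0)
        vol = render_phantom(small_geometry, (0, 0, 0), acq)
        pose = locate_phantom(vol, small_geometry)
        assert cnr_low_contrast(vol, pose, small_geometry) == math.inf

    def test_sum_denominator_smaller_than_quadrature(self, small_geometry,
                                                     small_sim):
        stationary, _, _ = small_sim
        pose = locate_phantom(stationary, small_geometry)
        quad = cnr_low_contrast(stationary, pose, small_geometry)
        arith = cnr_low_contrast(stationary, pose, small_geometry,
                                 denominator="sum")
        assert abs(arith) < abs(quad)


class TestLowContrast:
    def test_noiseless_targets_all_detected(self, small_geometry, small_acq):
        vol = render_phantom(small_geometry, (0, 0, 0), small_acq)
        pose = locate_phantom(vol, small_geometry)
        res = low_contrast_detectability(vol, pose, small_geometry)
        assert res.smallest_detectable_mm == pytest.approx(3.0)

    def test_overwhelming_noise_detects_none(self, small_geometry, small_acq):
        vol = render_phantom(small_geometry, (0, 0, 0), small_acq)
        rng = np.random.default_rng(0)
        noisy = vol.with_voxels(
            vol.voxels + rng.normal(0, 200.0, vol.voxels.shape).astype(np.float32))
        pose = locate_phantom(noisy, small_geometry)
        res = low_contrast_detectability(noisy, pose, small_geometry)
        assert res.smallest_detectable_mm is None
        assert res.largest_tested_mm == pytest.approx(9.0)

    def test_decision_matches_brute_force_roi_statistics(self, small_geometry,
                                                         small_acq):
        # independent recomputation of one target's score from raw voxels
        vol = render_phantom(small_geometry, (0, 0, 0), small_acq)
        rng = np.random.default_rng(3)
        noisy = vol.with_voxels(
            vol.voxels + rng.normal(0, 6.0, vol.voxels.shape).astype(np.float32))
        pose = locate_phantom(noisy, small_geometry)
        res = low_contrast_detectability(noisy, pose, small_geometry)
        detected = {d for d, s in res.scores.items() if s >= 2.0}
        assert res.smallest_detectable_mm == (min(detected) if detected else None)

        mod = small_geometry.module("low_contrast")
        target = max(mod.low_contrast_targets, key=lambda t: t.diameter_mm)
        cx, cy = target.center_xy()
        center = np.array(pose.center_mm) + [cx, cy, mod.z_offset_mm]
        xs, ys, zs = (noisy.axis_coords(a) for a in range(3))
        rr = ((xs[:, None, None] - center[0]) ** 2
              + (ys[None, :, None] - center[1]) ** 2)
        inz = np.abs(zs[None, None, :] - center[2]) <= min(8.0, 0.3 * mod.thickness_mm)
        r = target.diameter_mm / 2.0
        disc = noisy.voxels[(rr <= max(0.7 * r, 0.6) ** 2) & inz]
        ring = noisy.voxels[(rr >= (r + 3.0) ** 2) & (rr <= (r + 8.0) ** 2) & inz]
        brute = abs(disc.mean() - ring.mean()) / ring.std(ddof=1)
        assert res.scores[target.diameter_mm] == pytest.approx(float(brute),
                                                               rel=1e-6)

    def test_module_absent(self, small_geometry, small_acq):
        geom_dict_modules = tuple(m for m in small_geometry.modules
                                  if m.name != "low_contrast")
        geom = dataclasses.replace(small_geometry, modules=geom_dict_modules)
        vol = render_phantom(small_geometry, (0, 0, 0), small_acq)
        with pytest.raises(ConfigurationError):
            low_contrast_detectability(vol, ORIGIN_POSE, geom)


class TestGeometricDistortion:
    def test_perfect_render_near_zero(self, small_geometry, small_acq):
        vol = render_phantom(small_geometry, (0, 0, 0), small_acq)
        pose = locate_phantom(vol, small_geometry)
        assert geometric_distortion(vol, pose, small_geometry) < 0.15

    def test_inplane_scaling_detected(self, small_geometry, small_acq):
        # a 1 % in-plane scale error reads as ~1 % of the nominal spacing
        vol = render_phantom(small_geometry, (0, 0, 0), small_acq)
        scaled = dataclasses.replace(
            vol, spacing_mm=(1.01, 1.01, vol.spacing_mm[2]),
            origin_mm=(vol.origin_mm[0] * 1.01, vol.origin_mm[1] * 1.01,
                       vol.origin_mm[2]))
        pose = locate_phantom(scaled, small_geometry)
        nominal = small_geometry.sensitometry.marker_nominal_spacing_mm
        got = geometric_distortion(scaled, pose, small_geometry)
        assert got == pytest.approx(0.01 * nominal, abs=0.05)


class TestSuite:
    def test_invariance_under_constant_shift(self, small_geometry, small_sim):
        stationary, _, _ = small_sim
        pose = locate_phantom(stationary, small_geometry)
        shift = 10.0
        shifted = stationary.with_voxels(stationary.voxels + shift)
        pose_s = pose  # same ROIs: the invariance is a property of the metrics
        assert noise(shifted, pose_s, small_geometry) \
            == pytest.approx(noise(stationary, pose, small_geometry), rel=1e-5)
        assert uniformity(shifted, pose_s, small_geometry) \
            == pytest.approx(uniformity(stationary, pose, small_geometry),
                             abs=0.15)
        # CNR is a difference over noise: invariant up to the segmentation
        # perturbation the offset causes on the low-contrast plug masks
        assert cnr_low_contrast(shifted, pose_s, small_geometry) \
            == pytest.approx(cnr_low_contrast(stationary, pose, small_geometry),
                             rel=0.10)
        # hu_constancy is the exception: it shifts with the offset
        before = hu_constancy(stationary, pose, small_geometry)
        after = hu_constancy(shifted, pose_s, small_geometry)
        assert after == pytest.approx(before + shift, abs=1.0)

    def test_translation_invariance_whole_voxels(self, small_geometry,
                                                 small_acq_noisy):
        from fourdqa.synth import simulate_4dct, BinningSpec, MotionTrace

        acq = small_acq_noisy
        st, _, _ = simulate_4dct(small_geometry,
                                 MotionTrace(peak_to_peak_mm=(0, 0, 0)),
                                 BinningSpec(n_bins=1), acq)
        rolled = st.with_voxels(np.roll(st.voxels, 2, axis=0))
        pose = locate_phantom(st, small_geometry)
        pose_r = locate_phantom(rolled, small_geometry)
        assert noise(rolled, pose_r, small_geometry) \
            == pytest.approx(noise(st, pose, small_geometry), rel=1e-4)
        assert cnr_low_contrast(rolled, pose_r, small_geometry) \
            == pytest.approx(cnr_low_contrast(st, pose, small_geometry),
                             rel=1e-3)

    def test_suite_reports_all_metrics_and_reproducibly(self, small_geometry,
                                                        small_sim):
        stationary, _, _ = small_sim
        pose = locate_phantom(stationary, small_geometry)
        a = iq_suite(stationary, pose, small_geometry)
        b = iq_suite(stationary, pose, small_geometry)
        assert a == b  # bit-reproducible
        assert a.noise_hu is not None
        assert a.uniformity_hu is not None
        assert a.cnr_low_contrast is not None
        assert set(a.plug_mean_hu) == {p.plug_id
                                       for p in small_geometry.sensitometry.plugs}

    def test_suite_degrades_per_metric(self, small_geometry, small_sim):
        stationary, _, _ = small_sim
        pose = locate_phantom(stationary, small_geometry)
        geom = dataclasses.replace(
            small_geometry,
            modules=tuple(dataclasses.replace(m, bead=None)
                          for m in small_geometry.modules))
        m = iq_suite(stationary, pose, geom)
        assert "mtf10" in m.errors
        assert m.noise_hu is not None  # rest of the suite still ran
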