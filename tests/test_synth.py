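"""Synthetic 4DCT generator: trace binning, rendering, simulation contracts."""

import numpy as np
import pytest

from fourdqa.dicomio import CTVolume
from fourdqa.synth import (
    AcquisitionSpec,
    BinningSpec,
    DegenerateTraceError,
    MotionTrace,
    RenderError,
    Renderer,
    patient_like_trace,
    render_phantom,
    sample_trace_bins,
    simulate_4dct,
)


class TestMotionTrace:
    def test_sinusoid_extremes(self):
        trace = MotionTrace(peak_to_peak_mm=(0, 0, 15), period_s=6.0)
        assert trace.displacement_at_fraction(0.0)[0, 2] == pytest.approx(7.5)
        assert trace.displacement_at_fraction(0.5)[0, 2] == pytest.approx(-7.5)
        assert trace.peak_to_peak()[2] == pytest.approx(15.0)

    def test_invalid_traces_rejected(self):
        with pytest.raises(ValueError):
            MotionTrace(peak_to_peak_mm=(0, 0, -1))
        with pytest.raises(ValueError):
            MotionTrace(period_s=0.0)
        with pytest.raises(ValueError):
            MotionTrace(kind="sampled",
                        samples=np.array([[0.0, 0, 0, 0], [0.0, 0, 0, 1]]))

    def test_patient_like_trace_is_3d_and_periodic_metadata(self):
        trace = patient_like_trace()
        pp = trace.peak_to_peak()
        assert np.all(pp > 0)
        assert int(np.argmax(pp)) == 2
        assert trace.period_s > 0


class TestSampleTraceBins:
    def test_phase_bins_hit_cosine_extremes(self):
        trace = MotionTrace(peak_to_peak_mm=(0, 0, 15), period_s=6.0)
        bins = sample_trace_bins(trace, BinningSpec(n_bins=10, intra_bin_samples=1))
        assert bins[0][0][2] == pytest.approx(7.5)
        assert bins[5][0][2] == pytest.approx(-7.5)

    def test_amplitude_bin_width(self):
        trace = MotionTrace(peak_to_peak_mm=(0, 0, 15), period_s=6.0)
        bins = sample_trace_bins(trace, BinningSpec(mode="amplitude", n_bins=10,
                                                    intra_bin_samples=50))
        spans = [max(s[2] for s in b) - min(s[2] for s in b) for b in bins]
        # each amplitude interval is 15/10 = 1.5 mm wide
        assert max(spans) <= 1.5 + 1e-6
        # extremes are retained in the outer bins
        allz = [s[2] for b in bins for s in b]
        assert max(allz) == pytest.approx(7.5)
        assert min(allz) == pytest.approx(-7.5)

    def test_constant_trace_phase_bins_identical(self):
        trace = MotionTrace(peak_to_peak_mm=(0, 0, 0), period_s=6.0)
        bins = sample_trace_bins(trace, BinningSpec(n_bins=5, intra_bin_samples=2))
        for b in bins:
            for s in b:
                assert np.allclose(s, 0.0)

    def test_amplitude_mode_rejects_degenerate_trace(self):
        trace = MotionTrace(peak_to_peak_mm=(0, 0, 0), period_s=6.0)
        with pytest.raises(DegenerateTraceError):
            sample_trace_bins(trace, BinningSpec(mode="amplitude"))

    def test_sampled_trace_phase_binning_by_cycle(self):
        trace = patient_like_trace()
        bins = sample_trace_bins(trace, BinningSpec(n_bins=10, intra_bin_samples=3))
        assert len(bins) == 10
        assert all(1 <= len(b) <= 3 for b in bins)


class TestRenderPhantom:
    def test_interior_voxel_hits_nominal_hu(self, small_geometry):
        acq = AcquisitionSpec(grid_shape=(72, 72, 36), psf_sigma_mm=0.0,
                              noise_sigma_hu=0.0, supersampling=4)
        vol = render_phantom(small_geometry, (0, 0, 0), acq)
        idx = vol.index_of(small_geometry.plug_center("teflon"))
        assert vol.voxels[idx] == pytest.approx(990.0)
        idx = vol.index_of(small_geometry.plug_center("air"))
        assert vol.voxels[idx] == pytest.approx(-1000.0)

    def test_displacement_shifts_thresholded_centroid(self, small_geometry):
        acq = AcquisitionSpec(grid_shape=(72, 72, 36), psf_sigma_mm=0.0,
                              noise_sigma_hu=0.0)
        r = Renderer(small_geometry, acq)
        v0, v5 = r.render((0, 0, 0)), r.render((0, 0, 5.0))

        def centroid_z(vol):
            mask = vol.voxels >= 495.0
            zs = vol.axis_coords(2)
            w = mask.sum(axis=(0, 1)).astype(float)
            return float((w * zs).sum() / w.sum())

        assert centroid_z(v5) - centroid_z(v0) == pytest.approx(5.0, abs=1.0)

    def test_supersampling_only_affects_edges(self, small_geometry):
        kw = dict(grid_shape=(72, 72, 36), psf_sigma_mm=0.0, noise_sigma_hu=0.0)
        v1 = render_phantom(small_geometry, (0, 0, 0),
                            AcquisitionSpec(supersampling=1, **kw))
        v8 = render_phantom(small_geometry, (0, 0, 0),
                            AcquisitionSpec(supersampling=8, **kw))
        diff = np.abs(v1.voxels - v8.voxels)
        assert diff.max() > 0  # edge voxels differ
        idx = v1.index_of(small_geometry.plug_center("teflon"))
        assert diff[idx] == 0.0  # interior voxels equal

    def test_phantom_exceeding_grid_rejected(self, small_geometry):
        acq = AcquisitionSpec(grid_shape=(40, 40, 36))
        with pytest.raises(RenderError):
            render_phantom(small_geometry, (0, 0, 0), acq)

    def test_render_is_deterministic(self, small_geometry, small_acq):
        a = render_phantom(small_geometry, (0, 0, 3.0), small_acq)
        b = render_phantom(small_geometry, (0, 0, 3.0), small_acq)
        assert np.array_equal(a.voxels, b.voxels)


class TestSimulate4DCT:
    def test_same_seed_bit_identical(self, small_geometry, small_trace):
        acq = AcquisitionSpec(grid_shape=(72, 72, 36), noise_sigma_hu=10.0, seed=3)
        st1, s1, _ = simulate_4dct(small_geometry, small_trace, BinningSpec(), acq)
        st2, s2, _ = simulate_4dct(small_geometry, small_trace, BinningSpec(), acq)
        assert np.array_equal(st1.voxels, st2.voxels)
        for a, b in zip(s1, s2):
            assert a.bin_label == b.bin_label
            assert np.array_equal(a.voxels, b.voxels)

    def test_different_seed_differs(self, small_geometry, small_trace):
        kw = dict(grid_shape=(72, 72, 36), noise_sigma_hu=10.0)
        st1, _, _ = simulate_4dct(small_geometry, small_trace, BinningSpec(),
                                  AcquisitionSpec(seed=1, **kw))
        st2, _, _ = simulate_4dct(small_geometry, small_trace, BinningSpec(),
                                  AcquisitionSpec(seed=2, **kw))
        assert not np.array_equal(st1.voxels, st2.voxels)

    def test_noise_level_in_uniform_region(self, small_geometry, small_trace):
        acq = AcquisitionSpec(grid_shape=(72, 72, 36), noise_sigma_hu=10.0,
                              seed=11)
        st, _, _ = simulate_4dct(small_geometry, small_trace, BinningSpec(), acq)
        # central uniformity-module region: pure background + noise
        mod = small_geometry.uniformity_module
        idx = st.index_of((0.0, 0.0, mod.z_offset_mm))
        sub = st.voxels[idx[0] - 10:idx[0] + 10, idx[1] - 10:idx[1] + 10,
                        idx[2] - 2:idx[2] + 3]
        assert sub.size >= 1500
        assert sub.std(ddof=1) == pytest.approx(10.0, rel=0.10)

    def test_ground_truth_amplitude_and_labels(self, small_sim_noiseless):
        _, series, truth = small_sim_noiseless
        assert truth.peak_to_peak_mm[2] == pytest.approx(6.0)
        assert truth.bin_labels == [v.bin_label for v in series]
        assert len(truth.bin_mean_displacement_mm) == 10
        # bins anchored at the peak include both extremes
        zs = [d[2] for d in truth.bin_mean_displacement_mm]
        assert max(zs) == pytest.approx(3.0)
        assert min(zs) == pytest.approx(-3.0)
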