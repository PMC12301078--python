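"""Canned desk-scale QA studies on the bundled simulator.

These drive the full pipeline end to end — simulate, localise, measure —
and return compact measurement records.  They are the backbone of the
commissioning checks (`scripts/acceptance.py`) and of the example scripts;
each function is an ordinary library entry point and contains no expected
values of its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contour_oracle import contour_plug_measurement
from .dicomio import CTVolume, Phase4DSeries
from .geometry import PhantomGeometry, builtin_geometry
from .localize import locate_phantom, detect_plug, measure_plug_dimensions
from .quality import mtf_from_bead, noise as noise_metric
from .spatial import (
    PROJECTION_PAIRS,
    average_ct,
    intensity_projection,
    projection_dimension_check,
)
from .synth import (
    AcquisitionSpec,
    BinningSpec,
    MotionTrace,
    patient_like_trace,
    simulate_4dct,
)


@dataclass
class SurrogateStudy:
    """Measurements of one simulated 4DCT against its stationary baseline."""

    trace_peak_to_peak_mm: tuple[float, float, float]
    stationary_fwhm_mm: dict[str, tuple[float, float, float]]
    bin_fwhm_mm: dict[str, list[tuple[float, float, float]]]
    bin_centroids_mm: dict[str, list[tuple[float, float, float]]]
    stationary_hu: dict[str, float] = field(default_factory=dict)
    bin_hu: dict[str, list[float]] = field(default_factory=dict)
    projections: dict[str, tuple[float, float]] = field(default_factory=dict)
    # plug -> (measured z-FWHM in projection, expected = stationary z + amp)

    def dimension_deltas(self) -> dict[str, tuple[float, float, float]]:
        """Per plug: mean-over-bins FWHM minus stationary FWHM, per axis."""
        out = {}
        for pid, stat in self.stationary_fwhm_mm.items():
            mean = np.mean(np.asarray(self.bin_fwhm_mm[pid]), axis=0)
            out[pid] = tuple(float(m - s) for m, s in zip(mean, stat))
        return out

    def max_dimension_delta(self) -> float:
        return max(abs(d) for v in self.dimension_deltas().values() for d in v)

    def amplitude_extents(self) -> dict[str, float]:
        """Per plug: centroid extent along the principal motion axis."""
        axis = int(np.argmax(self.trace_peak_to_peak_mm))
        return {
            pid: float(np.ptp(np.asarray(c)[:, axis]))
            for pid, c in self.bin_centroids_mm.items()
        }

    def max_amplitude_delta(self) -> float:
        axis = int(np.argmax(self.trace_peak_to_peak_mm))
        expected = self.trace_peak_to_peak_mm[axis]
        return max(abs(e - expected) for e in self.amplitude_extents().values())

    def hu_deltas(self) -> dict[str, float]:
        return {
            pid: float(np.mean(self.bin_hu[pid]) - self.stationary_hu[pid])
            for pid in self.stationary_hu
        }

    def max_projection_delta(self) -> float:
        return max(abs(m - e) for m, e in self.projections.values())


def measure_surrogates(
    stationary: CTVolume,
    series: Phase4DSeries,
    geometry: PhantomGeometry,
    trace: MotionTrace,
    include_hu: bool = True,
    include_projections: bool = True,
) -> SurrogateStudy:
    """Measure both motion surrogates (and optionally all sensitometry plug
    HUs and the MIP/MinIP pairs) on a stationary + 4D dataset."""
    surrogates = geometry.surrogate_plugs()
    pose_st = locate_phantom(stationary, geometry)
    stat_meas = {
        p.plug_id: measure_plug_dimensions(stationary, pose_st, p, geometry)
        for p in surrogates
    }
    study = SurrogateStudy(
        trace_peak_to_peak_mm=tuple(trace.peak_to_peak()),
        stationary_fwhm_mm={pid: m.fwhm_mm for pid, m in stat_meas.items()},
        bin_fwhm_mm={p.plug_id: [] for p in surrogates},
        bin_centroids_mm={p.plug_id: [] for p in surrogates},
    )
    if include_hu:
        for plug in geometry.sensitometry.plugs:
            m = detect_plug(stationary, pose_st, plug, geometry)
            study.stationary_hu[plug.plug_id] = m.mean_hu
            study.bin_hu[plug.plug_id] = []
    for vol in series:
        pose = locate_phantom(vol, geometry)
        for plug in surrogates:
            m = measure_plug_dimensions(vol, pose, plug, geometry)
            study.bin_fwhm_mm[plug.plug_id].append(m.fwhm_mm)
            study.bin_centroids_mm[plug.plug_id].append(m.centroid_mm)
        if include_hu:
            for plug in geometry.sensitometry.plugs:
                m = detect_plug(vol, pose, plug, geometry)
                study.bin_hu[plug.plug_id].append(m.mean_hu)
    if include_projections:
        mip = intensity_projection(series, "MIP")
        minip = intensity_projection(series, "MinIP")
        for pid, kind in PROJECTION_PAIRS.items():
            if pid not in stat_meas:
                continue
            res = projection_dimension_check(
                mip if kind == "MIP" else minip,
                stat_meas[pid], trace, geometry.plug(pid), geometry)
            study.projections[pid] = (res.measured_z_fwhm_mm, res.expected_mm)
    return study


def sinusoid_study(
    model: int = 504,
    peak_to_peak_mm: float = 15.0,
    period_s: float = 6.0,
    seed: int = 1,
    noiseless: bool = False,
    binning: BinningSpec | None = None,
    include_hu: bool = True,
    include_projections: bool = True,
) -> SurrogateStudy:
    """Simulate one sinusoidal 4DCT and measure it end to end."""
    geometry = builtin_geometry(model)
    trace = MotionTrace(peak_to_peak_mm=(0.0, 0.0, peak_to_peak_mm),
                        period_s=period_s)
    binning = binning or BinningSpec()
    acq = AcquisitionSpec(seed=seed, noise_sigma_hu=0.0) if noiseless \
        else AcquisitionSpec(seed=seed)
    stationary, series, _ = simulate_4dct(geometry, trace, binning, acq)
    return measure_surrogates(stationary, series, geometry, trace,
                              include_hu=include_hu,
                              include_projections=include_projections)


def spatial_integrity_bundle(
    model: int = 504,
    periods_s: tuple[float, ...] = (3.0, 6.0, 10.0),
    seeds: tuple[int, ...] = (1, 2, 3),
) -> dict[tuple[float, int], SurrogateStudy]:
    """The three-trace, three-seed study: 15 mm p-p sinusoids at periods
    3/6/10 s, 10 phase bins, default blur and noise."""
    out = {}
    for period in periods_s:
        for seed in seeds:
            out[(period, seed)] = sinusoid_study(
                model=model, period_s=period, seed=seed)
    return out


# ---------------------------------------------------------------------------
# oracle agreement


def oracle_agreement(
    models: tuple[int, ...] = (504, 604),
    peak_to_peak_mm: float = 15.0,
    period_s: float = 6.0,
    seed: int = 1,
) -> dict:
    """Pipeline vs independent iso-contour oracle on simulated 4DCTs.

    Returns the per-quantity disagreements (plug dimensions on every bin
    and the stationary scan, and the centroid-extent amplitude) between the
    threshold/FWHM pipeline and the contour-based measurement.
    """
    dim_disagreements: list[float] = []
    amp_disagreements: list[float] = []
    for model in models:
        geometry = builtin_geometry(model)
        trace = MotionTrace(peak_to_peak_mm=(0.0, 0.0, peak_to_peak_mm),
                            period_s=period_s)
        stationary, series, _ = simulate_4dct(
            geometry, trace, BinningSpec(), AcquisitionSpec(seed=seed))
        for plug in geometry.surrogate_plugs():
            pipeline_z: list[float] = []
            oracle_z: list[float] = []
            for vol in [stationary, *series]:
                pose = locate_phantom(vol, geometry)
                m = measure_plug_dimensions(vol, pose, plug, geometry)
                c, fw = contour_plug_measurement(vol, pose, plug, geometry)
                dim_disagreements.extend(
                    abs(a - b) for a, b in zip(m.fwhm_mm, fw))
                if vol is not stationary:
                    pipeline_z.append(m.centroid_mm[2])
                    oracle_z.append(c[2])
            amp_disagreements.append(
                abs(float(np.ptp(pipeline_z)) - float(np.ptp(oracle_z))))
    return {
        "max_dimension_disagreement_mm": max(dim_disagreements),
        "max_amplitude_disagreement_mm": max(amp_disagreements),
        "n_comparisons": len(dim_disagreements) + len(amp_disagreements),
    }


# ---------------------------------------------------------------------------
# nominal dimensions


def nominal_dimension_study(model: int,
                            supersampling: int = 4) -> dict[str, tuple]:
    """Noiseless stationary render -> measured FWHM per surrogate plug."""
    geometry = builtin_geometry(model)
    acq = AcquisitionSpec(noise_sigma_hu=0.0, supersampling=supersampling)
    from .synth import Renderer

    vol = Renderer(geometry, acq).render((0.0, 0.0, 0.0))
    pose = locate_phantom(vol, geometry)
    out = {}
    for plug in geometry.surrogate_plugs():
        m = measure_plug_dimensions(vol, pose, plug, geometry)
        out[plug.plug_id] = (
            m.fwhm_mm,
            (plug.diameter_mm, plug.diameter_mm, plug.length_mm),
        )
    return out


# ---------------------------------------------------------------------------
# binning-mode equivalence


def binning_equivalence(
    model: int = 504,
    seed: int = 1,
    sinusoid_peak_to_peak_mm: float = 15.0,
) -> dict[str, dict[str, float]]:
    """Phase vs amplitude binning on a sinusoid and on the synthetic
    3D patient-like trace: max plug-dimension delta per (trace, mode)."""
    geometry = builtin_geometry(model)
    traces = {
        "sinusoid": MotionTrace(
            peak_to_peak_mm=(0.0, 0.0, sinusoid_peak_to_peak_mm), period_s=6.0),
        "patient_like_3d": patient_like_trace(),
    }
    out: dict[str, dict[str, float]] = {}
    for tname, trace in traces.items():
        out[tname] = {}
        for mode in ("phase", "amplitude"):
            stationary, series, _ = simulate_4dct(
                geometry, trace, BinningSpec(mode=mode),
                AcquisitionSpec(seed=seed))
            study = measure_surrogates(stationary, series, geometry, trace,
                                       include_hu=False,
                                       include_projections=False)
            out[tname][mode] = study.max_dimension_delta()
    return out


# ---------------------------------------------------------------------------
# averaging / noise structure


def average_ct_noise_study(stationary: CTVolume, series: Phase4DSeries,
                           geometry: PhantomGeometry) -> dict[str, float]:
    """Noise metric per bin and on the average CT (1/sqrt(N) check)."""
    per_bin = []
    for vol in series:
        pose = locate_phantom(vol, geometry)
        per_bin.append(noise_metric(vol, pose, geometry))
    avg = average_ct(series)
    pose = locate_phantom(avg, geometry)
    return {
        "mean_bin_noise_hu": float(np.mean(per_bin)),
        "average_ct_noise_hu": float(noise_metric(avg, pose, geometry)),
        "n_bins": len(per_bin),
    }


# ---------------------------------------------------------------------------
# MTF oracle


def analytic_gaussian_mtf10(sigma_mm: float) -> float:
    """Frequency (cycles/mm) where a Gaussian-PSF MTF falls to 10 %."""
    return math.sqrt(math.log(10.0) / (2.0 * math.pi ** 2 * sigma_mm ** 2))


def gaussian_mtf_study(sigmas_mm=(0.3, 0.5, 0.9, 1.5),
                       pixel_mm: float = 0.25) -> dict[float, dict[str, float]]:
    """Measured vs closed-form MTF-10 % for synthetic Gaussian PSFs.

    The pixel pitch must resolve the 10 % crossing (f10 below ~80 % of the
    Nyquist frequency); 0.25 mm covers the whole sigma range.
    """
    from .geometry import BeadSpec, MaterialSpec, ModuleSpec
    from .localize import PhantomPose

    geom = PhantomGeometry(
        model=504, outer_diameter_mm=200.0,
        background=MaterialSpec("water", 0), air=MaterialSpec("air", -1000),
        modules=(
            ModuleSpec("sensitometry", -60.0, 40.0),
            ModuleSpec("spatial_resolution", 0.0, 30.0,
                       bead=BeadSpec(0.0, 0.0, 0.0, 1e-3,
                                     MaterialSpec("bead", 3000))),
            ModuleSpec("uniformity", 65.0, 50.0),
        ))
    pose = PhantomPose((0.0, 0.0, 0.0))
    out = {}
    for sigma in sigmas_mm:
        n = int(2 * round(20.0 * max(sigma, 0.5) / pixel_mm) + 1)
        xs = (np.arange(n) - n // 2) * pixel_mm
        blob = np.exp(-(xs[:, None] ** 2 + xs[None, :] ** 2)
                      / (2.0 * sigma ** 2))
        vox = np.zeros((n, n, 5), dtype=np.float32)
        vox[:, :, 2] = 1000.0 * blob
        vol = CTVolume(voxels=vox, spacing_mm=(pixel_mm, pixel_mm, 1.0),
                       origin_mm=(-(n // 2) * pixel_mm, -(n // 2) * pixel_mm,
                                  -2.0))
        curve, f10 = mtf_from_bead(vol, pose, geom,
                                   roi_half_mm=min(8 * sigma + 2, 12.0),
                                   roi_z_half_mm=2.0)
        out[sigma] = {
            "measured_lp_per_cm": f10,
            "analytic_lp_per_cm": 10.0 * analytic_gaussian_mtf10(sigma),
            "saturated": curve.saturated,
        }
    return out
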