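"""Phase-resolved spatial-integrity tests of a binned 4DCT.

Three checks against the stationary baseline: (1) plug-dimension
consistency — the mean-over-bins FWHM dimension of each surrogate plug
minus its stationary value; (2) motion-amplitude recovery — the extent
(max - min) of per-bin plug centroids per axis versus the known platform
input amplitude; (3) the intensity-projection dimension check — the
surrogate z-dimension in MIP/MinIP images versus stationary z-dimension
plus input amplitude (Teflon pairs with MIP, Air with MinIP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dicomio import CTVolume, Phase4DSeries
from .geometry import PhantomGeometry, PlugSpec
from .localize import PhantomPose, PlugMeasurement, locate_phantom, measure_plug_dimensions
from .synth import MotionTrace


@dataclass
class DimensionDelta:
    plug_id: str
    axis: str  # 'x' | 'y' | 'z'
    per_bin_fwhm_mm: list[float]
    mean_fwhm_mm: float
    stationary_fwhm_mm: float
    delta_mm: float


@dataclass
class AmplitudeResult:
    plug_id: str
    per_bin_centroid_mm: list[tuple[float, float, float]]
    extent_mm: tuple[float, float, float]
    expected_mm: tuple[float, float, float]
    delta_mm: tuple[float, float, float]


@dataclass
class ProjectionResult:
    plug_id: str
    kind: str  # 'MIP' | 'MinIP'
    measured_z_fwhm_mm: float
    expected_mm: float
    delta_mm: float


def dimension_consistency(
    bin_measurements: list[PlugMeasurement],
    stationary_measurement: PlugMeasurement,
) -> list[DimensionDelta]:
    """Per-axis mean-over-bins FWHM minus the stationary FWHM for one plug."""
    if not bin_measurements:
        raise ValueError("at least one bin measurement required")
    pid = stationary_measurement.plug_id
    if any(m.plug_id != pid for m in bin_measurements):
        raise ValueError("bin and stationary measurements refer to different plugs")
    out = []
    for ax, name in enumerate("xyz"):
        per_bin = [float(m.fwhm_mm[ax]) for m in bin_measurements]
        mean = float(np.mean(per_bin))
        stat = float(stationary_measurement.fwhm_mm[ax])
        out.append(DimensionDelta(
            plug_id=pid, axis=name, per_bin_fwhm_mm=per_bin,
            mean_fwhm_mm=mean, stationary_fwhm_mm=stat, delta_mm=mean - stat,
        ))
    return out


def motion_amplitude(
    bin_measurements: list[PlugMeasurement],
    trace: MotionTrace,
) -> AmplitudeResult:
    """Centroid-extent motion amplitude per axis versus the input amplitude."""
    if len(bin_measurements) < 2:
        raise ValueError("motion amplitude requires at least two bins")
    pid = bin_measurements[0].plug_id
    if any(m.plug_id != pid for m in bin_measurements):
        raise ValueError("measurements refer to different plugs")
    cent = np.array([m.centroid_mm for m in bin_measurements])
    extent = cent.max(axis=0) - cent.min(axis=0)
    expected = trace.peak_to_peak()
    return AmplitudeResult(
        plug_id=pid,
        per_bin_centroid_mm=[tuple(c) for c in cent],
        extent_mm=tuple(float(e) for e in extent),
        expected_mm=tuple(float(e) for e in expected),
        delta_mm=tuple(float(e - x) for e, x in zip(extent, expected)),
    )


def _aligned_stack(series: Phase4DSeries) -> np.ndarray:
    ref = series.volumes[0]
    for v in series.volumes[1:]:
        if not v.same_grid(ref):
            raise ValueError("series volumes are not on a common grid")
    return np.stack([v.voxels for v in series.volumes], axis=0)


def average_ct(series: Phase4DSeries) -> CTVolume:
    """Voxelwise arithmetic mean of all bins (clinical 'average CT')."""
    stack = _aligned_stack(series)
    return series.volumes[0].with_voxels(
        stack.mean(axis=0).astype(np.float32), bin_label="average"
    )


def intensity_projection(series: Phase4DSeries, kind: str) -> CTVolume:
    """Voxelwise maximum (MIP) or minimum (MinIP) across bins."""
    if kind not in ("MIP", "MinIP"):
        raise ValueError(f"projection kind must be 'MIP' or 'MinIP', got {kind!r}")
    stack = _aligned_stack(series)
    vox = stack.max(axis=0) if kind == "MIP" else stack.min(axis=0)
    return series.volumes[0].with_voxels(vox.astype(np.float32), bin_label=kind)


#: default surrogate/projection pairing: the dense plug keeps its footprint
#: in the maximum projection, the air plug in the minimum projection
PROJECTION_PAIRS = {"teflon": "MIP", "air": "MinIP"}


def projection_dimension_check(
    projection: CTVolume,
    stationary_measurement: PlugMeasurement,
    trace: MotionTrace,
    plug: PlugSpec,
    geometry: PhantomGeometry,
    pose: PhantomPose | None = None,
) -> ProjectionResult:
    """Surrogate z-dimension in a MIP/MinIP versus stationary-z + amplitude."""
    kind = projection.bin_label if projection.bin_label in ("MIP", "MinIP") else \
        PROJECTION_PAIRS.get(plug.plug_id, "MIP")
    if pose is None:
        pose = locate_phantom(projection, geometry)
    amplitude_z = float(trace.peak_to_peak()[2])
    meas = measure_plug_dimensions(
        projection, pose, plug, geometry, z_margin_mm=amplitude_z / 2.0 + 4.0
    )
    expected = float(stationary_measurement.fwhm_mm[2]) + amplitude_z
    measured = float(meas.fwhm_mm[2])
    return ProjectionResult(
        plug_id=plug.plug_id, kind=kind,
        measured_z_fwhm_mm=measured, expected_mm=expected,
        delta_mm=measured - expected,
    )
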