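"""Phantom localisation and plug measurement.

The analysis chain per volume: find the phantom pose (body-mask centroid +
marker-constellation rotation), then for each target plug segment it by HU
thresholding in a search box around its expected position, take the
centroid of the thresholded region, and measure the full width at half
maximum (FWHM) of the HU profile through the centroid along each axis.

The half level is the midpoint of the plug's nominal HU and the background
nominal HU, so the segmentation threshold and the FWHM level coincide and
are visible in the geometry config.  Profile crossings are located by
linear interpolation between samples, scanning outward from the profile
extremum; samples exactly at the half level count as inside (ties break
toward the wider width).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dicomio import CTVolume
from .geometry import PhantomGeometry, PlugSpec


class DetectionError(RuntimeError):
    """No phantom-like object / plug region found where expected."""


class ProfileTruncationError(RuntimeError):
    """An HU profile never crosses the half level on one side."""


@dataclass(frozen=True)
class PhantomPose:
    """Rigid pose of the phantom in a volume: geometry origin + in-plane rotation."""

    center_mm: tuple[float, float, float]
    rotation_deg: float = 0.0

    def to_world(self, point_mm) -> np.ndarray:
        """Map a phantom-coordinate point into volume world coordinates."""
        th = math.radians(self.rotation_deg)
        c, s = math.cos(th), math.sin(th)
        x, y, z = point_mm
        return np.array(self.center_mm) + np.array(
            [c * x - s * y, s * x + c * y, z]
        )


@dataclass
class PlugMeasurement:
    plug_id: str
    bin_label: str
    centroid_mm: tuple[float, float, float]
    fwhm_mm: tuple[float, float, float] | None
    mean_hu: float
    std_hu: float
    threshold_hu: float
    voxel_count: int
    touches_boundary: bool = False


# ---------------------------------------------------------------------------
# pose


def _body_mask(volume: CTVolume, geometry: PhantomGeometry) -> np.ndarray:
    threshold = 0.5 * (geometry.air.nominal_hu + geometry.background.nominal_hu)
    mask = volume.voxels > threshold
    if not mask.any():
        raise DetectionError("no phantom-like object found (body threshold empty)")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def _weighted_centroid(volume: CTVolume, center_mm, half_mm: float,
                       baseline_hu: float,
                       floor_frac: float = 0.25) -> np.ndarray | None:
    """Intensity-weighted centroid of above-floor signal in a box (sub-voxel).

    The floor adapts to the box: baseline + ``floor_frac`` of the peak
    excursion above baseline, so point-like objects attenuated by the PSF
    and slice partial volume are still caught.
    """
    lo, hi = [], []
    for ax in range(3):
        i0 = int(math.floor((center_mm[ax] - half_mm - volume.origin_mm[ax])
                            / volume.spacing_mm[ax]))
        i1 = int(math.ceil((center_mm[ax] + half_mm - volume.origin_mm[ax])
                           / volume.spacing_mm[ax]))
        lo.append(max(i0, 0))
        hi.append(min(i1, volume.shape[ax] - 1))
    if any(h < l for l, h in zip(lo, hi)):
        return None
    sub = volume.voxels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    peak = float(sub.max())
    if peak <= baseline_hu + 100.0:  # high-contrast objects only, not noise
        return None
    floor_hu = baseline_hu + floor_frac * (peak - baseline_hu)
    w = np.clip(sub - floor_hu, 0.0, None)
    total = w.sum()
    if total <= 0:
        return None
    grids = np.meshgrid(*[
        volume.origin_mm[a] + volume.spacing_mm[a] * np.arange(lo[a], hi[a] + 1)
        for a in range(3)
    ], indexing="ij")
    return np.array([float((w * gaxis).sum() / total) for gaxis in grids])


def locate_phantom(volume: CTVolume, geometry: PhantomGeometry) -> PhantomPose:
    """Estimate phantom pose: body-mask centroid, marker-based rotation.

    Rotation defaults to 0 deg when the marker constellation cannot be
    resolved.  Contract on simulator output: centre within 2 mm, rotation
    within 2 deg.
    """
    mask = _body_mask(volume, geometry)
    com = ndimage.center_of_mass(mask)
    center = np.array([
        volume.origin_mm[a] + volume.spacing_mm[a] * com[a] for a in range(3)
    ])
    # geometry origin = body centre, which the builtin geometries place at
    # the phantom coordinate origin; account for an asymmetric body anyway
    body_mid_z = 0.5 * sum(geometry.body_z_range_mm)
    center[2] -= body_mid_z

    rotation = 0.0
    sens = geometry.sensitometry
    markers = sens.markers
    if len(markers) >= 2:
        expected, measured = [], []
        bg = geometry.background.nominal_hu
        for mk in markers:
            exp = np.array([mk.x_mm, mk.y_mm, sens.z_offset_mm + mk.z_mm]) + center
            got = _weighted_centroid(volume, exp, mk.diameter_mm / 2.0 + 4.0, bg)
            if got is not None:
                expected.append([mk.x_mm, mk.y_mm])
                measured.append([got[0] - center[0], got[1] - center[1]])
        if len(expected) == len(markers):
            e = np.asarray(expected)
            m = np.asarray(measured)
            num = float(np.sum(e[:, 0] * m[:, 1] - e[:, 1] * m[:, 0]))
            den = float(np.sum(e[:, 0] * m[:, 0] + e[:, 1] * m[:, 1]))
            if den != 0.0 or num != 0.0:
                rotation = math.degrees(math.atan2(num, den))
    return PhantomPose(center_mm=tuple(center), rotation_deg=rotation)


# ---------------------------------------------------------------------------
# plug detection


def plug_threshold(geometry: PhantomGeometry, plug: PlugSpec) -> float:
    """Segmentation threshold = FWHM half level: midpoint of plug and background HU."""
    return 0.5 * (plug.material.nominal_hu + geometry.background.nominal_hu)


def _body_bounds(pose: PhantomPose, geometry: PhantomGeometry, at_mm):
    """Per-axis world intervals 1 mm inside the phantom body at a point.

    In-plane bounds use the body-cylinder chord through the point, so a
    search region near the rim cannot leak into outside air.
    """
    r = geometry.outer_diameter_mm / 2.0
    z0, z1 = geometry.body_z_range_mm
    cx, cy, cz = pose.center_mm
    chord_x = math.sqrt(max(r * r - (at_mm[1] - cy) ** 2, 1.0))
    chord_y = math.sqrt(max(r * r - (at_mm[0] - cx) ** 2, 1.0))
    return (
        (cx - chord_x + 1.0, cx + chord_x - 1.0),
        (cy - chord_y + 1.0, cy + chord_y - 1.0),
        (cz + z0 + 1.0, cz + z1 - 1.0),
    )


def _search_box(volume: CTVolume, center_mm, half_mm,
                bounds_mm=None) -> tuple[slice, ...]:
    slices = []
    for ax in range(3):
        lo = center_mm[ax] - half_mm[ax]
        hi = center_mm[ax] + half_mm[ax]
        if bounds_mm is not None:
            lo = max(lo, bounds_mm[ax][0])
            hi = min(hi, bounds_mm[ax][1])
        i0 = int(math.floor((lo - volume.origin_mm[ax]) / volume.spacing_mm[ax]))
        i1 = int(math.ceil((hi - volume.origin_mm[ax]) / volume.spacing_mm[ax]))
        slices.append(slice(max(i0, 0), min(i1, volume.shape[ax] - 1) + 1))
    return tuple(slices)


def detect_plug(
    volume: CTVolume,
    pose: PhantomPose,
    plug: PlugSpec,
    geometry: PhantomGeometry,
    z_margin_mm: float = 0.0,
) -> PlugMeasurement:
    """Segment one plug by HU thresholding and measure centroid + ROI HU stats.

    Voxels beyond the half-level threshold (above for plugs denser than
    background, below for Air-like plugs) inside a search box around the
    expected position form the region; the largest connected component is
    kept and its unweighted centroid reported.  HU statistics are taken
    over a fixed coaxial interior ROI (70 % diameter, 60 % length, centred
    on the measured centroid) so they sample the flat plug core and stay
    decoupled from partial-volume and motion-blur rims.
    """
    geom_center = geometry.plug_center(plug)
    expected = pose.to_world(geom_center)
    pad_xy, pad_z = 4.0, 6.0
    half = (plug.diameter_mm / 2.0 + pad_xy,
            plug.diameter_mm / 2.0 + pad_xy,
            plug.length_mm / 2.0 + pad_z + z_margin_mm)
    bounds = _body_bounds(pose, geometry, expected)
    box = _search_box(volume, expected, half, bounds)
    sub = volume.voxels[box]
    if sub.size == 0:
        raise DetectionError(f"plug {plug.plug_id!r}: search box outside volume")
    threshold = plug_threshold(geometry, plug)
    polarity = 1.0 if plug.material.nominal_hu >= geometry.background.nominal_hu else -1.0
    mask = (sub >= threshold) if polarity > 0 else (sub <= threshold)
    if not mask.any():
        raise DetectionError(
            f"plug {plug.plug_id!r}: no voxels beyond threshold {threshold:.1f} HU"
        )
    labels, n = ndimage.label(mask)
    if n > 1:
        # keep the component at the expected plug position; outside-phantom
        # air can form a larger below-threshold component than an Air plug
        # when the search box crosses the phantom end (MinIP images)
        exp_idx = tuple(
            int(np.clip(round((expected[a] - volume.origin_mm[a])
                              / volume.spacing_mm[a]) - box[a].start,
                        0, sub.shape[a] - 1))
            for a in range(3)
        )
        lab = labels[exp_idx]
        if lab == 0:
            centroids = ndimage.center_of_mass(mask, labels, np.arange(1, n + 1))
            d = [np.linalg.norm(np.asarray(c) - np.asarray(exp_idx))
                 for c in centroids]
            lab = 1 + int(np.argmin(d))
        mask = labels == lab
    touches = bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    com = ndimage.center_of_mass(mask)
    centroid = np.array([
        volume.origin_mm[a] + volume.spacing_mm[a] * (box[a].start + com[a])
        for a in range(3)
    ])
    # sub-voxel refinement: per axis, move the centroid coordinate to the
    # midpoint of the two crossings of the segmentation threshold level,
    # scanning outward from the mask centroid (robustly inside the plug);
    # this removes the half-voxel quantisation of the discrete mask centroid
    half_lens = (plug.diameter_mm / 2.0 + 8.0,
                 plug.diameter_mm / 2.0 + 8.0,
                 plug.length_mm / 2.0 + 8.0 + z_margin_mm)
    for axis in range(3):
        try:
            profile, positions = _axis_profile(volume, centroid, axis,
                                               half_lens[axis], bounds[axis])
            start = int(np.argmin(np.abs(positions - centroid[axis])))
            left, right = _threshold_crossings(profile, positions, start,
                                               threshold, polarity)
            centroid[axis] = 0.5 * (left + right)
        except ProfileTruncationError:
            pass  # keep the mask centroid on truncated axes

    # interior HU ROI: coaxial cylinder, 70 % diameter, 60 % length —
    # sized so the ROI keeps clear of axial motion-blur rims while holding
    # enough voxels for sub-HU precision of the plug mean
    roi_r = 0.35 * plug.diameter_mm
    roi_hz = 0.3 * plug.length_mm
    rbox = _search_box(volume, centroid, (roi_r, roi_r, roi_hz))
    coords = [
        volume.origin_mm[a] + volume.spacing_mm[a] * np.arange(rbox[a].start, rbox[a].stop)
        for a in range(3)
    ]
    rr = ((coords[0][:, None] - centroid[0]) ** 2
          + (coords[1][None, :] - centroid[1]) ** 2)
    in_roi = (rr[:, :, None] <= roi_r ** 2) & (
        np.abs(coords[2][None, None, :] - centroid[2]) <= roi_hz
    )
    rsub = volume.voxels[rbox]
    if not in_roi.any():
        vals = rsub.ravel()
    else:
        vals = rsub[in_roi]
    return PlugMeasurement(
        plug_id=plug.plug_id,
        bin_label=volume.bin_label,
        centroid_mm=tuple(float(c) for c in centroid),
        fwhm_mm=None,
        mean_hu=float(vals.mean()),
        std_hu=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        threshold_hu=threshold,
        voxel_count=int(mask.sum()),
        touches_boundary=touches,
    )


# ---------------------------------------------------------------------------
# FWHM


def fwhm_profile(values, positions, baseline_hu: float, peak_hu: float) -> float:
    """Full width at half maximum of a 1D HU profile.

    The half level is ``baseline + (peak - baseline)/2``; the two crossings
    are found by linear interpolation between adjacent samples, scanning
    outward from the profile extremum (minimum for inverted profiles).
    Samples exactly at the half level count as inside the object.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if values.shape != positions.shape or values.ndim != 1:
        raise ValueError("values and positions must be matching 1D sequences")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if peak_hu == baseline_hu:
        raise ValueError("peak_hu must differ from baseline_hu")
    left, right = half_level_crossings(values, positions, baseline_hu, peak_hu)
    return right - left


def half_level_crossings(values, positions, baseline_hu: float,
                         peak_hu: float) -> tuple[float, float]:
    """Positions of the two half-level crossings around the profile extremum."""
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    sign = 1.0 if peak_hu > baseline_hu else -1.0
    half = baseline_hu + (peak_hu - baseline_hu) / 2.0
    i_ext = int(np.argmax(sign * values))
    return _threshold_crossings(values, positions, i_ext, half, sign)


def _threshold_crossings(values, positions, start: int, level: float,
                         sign: float) -> tuple[float, float]:
    """Outermost-scan crossings of ``level`` walking outward from ``start``.

    Samples exactly at the level count as inside the object.
    """
    v = sign * np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    lvl = sign * level
    if v[start] < lvl:
        raise ProfileTruncationError("profile never attains the half level")

    def crossing(direction: int) -> float:
        i = start
        while True:
            j = i + direction
            if j < 0 or j >= len(v):
                side = "left" if direction < 0 else "right"
                raise ProfileTruncationError(
                    f"profile truncated: half level never crossed on the {side} side"
                )
            if v[j] < lvl:
                frac = (v[i] - lvl) / (v[i] - v[j])
                return positions[i] + frac * (positions[j] - positions[i])
            i = j

    return crossing(-1), crossing(+1)


def _axis_profile(volume: CTVolume, centroid_mm, axis: int,
                  half_len_mm: float,
                  bounds_mm: tuple[float, float] | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """HU profile along one axis through a point, averaged over the
    3x3 perpendicular voxel neighbourhood.

    ``bounds_mm`` clips the profile (e.g. to the phantom body) so the
    search for the half-level crossings cannot wander into outside air.
    """
    ci = volume.index_of(centroid_mm)
    lo_mm = centroid_mm[axis] - half_len_mm
    hi_mm = centroid_mm[axis] + half_len_mm
    if bounds_mm is not None:
        lo_mm = max(lo_mm, bounds_mm[0])
        hi_mm = min(hi_mm, bounds_mm[1])
    i0 = int(math.floor((lo_mm - volume.origin_mm[axis])
                        / volume.spacing_mm[axis]))
    i1 = int(math.ceil((hi_mm - volume.origin_mm[axis])
                       / volume.spacing_mm[axis]))
    i0, i1 = max(i0, 0), min(i1, volume.shape[axis] - 1)
    other = [a for a in range(3) if a != axis]
    sel: list = [None, None, None]
    sel[axis] = slice(i0, i1 + 1)
    for a in other:
        sel[a] = slice(max(ci[a] - 1, 0), min(ci[a] + 1, volume.shape[a] - 1) + 1)
    sub = volume.voxels[tuple(sel)]
    profile = sub.mean(axis=tuple(other))
    positions = volume.origin_mm[axis] + volume.spacing_mm[axis] * np.arange(i0, i1 + 1)
    return profile, positions


def measure_plug_dimensions(
    volume: CTVolume,
    pose: PhantomPose,
    plug: PlugSpec,
    geometry: PhantomGeometry,
    z_margin_mm: float = 0.0,
) -> PlugMeasurement:
    """Detect a plug and fill its per-axis FWHM dimensions.

    Profiles run axis-parallel through the measured centroid, each averaged
    over the 3x3 perpendicular neighbourhood; the baseline is the background
    nominal HU and the peak is the profile extremum.  ``z_margin_mm``
    lengthens the search box and Z profile for intensity-projection images
    whose plug footprint is widened by the motion amplitude.
    """
    meas = detect_plug(volume, pose, plug, geometry, z_margin_mm=z_margin_mm)
    baseline = float(geometry.background.nominal_hu)
    inverted = plug.material.nominal_hu < geometry.background.nominal_hu
    half_lens = (
        plug.diameter_mm / 2.0 + 8.0,
        plug.diameter_mm / 2.0 + 8.0,
        plug.length_mm / 2.0 + 8.0 + z_margin_mm,
    )
    bounds = _body_bounds(pose, geometry, meas.centroid_mm)
    fwhm = []
    for axis in range(3):
        profile, positions = _axis_profile(volume, meas.centroid_mm, axis,
                                           half_lens[axis], bounds[axis])
        peak = float(profile.min() if inverted else profile.max())
        try:
            fwhm.append(fwhm_profile(profile, positions, baseline, peak))
        except ProfileTruncationError as exc:
            raise ProfileTruncationError(
                f"plug {plug.plug_id!r}, axis {'xyz'[axis]}: {exc}"
            ) from exc
    meas.fwhm_mm = tuple(fwhm)
    return meas
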