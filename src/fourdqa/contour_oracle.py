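"""Independent contour-based plug measurement for cross-validation.

Mirrors a manual contour workflow: the plug is delineated as an explicit
iso-contour at the same half-maximum HU level the pipeline uses, and its
dimensions are read off as the bounding extents of the contour on planes
through the plug centre (marching squares via
``skimage.measure.find_contours``).  The centroid comes from the
centre-of-mass of the iso-level binary region.  Deliberately implemented
on a different code path from :mod:`fourdqa.localize` (no shared profile
or FWHM code) so the two can serve as mutual checks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .dicomio import CTVolume
from .geometry import PhantomGeometry, PlugSpec
from .localize import DetectionError, PhantomPose, plug_threshold


def _subvolume(volume: CTVolume, center_mm, half_mm):
    lo, hi = [], []
    for ax in range(3):
        i0 = int(np.floor((center_mm[ax] - half_mm[ax] - volume.origin_mm[ax])
                          / volume.spacing_mm[ax]))
        i1 = int(np.ceil((center_mm[ax] + half_mm[ax] - volume.origin_mm[ax])
                         / volume.spacing_mm[ax]))
        lo.append(max(i0, 0))
        hi.append(min(i1, volume.shape[ax] - 1))
    sub = volume.voxels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    return sub, lo


def _plane_extents(plane: np.ndarray, level: float, invert: bool):
    """Bounding extents (rows, cols) of the iso-contour enclosing the
    plane's extremum, in index units."""
    img = -plane if invert else plane
    lvl = -level if invert else level
    contours = measure.find_contours(img, lvl)
    if not contours:
        raise DetectionError("no iso-contour at the half-maximum level")
    peak = np.unravel_index(np.argmax(img), img.shape)
    best = None
    for c in contours:
        rmin, cmin = c.min(axis=0)
        rmax, cmax = c.max(axis=0)
        if rmin - 1 <= peak[0] <= rmax + 1 and cmin - 1 <= peak[1] <= cmax + 1:
            area = (rmax - rmin) * (cmax - cmin)
            if best is None or area > best[0]:
                best = (area, rmax - rmin, cmax - cmin)
    if best is None:
        raise DetectionError("no iso-contour encloses the plug signal")
    return best[1], best[2]


def contour_plug_measurement(
    volume: CTVolume,
    pose: PhantomPose,
    plug: PlugSpec,
    geometry: PhantomGeometry,
    z_margin_mm: float = 0.0,
):
    """Contour-based (centroid_mm, fwhm_mm) for one plug.

    Dimensions: X and Y from the iso-contour on the axial plane through the
    plug centre, Z from the contour on the coronal (x-z) plane; all at the
    half-maximum level shared with the pipeline.
    """
    level = plug_threshold(geometry, plug)
    invert = plug.material.nominal_hu < geometry.background.nominal_hu
    expected = pose.to_world(geometry.plug_center(plug))
    half = (plug.diameter_mm / 2.0 + 5.0,
            plug.diameter_mm / 2.0 + 5.0,
            plug.length_mm / 2.0 + 7.0 + z_margin_mm)
    sub, lo = _subvolume(volume, expected, half)
    if sub.size == 0:
        raise DetectionError(f"plug {plug.plug_id!r}: empty oracle subvolume")

    mask = (sub <= level) if invert else (sub >= level)
    if not mask.any():
        raise DetectionError(f"plug {plug.plug_id!r}: no voxels at iso level")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    com = ndimage.center_of_mass(mask)
    centroid = tuple(
        volume.origin_mm[a] + volume.spacing_mm[a] * (lo[a] + com[a])
        for a in range(3)
    )
    ci = [int(round(c)) for c in com]
    axial = sub[:, :, ci[2]]
    dx_idx, dy_idx = _plane_extents(axial, level, invert)
    coronal = sub[:, ci[1], :]
    _, dz_idx = _plane_extents(coronal, level, invert)
    sx, sy, sz = volume.spacing_mm
    return centroid, (float(dx_idx) * sx, float(dy_idx) * sy, float(dz_idx) * sz)
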