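"""CT image-quality metric suite.

Computed identically for the stationary scan, every 4D bin, and the
average CT: geometric distortion (marker-pair distances), spatial
resolution (MTF at 10 % from the bead point-spread function), low-contrast
detectability at 1 % contrast, HU constancy against expected CT numbers,
uniformity (peripheral-vs-centre ROIs), noise (sd in the central
uniformity ROI of 40 % module diameter), and low-contrast CNR between the
polystyrene and LDPE plugs.

The CNR denominator is the quadrature sum sqrt(sd1^2 + sd2^2) — the
conventional combination of two independent ROI noises; the literal
arithmetic sum is available behind ``denominator='sum'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dicomio import CTVolume
from .geometry import PhantomGeometry
from .localize import (
    DetectionError,
    PhantomPose,
    PlugMeasurement,
    _weighted_centroid,
    detect_plug,
)


class ConfigurationError(RuntimeError):
    """A metric was requested for a module the geometry does not define."""


# ---------------------------------------------------------------------------
# ROI helpers


def _disc_values(volume: CTVolume, center_mm, radius_mm: float,
                 z_half_mm: float) -> np.ndarray:
    xs = volume.axis_coords(0)
    ys = volume.axis_coords(1)
    zs = volume.axis_coords(2)
    ix = np.nonzero(np.abs(xs - center_mm[0]) <= radius_mm)[0]
    iy = np.nonzero(np.abs(ys - center_mm[1]) <= radius_mm)[0]
    iz = np.nonzero(np.abs(zs - center_mm[2]) <= z_half_mm)[0]
    if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
        return np.empty(0, dtype=np.float32)
    sub = volume.voxels[np.ix_(ix, iy, iz)]
    rr = ((xs[ix][:, None] - center_mm[0]) ** 2
          + (ys[iy][None, :] - center_mm[1]) ** 2)
    return sub[rr <= radius_mm ** 2]


def _annulus_values(volume: CTVolume, center_mm, r_inner_mm: float,
                    r_outer_mm: float, z_half_mm: float) -> np.ndarray:
    xs = volume.axis_coords(0)
    ys = volume.axis_coords(1)
    zs = volume.axis_coords(2)
    ix = np.nonzero(np.abs(xs - center_mm[0]) <= r_outer_mm)[0]
    iy = np.nonzero(np.abs(ys - center_mm[1]) <= r_outer_mm)[0]
    iz = np.nonzero(np.abs(zs - center_mm[2]) <= z_half_mm)[0]
    if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
        return np.empty(0, dtype=np.float32)
    sub = volume.voxels[np.ix_(ix, iy, iz)]
    rr = ((xs[ix][:, None] - center_mm[0]) ** 2
          + (ys[iy][None, :] - center_mm[1]) ** 2)
    ring = (rr >= r_inner_mm ** 2) & (rr <= r_outer_mm ** 2)
    return sub[ring]


# ---------------------------------------------------------------------------
# geometric distortion


def geometric_distortion(volume: CTVolume, pose: PhantomPose,
                         geometry: PhantomGeometry) -> float:
    """|mean measured marker-pair distance - nominal| in mm.

    Marker pairs whose nominal (geometry) separation matches the module's
    stated nominal spacing within 1 mm are measured; markers are localised
    by intensity-weighted centroid.
    """
    sens = geometry.sensitometry
    markers = sens.markers
    nominal = sens.marker_nominal_spacing_mm
    if len(markers) < 2 or nominal is None:
        raise ConfigurationError("geometry defines no marker constellation")
    bg = geometry.background.nominal_hu
    positions = []
    for mk in markers:
        exp = pose.to_world((mk.x_mm, mk.y_mm, sens.z_offset_mm + mk.z_mm))
        got = _weighted_centroid(volume, exp, mk.diameter_mm / 2.0 + 4.0, bg)
        if got is None:
            raise DetectionError(
                f"marker at ({mk.x_mm}, {mk.y_mm}) not found"
            )
        positions.append(got)
    geom_pts = [np.array([mk.x_mm, mk.y_mm, sens.z_offset_mm + mk.z_mm])
                for mk in markers]
    measured = []
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            if abs(np.linalg.norm(geom_pts[i] - geom_pts[j]) - nominal) <= 1.0:
                measured.append(float(np.linalg.norm(positions[i] - positions[j])))
    if not measured:
        raise ConfigurationError("no marker pair at the nominal spacing")
    return abs(float(np.mean(measured)) - float(nominal))


# ---------------------------------------------------------------------------
# MTF


@dataclass
class MTFCurve:
    """Radially averaged in-plane MTF, normalised to 1 at zero frequency."""

    frequency_lp_per_cm: np.ndarray
    modulation: np.ndarray
    saturated: bool = False  # modulation never reached 0.10 below the cap


def _sphere_mtf(freq_per_mm: np.ndarray, diameter_mm: float) -> np.ndarray:
    """Modulus of the normalised 3D Fourier transform of a uniform sphere."""
    u = 2.0 * math.pi * (diameter_mm / 2.0) * freq_per_mm
    out = np.ones_like(u)
    nz = u > 1e-9
    un = u[nz]
    out[nz] = 3.0 * (np.sin(un) - un * np.cos(un)) / un ** 3
    return np.abs(out)


def mtf_from_bead(volume: CTVolume, pose: PhantomPose,
                  geometry: PhantomGeometry,
                  roi_half_mm: float = 10.0,
                  roi_z_half_mm: float = 6.0) -> tuple[MTFCurve, float]:
    """In-plane MTF from the bead image; returns (curve, MTF-10 % in lp/cm).

    The ROI around the bead is background-subtracted (median of the
    ROI shell) and summed along Z, giving the projected point-spread
    function (invariant to axial motion blur); the radially averaged 2D DFT
    magnitude, normalised at zero
    frequency and divided by the analytic sphere-aperture transform of the
    bead diameter, is the MTF.  The aperture correction is clamped at its
    80 %-Nyquist value to avoid noise blow-up; if the modulation never
    falls to 0.10 below that cap, the capped frequency is returned with a
    saturation flag.
    """
    bead = bead_mod = None
    for mod in geometry.modules:
        if mod.bead is not None:
            bead, bead_mod = mod.bead, mod
    if bead is None:
        raise ConfigurationError("geometry defines no bead")
    center = pose.to_world(
        (bead.x_mm, bead.y_mm, bead_mod.z_offset_mm + bead.z_mm))
    half = (roi_half_mm, roi_half_mm, roi_z_half_mm)
    box = []
    for ax in range(3):
        i0 = int(round((center[ax] - half[ax] - volume.origin_mm[ax])
                       / volume.spacing_mm[ax]))
        i1 = int(round((center[ax] + half[ax] - volume.origin_mm[ax])
                       / volume.spacing_mm[ax]))
        box.append(slice(max(i0, 0), min(i1, volume.shape[ax] - 1) + 1))
    sub = volume.voxels[tuple(box)].astype(np.float64)
    if sub.size == 0:
        raise DetectionError("bead ROI outside volume")
    shell = np.ones(sub.shape, dtype=bool)
    shell[1:-1, 1:-1, 1:-1] = False
    background = float(np.median(sub[shell]))
    psf2d = (sub - background).sum(axis=2)
    total = psf2d.sum()
    if not np.isfinite(total) or total == 0.0:
        raise DetectionError("bead signal not above the noise floor")

    px = float(np.mean(volume.spacing_mm[:2]))
    n = 1
    while n < 8 * max(psf2d.shape):
        n *= 2
    spec = np.fft.fft2(psf2d, s=(n, n))
    # recentre: remove the linear phase of the PSF position so the signal
    # is real and positive across each frequency ring; ring-averaging the
    # complex spectrum then averages the noise down instead of rectifying
    # it into a magnitude bias
    w = np.clip(psf2d, 0.0, None)
    ii, jj = np.meshgrid(*[np.arange(s) for s in psf2d.shape], indexing="ij")
    ci = float((w * ii).sum() / w.sum())
    cj = float((w * jj).sum() / w.sum())
    fx = np.fft.fftfreq(n, d=1.0)  # per-sample frequency for the phase ramp
    spec = spec * np.exp(2j * math.pi * (fx[:, None] * ci + fx[None, :] * cj))
    fx = np.fft.fftfreq(n, d=px)
    fr = np.hypot(fx[:, None], fx[None, :])
    nyquist = 0.5 / px
    df = 1.0 / (n * px)
    nbins = int(nyquist / df)
    bins = np.clip((fr / df).astype(int), 0, nbins)
    sums = np.bincount(bins.ravel(), weights=spec.real.ravel(), minlength=nbins + 1)
    counts = np.bincount(bins.ravel(), minlength=nbins + 1)
    radial = sums[: nbins + 1] / np.maximum(counts[: nbins + 1], 1)
    freq = df * np.arange(nbins + 1)
    radial = radial / radial[0]

    cap = 0.8 * nyquist
    aperture = _sphere_mtf(np.minimum(freq, cap), bead.diameter_mm)
    modulation = radial / np.maximum(aperture, 1e-6)
    keep = freq <= cap
    freq, modulation = freq[keep], modulation[keep]
    modulation = modulation / modulation[0]

    saturated = True
    f10 = freq[-1]
    below = np.nonzero(modulation < 0.10)[0]
    if len(below) > 0:
        j = int(below[0])
        if j == 0:
            f10 = freq[0]
        else:
            frac = (modulation[j - 1] - 0.10) / (modulation[j - 1] - modulation[j])
            f10 = freq[j - 1] + frac * (freq[j] - freq[j - 1])
        saturated = False
    curve = MTFCurve(
        frequency_lp_per_cm=freq * 10.0,
        modulation=modulation,
        saturated=saturated,
    )
    return curve, float(f10 * 10.0)  # cycles/mm -> lp/cm


# ---------------------------------------------------------------------------
# low contrast


@dataclass
class LowContrastResult:
    smallest_detectable_mm: float | None
    largest_tested_mm: float
    decision_threshold: float
    scores: dict[float, float]  # diameter -> contrast-to-noise score


def low_contrast_detectability(
    volume: CTVolume, pose: PhantomPose, geometry: PhantomGeometry,
    decision_threshold: float = 2.0, contrast_percent: float = 1.0,
) -> LowContrastResult:
    """Smallest detectable target diameter at the given nominal contrast.

    A target counts as detectable when |mean(disc) - mean(background
    annulus)| / sd(annulus) reaches the decision threshold.
    """
    try:
        mod = geometry.module("low_contrast")
    except KeyError:
        raise ConfigurationError("geometry defines no low_contrast module") from None
    targets = [t for t in mod.low_contrast_targets
               if abs(t.contrast_percent - contrast_percent) < 1e-9]
    if not targets:
        raise ConfigurationError(
            f"no low-contrast targets at {contrast_percent} % contrast"
        )
    targets = sorted(targets, key=lambda t: -t.diameter_mm)
    z_half = min(8.0, 0.3 * mod.thickness_mm)
    scores: dict[float, float] = {}
    smallest = None
    for t in targets:
        x, y = t.center_xy()
        center = pose.to_world((x, y, mod.z_offset_mm))
        r = t.diameter_mm / 2.0
        disc = _disc_values(volume, center, max(0.7 * r, 0.6), z_half)
        ring = _annulus_values(volume, center, r + 3.0, r + 8.0, z_half)
        if disc.size == 0 or ring.size < 10:
            continue
        sd = float(ring.std(ddof=1))
        score = abs(float(disc.mean()) - float(ring.mean())) / max(sd, 1e-9)
        scores[t.diameter_mm] = score
        if score >= decision_threshold:
            smallest = t.diameter_mm if smallest is None else min(smallest, t.diameter_mm)
    return LowContrastResult(
        smallest_detectable_mm=smallest,
        largest_tested_mm=targets[0].diameter_mm,
        decision_threshold=decision_threshold,
        scores=scores,
    )


# ---------------------------------------------------------------------------
# HU metrics


def hu_constancy(volume: CTVolume, pose: PhantomPose,
                 geometry: PhantomGeometry) -> float:
    """Max absolute deviation of measured plug HU from expected CT numbers.

    Runs over the plugs carrying the ``hu_constancy`` role (air, LDPE,
    acrylic in the builtin geometries, with expected -1000/-100/120 HU).
    """
    plugs = [p for p in geometry.plugs() if "hu_constancy" in p.roles]
    if not plugs:
        raise ConfigurationError("no plugs carry the hu_constancy role")
    worst = 0.0
    for plug in plugs:
        meas = detect_plug(volume, pose, plug, geometry)
        worst = max(worst, abs(meas.mean_hu - plug.material.nominal_hu))
    return worst


def hu_consistency_per_plug(
    bin_measurements: dict[str, list[PlugMeasurement]],
    stationary_measurements: dict[str, PlugMeasurement],
) -> dict[str, float]:
    """Per plug: mean-over-bins mean HU minus the stationary mean HU."""
    if set(bin_measurements) != set(stationary_measurements):
        raise ValueError(
            "plug sets differ between bins and stationary: "
            f"{sorted(bin_measurements)} vs {sorted(stationary_measurements)}"
        )
    out = {}
    for pid, meas_list in bin_measurements.items():
        mean_bins = float(np.mean([m.mean_hu for m in meas_list]))
        out[pid] = mean_bins - float(stationary_measurements[pid].mean_hu)
    return out


def uniformity(volume: CTVolume, pose: PhantomPose,
               geometry: PhantomGeometry,
               peripheral_diameter_fraction: float = 0.10,
               peripheral_radius_fraction: float = 0.80) -> float:
    """Max |peripheral ROI mean - centre ROI mean| in the uniformity module."""
    mod = geometry.uniformity_module
    module_diameter = geometry.outer_diameter_mm
    roi_r = 0.5 * peripheral_diameter_fraction * module_diameter
    offset = peripheral_radius_fraction * module_diameter / 2.0
    z_half = min(5.0, 0.3 * mod.thickness_mm)
    center = pose.to_world((0.0, 0.0, mod.z_offset_mm))
    c_mean = float(_disc_values(volume, center, roi_r, z_half).mean())
    worst = 0.0
    for ang in (90.0, 0.0, 270.0, 180.0):  # 12 / 3 / 6 / 9 o'clock
        th = math.radians(ang)
        p = pose.to_world((offset * math.cos(th), offset * math.sin(th),
                           mod.z_offset_mm))
        p_mean = float(_disc_values(volume, p, roi_r, z_half).mean())
        worst = max(worst, abs(p_mean - c_mean))
    return worst


def noise(volume: CTVolume, pose: PhantomPose,
          geometry: PhantomGeometry) -> float:
    """Sample sd of HU in the central uniformity ROI (40 % module diameter)."""
    mod = geometry.uniformity_module
    roi_r = 0.5 * 0.40 * geometry.outer_diameter_mm
    z_half = min(5.0, 0.3 * mod.thickness_mm)
    center = pose.to_world((0.0, 0.0, mod.z_offset_mm))
    vals = _disc_values(volume, center, roi_r, z_half)
    if vals.size < 2:
        raise ConfigurationError("uniformity ROI empty")
    return float(vals.std(ddof=1))


def cnr_low_contrast(volume: CTVolume, pose: PhantomPose,
                     geometry: PhantomGeometry,
                     denominator: str = "quadrature") -> float:
    """CNR between the two cnr_pair_member plugs (polystyrene vs LDPE).

    Difference of the two interior-ROI mean HUs divided by the quadrature
    sum of their sds (or the arithmetic sum with ``denominator='sum'``).
    Sign preserved: the denser material's mean comes first.
    """
    pair = [p for p in geometry.plugs() if "cnr_pair_member" in p.roles]
    if len(pair) != 2:
        raise ConfigurationError(
            f"expected exactly two cnr_pair_member plugs, got {len(pair)}"
        )
    pair = sorted(pair, key=lambda p: -p.material.nominal_hu)
    m1 = detect_plug(volume, pose, pair[0], geometry)
    m2 = detect_plug(volume, pose, pair[1], geometry)
    if denominator == "quadrature":
        denom = math.hypot(m1.std_hu, m2.std_hu)
    elif denominator == "sum":
        denom = m1.std_hu + m2.std_hu
    else:
        raise ValueError("denominator must be 'quadrature' or 'sum'")
    if denom == 0.0:
        return math.inf  # undefined-CNR sentinel (noiseless input)
    return (m1.mean_hu - m2.mean_hu) / denom


# ---------------------------------------------------------------------------
# suite


@dataclass
class IQMetrics:
    bin_label: str
    geometric_distortion_mm: float | None = None
    mtf10_lp_per_cm: float | None = None
    mtf_saturated: bool | None = None
    contrast_detectability_mm: float | None = None
    contrast_none_detected: bool = False
    hu_constancy_hu: float | None = None
    uniformity_hu: float | None = None
    noise_hu: float | None = None
    cnr_low_contrast: float | None = None
    plug_mean_hu: dict[str, float] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def iq_suite(volume: CTVolume, pose: PhantomPose, geometry: PhantomGeometry,
             decision_threshold: float = 2.0) -> IQMetrics:
    """Run every metric the geometry supports; failures are recorded
    per-metric and never abort the suite."""
    out = IQMetrics(bin_label=volume.bin_label)

    def attempt(name, fn):
        try:
            return fn()
        except Exception as exc:  # per-metric degradation by contract
            out.errors[name] = f"{type(exc).__name__}: {exc}"
            return None

    out.geometric_distortion_mm = attempt(
        "geometric_distortion", lambda: geometric_distortion(volume, pose, geometry))

    def _mtf():
        curve, f10 = mtf_from_bead(volume, pose, geometry)
        out.mtf_saturated = curve.saturated
        return f10

    out.mtf10_lp_per_cm = attempt("mtf10", _mtf)

    def _contrast():
        res = low_contrast_detectability(volume, pose, geometry,
                                         decision_threshold=decision_threshold)
        if res.smallest_detectable_mm is None:
            out.contrast_none_detected = True
            return None
        return res.smallest_detectable_mm

    out.contrast_detectability_mm = attempt("contrast", _contrast)
    out.hu_constancy_hu = attempt(
        "hu_constancy", lambda: hu_constancy(volume, pose, geometry))
    out.uniformity_hu = attempt(
        "uniformity", lambda: uniformity(volume, pose, geometry))
    out.noise_hu = attempt("noise", lambda: noise(volume, pose, geometry))
    out.cnr_low_contrast = attempt(
        "cnr", lambda: cnr_low_contrast(volume, pose, geometry))

    def _plug_table():
        table = {}
        for plug in geometry.sensitometry.plugs:
            table[plug.plug_id] = detect_plug(volume, pose, plug, geometry).mean_hu
        return table

    out.plug_mean_hu = attempt("plug_hu", _plug_table) or {}
    return out


def iq_summary(per_bin: list[IQMetrics]) -> dict[str, tuple[float, float]]:
    """Unweighted mean +/- sample sd of each scalar metric across bins."""
    fields = ("geometric_distortion_mm", "mtf10_lp_per_cm",
              "contrast_detectability_mm", "hu_constancy_hu",
              "uniformity_hu", "noise_hu", "cnr_low_contrast")
    out = {}
    for name in fields:
        vals = [getattr(m, name) for m in per_bin
                if getattr(m, name) is not None and np.isfinite(getattr(m, name))]
        if vals:
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            out[name] = (float(np.mean(vals)), sd)
    return out
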