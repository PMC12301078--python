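"""Synthetic 4DCT generator: voxel rendering of the phantom under rigid motion.

Stands in for the physical phantom + motion platform + scanner chain: the
phantom geometry is rendered at arbitrary rigid displacements on a regular
HU grid with partial-volume edges and a Gaussian point-spread function, and
a retrospectively binned 4DCT (phase- or amplitude-based, default 10 bins)
is assembled by averaging renderings at each bin's sub-displacements
(intra-bin motion blur) and adding seeded Gaussian noise per bin.

Rendering model
---------------
Every solid in the geometry is either a Z-axis cylinder (phantom body,
sensitometry plugs, low-contrast rods) or a sphere (bead, markers).
Cylinder occupancy is separable: the in-plane disc fraction is computed by
``supersampling``:math:`^2` subsampling of boundary pixels, and the axial
cell/interval overlap is computed analytically (exact).  Spheres are
subsampled in 3D.  Solids are composited back-to-front
(air -> body -> inserts) by occupancy-weighted blending, then blurred by
the PSF and clipped to [-1024, 3071] HU.  Rendering is deterministic; noise
is only added by :func:`simulate_4dct`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .dicomio import CTVolume, Phase4DSeries, HU_MIN, HU_MAX, phase_label, amplitude_label
from .geometry import PhantomGeometry


class RenderError(ValueError):
    """Phantom does not fit the requested grid."""


class DegenerateTraceError(ValueError):
    """Amplitude binning requested for a zero-amplitude trace."""


# ---------------------------------------------------------------------------
# motion traces


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-motion trace of the whole phantom.

    ``kind='sinusoid'``: per-axis peak-to-peak amplitudes sharing one phase,
    anchored so cycle fraction 0 sits at peak displacement (peak-inhale
    analog); ``kind='sampled'``: an explicit (t, dx, dy, dz) time series
    with an optional dominant period used for phase binning.
    """

    kind: str = "sinusoid"
    peak_to_peak_mm: tuple[float, float, float] = (0.0, 0.0, 15.0)
    period_s: float = 6.0
    phase_offset_fraction: float = 0.0
    samples: np.ndarray | None = None  # (N, 4): t_s, dx, dy, dz

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoid", "sampled"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.kind == "sinusoid":
            if any(a < 0 for a in self.peak_to_peak_mm):
                raise ValueError("peak_to_peak_mm must be >= 0 per axis")
            if self.period_s <= 0:
                raise ValueError("period_s must be > 0")
            if not (0.0 <= self.phase_offset_fraction < 1.0):
                raise ValueError("phase_offset_fraction must lie in [0, 1)")
        else:
            if self.samples is None or np.asarray(self.samples).ndim != 2 \
                    or np.asarray(self.samples).shape[1] != 4:
                raise ValueError("sampled trace requires an (N, 4) sample array")
            t = np.asarray(self.samples)[:, 0]
            if len(t) < 2 or np.any(np.diff(t) <= 0):
                raise ValueError("sampled trace times must be strictly increasing")

    def displacement_at_fraction(self, frac) -> np.ndarray:
        """Sinusoid displacement (mm, 3-vector rows) at cycle fraction(s)."""
        if self.kind != "sinusoid":
            raise ValueError("displacement_at_fraction applies to sinusoid traces")
        frac = np.atleast_1d(np.asarray(frac, dtype=float))
        amp = np.asarray(self.peak_to_peak_mm) / 2.0
        c = np.cos(2.0 * math.pi * (frac + self.phase_offset_fraction))
        return c[:, None] * amp[None, :]

    def sample_vectors(self) -> np.ndarray:
        """Displacement vectors of the trace, densely for a sinusoid."""
        if self.kind == "sampled":
            return np.asarray(self.samples, dtype=float)[:, 1:4]
        frac = np.arange(720) / 720.0
        return self.displacement_at_fraction(frac)

    def peak_to_peak(self) -> np.ndarray:
        """Known input amplitude per axis (mm): max - min displacement."""
        if self.kind == "sinusoid":
            return np.asarray(self.peak_to_peak_mm, dtype=float)
        d = self.sample_vectors()
        return d.max(axis=0) - d.min(axis=0)

    def principal_axis(self) -> int:
        return int(np.argmax(self.peak_to_peak()))


def patient_like_trace(
    peak_to_peak_mm: tuple[float, float, float] = (3.0, 2.0, 12.0),
    period_s: float = 5.0,
    duration_s: float = 30.0,
    dt_s: float = 0.05,
    drift_mm: float = 1.0,
) -> MotionTrace:
    """Synthetic breathing-like 3D trace: two harmonics plus a slow drift.

    A stand-in for a recorded patient breathing trace: the dominant
    respiratory harmonic plus a second harmonic (breathing asymmetry) on
    each axis with small phase lags, and a linear baseline drift on Z.  The
    realised per-axis peak-to-peak comes out close to, but not exactly,
    ``peak_to_peak_mm``; downstream "expected amplitude" is always taken
    from the sampled extremes, never from the nominal inputs.
    """
    t = np.arange(0.0, duration_s, dt_s)
    w = 2.0 * math.pi * t / period_s
    lags = (0.3, 1.0, 0.0)
    cols = []
    for ax in range(3):
        shape = 0.78 * np.cos(w - lags[ax]) + 0.22 * np.cos(2.0 * (w - lags[ax]) - 0.4)
        cols.append(0.5 * peak_to_peak_mm[ax] * shape)
    cols[2] = cols[2] + drift_mm * (t / duration_s - 0.5)
    samples = np.column_stack([t, *cols])
    return MotionTrace(kind="sampled", samples=samples, period_s=period_s)


# ---------------------------------------------------------------------------
# acquisition / binning specs


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scanner-chain parameters of the simulator.

    Defaults emulate a lung protocol: 1 mm in-plane voxels, 2 mm slices,
    1 mm Gaussian PSF (chosen no sharper than the in-plane pitch so the
    PSF — and hence the MTF 10 % frequency — is resolvable on the default
    grid), 10 HU additive noise.
    """

    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    grid_shape: tuple[int, int, int] = (216, 216, 104)
    psf_sigma_mm: float = 1.0
    noise_sigma_hu: float = 10.0
    supersampling: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacings must be > 0")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be >= 0")
        if self.psf_sigma_mm < 0:
            raise ValueError("psf_sigma_mm must be >= 0")


@dataclass(frozen=True)
class BinningSpec:
    mode: str = "phase"  # "phase" | "amplitude"
    n_bins: int = 10
    intra_bin_samples: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("phase", "amplitude"):
            raise ValueError(f"unknown binning mode {self.mode!r}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.intra_bin_samples < 1:
            raise ValueError("intra_bin_samples must be >= 1")


@dataclass
class GroundTruth:
    """Simulator ground truth emitted next to the synthetic dataset."""

    plug_dimensions_mm: dict[str, tuple[float, float, float]]
    bin_mean_displacement_mm: list[tuple[float, float, float]]
    peak_to_peak_mm: tuple[float, float, float]
    bin_labels: list[str]


# ---------------------------------------------------------------------------
# trace binning


def _representatives(members: np.ndarray, m: int,
                     include_last: bool = False) -> list[np.ndarray]:
    """Pick m evenly spaced rows from an ordered member array.

    ``include_last`` keeps both endpoints (used for value-ordered amplitude
    bins so the outer bins retain the trace extremes); otherwise the
    selection is anchored at the start, matching phase-window sampling.
    """
    n = len(members)
    if n == 0:
        raise DegenerateTraceError("a bin received no trace samples")
    if n <= m:
        return [members[i] for i in range(n)]
    if include_last and m > 1:
        idx = np.unique(np.round(np.linspace(0, n - 1, m)).astype(int))
    else:
        idx = np.floor(np.arange(m) * n / m).astype(int)
    return [members[i] for i in idx]


def sample_trace_bins(trace: MotionTrace, binning: BinningSpec) -> list[list[np.ndarray]]:
    """Per-bin sub-displacement vectors for a retrospective 4D binning.

    Phase mode: bin *k* covers cycle fractions [k/n, (k+1)/n); its
    ``intra_bin_samples`` sub-displacements are taken at evenly spaced
    fractions anchored at the bin start.  Amplitude mode: the displacement
    range along the principal motion axis is split into n equal-width
    intervals; each bin's sub-displacements are trace samples falling in
    its interval (reduced to evenly spaced representatives ordered by
    displacement, so the outer bins retain the trace extremes).
    """
    n, m = binning.n_bins, binning.intra_bin_samples
    if binning.mode == "phase":
        if trace.kind == "sinusoid":
            out = []
            for k in range(n):
                frac = (k + np.arange(m) / m) / n
                out.append(list(trace.displacement_at_fraction(frac)))
            return out
        samples = np.asarray(trace.samples, dtype=float)
        t = samples[:, 0]
        if trace.period_s and trace.period_s > 0:
            frac = np.mod(t - t[0], trace.period_s) / trace.period_s
        else:
            frac = (t - t[0]) / (t[-1] - t[0] + (t[-1] - t[0]) / max(len(t) - 1, 1))
        out = []
        for k in range(n):
            sel = (frac >= k / n) & (frac < (k + 1) / n)
            members = samples[sel][np.argsort(frac[sel])][:, 1:4]
            out.append(_representatives(members, m))
        return out

    # amplitude mode
    disp = trace.sample_vectors()
    axis = trace.principal_axis()
    z = disp[:, axis]
    lo, hi = float(z.min()), float(z.max())
    if hi - lo <= 0.0:
        raise DegenerateTraceError("amplitude binning requires a nonzero-amplitude trace")
    edges = np.linspace(lo, hi, n + 1)
    out = []
    for k in range(n):
        sel = (z >= edges[k]) & ((z < edges[k + 1]) if k < n - 1 else (z <= edges[k + 1]))
        members = disp[sel][np.argsort(z[sel])]
        out.append(_representatives(members, m, include_last=True))
    return out


# ---------------------------------------------------------------------------
# rendering


def _disc_occupancy(xs: np.ndarray, ys: np.ndarray, cx: float, cy: float,
                    radius: float, ss: int) -> np.ndarray:
    """Area fraction of each pixel covered by a disc (supersampled edges).

    ``xs``/``ys`` are pixel-centre coordinate vectors; the result has shape
    (len(xs), len(ys)).
    """
    dx = xs[:, None] - cx
    dy = ys[None, :] - cy
    d = np.hypot(dx, dy)
    px = abs(xs[1] - xs[0]) if len(xs) > 1 else 1.0
    py = abs(ys[1] - ys[0]) if len(ys) > 1 else px
    half_diag = 0.5 * math.hypot(px, py)
    occ = (d <= radius - half_diag).astype(np.float32)
    band = (d > radius - half_diag) & (d < radius + half_diag)
    if np.any(band):
        bi, bj = np.nonzero(band)
        off_x = (np.arange(ss) + 0.5) / ss - 0.5
        sub_x = xs[bi][:, None] + (off_x * px)[None, :]
        sub_y = ys[bj][:, None] + (off_x * py)[None, :]
        inside = (
            (sub_x[:, :, None] - cx) ** 2 + (sub_y[:, None, :] - cy) ** 2
            <= radius * radius
        )
        occ[bi, bj] = inside.mean(axis=(1, 2)).astype(np.float32)
    return occ


def _interval_occupancy(zs: np.ndarray, sz: float, z0: float, z1: float) -> np.ndarray:
    """Exact overlap fraction of each slice cell [z - sz/2, z + sz/2] with [z0, z1]."""
    lo = np.maximum(zs - sz / 2.0, z0)
    hi = np.minimum(zs + sz / 2.0, z1)
    return np.clip((hi - lo) / sz, 0.0, 1.0).astype(np.float32)


class Renderer:
    """Renders a phantom geometry on a fixed grid at arbitrary displacements.

    Caches in-plane disc occupancies keyed by (centre, radius), so 1D
    axial-motion series re-render at the cost of the axial overlap and the
    compositing only.
    """

    def __init__(self, geometry: PhantomGeometry, acq: AcquisitionSpec):
        self.geometry = geometry
        self.acq = acq
        nx, ny, nz = acq.grid_shape
        sx, sy, sz = acq.voxel_spacing_mm
        self.origin = (-(nx - 1) / 2.0 * sx, -(ny - 1) / 2.0 * sy, -(nz - 1) / 2.0 * sz)
        self.xs = self.origin[0] + sx * np.arange(nx)
        self.ys = self.origin[1] + sy * np.arange(ny)
        self.zs = self.origin[2] + sz * np.arange(nz)
        self._disc_cache: dict[tuple, np.ndarray] = {}
        self._cylinders, self._spheres = self._collect_solids()

    def _collect_solids(self):
        g = self.geometry
        cylinders = []  # (cx, cy, radius, z0, z1, hu)
        spheres = []  # (cx, cy, cz, radius, hu)
        cylinders.append(
            (0.0, 0.0, g.outer_diameter_mm / 2.0,
             g.body_z_range_mm[0], g.body_z_range_mm[1], float(g.background.nominal_hu))
        )
        for mod in g.modules:
            for plug in mod.plugs:
                cx, cy, cz = g.plug_center(plug)
                cylinders.append(
                    (cx, cy, plug.diameter_mm / 2.0,
                     cz - plug.length_mm / 2.0, cz + plug.length_mm / 2.0,
                     float(plug.material.nominal_hu))
                )
            for t in mod.low_contrast_targets:
                cx, cy = t.center_xy()
                z0, z1 = mod.z_range
                from .geometry import HU_PER_PERCENT_CONTRAST

                hu = g.background.nominal_hu + HU_PER_PERCENT_CONTRAST * t.contrast_percent
                cylinders.append((cx, cy, t.diameter_mm / 2.0, z0, z1, float(hu)))
            if mod.bead is not None:
                b = mod.bead
                spheres.append((b.x_mm, b.y_mm, mod.z_offset_mm + b.z_mm,
                                b.diameter_mm / 2.0, float(b.material.nominal_hu)))
            for mk in mod.markers:
                spheres.append((mk.x_mm, mk.y_mm, mod.z_offset_mm + mk.z_mm,
                                mk.diameter_mm / 2.0, float(mk.material.nominal_hu)))
        return cylinders, spheres

    def _check_fits(self, disp: np.ndarray) -> None:
        g = self.geometry
        rad = g.outer_diameter_mm / 2.0
        sx, sy, sz = self.acq.voxel_spacing_mm
        if (abs(disp[0]) + rad > abs(self.xs[0]) + sx / 2.0
                or abs(disp[1]) + rad > abs(self.ys[0]) + sy / 2.0):
            raise RenderError("displaced phantom exceeds the in-plane grid extent")
        z0 = g.body_z_range_mm[0] + disp[2]
        z1 = g.body_z_range_mm[1] + disp[2]
        if z0 < self.zs[0] - sz / 2.0 or z1 > self.zs[-1] + sz / 2.0:
            raise RenderError("displaced phantom exceeds the axial grid extent")

    def _disc(self, cx: float, cy: float, radius: float) -> np.ndarray:
        key = (round(cx, 6), round(cy, 6), round(radius, 6))
        occ = self._disc_cache.get(key)
        if occ is None:
            occ = _disc_occupancy(self.xs, self.ys, cx, cy, radius,
                                  self.acq.supersampling)
            self._disc_cache[key] = occ
        return occ

    def render(self, displacement) -> CTVolume:
        """Noise-free HU volume of the phantom displaced rigidly by ``displacement``."""
        disp = np.asarray(displacement, dtype=float)
        self._check_fits(disp)
        acq = self.acq
        sx, sy, sz = acq.voxel_spacing_mm
        nx, ny, nz = acq.grid_shape
        vol = np.full((nx, ny, nz), float(self.geometry.air.nominal_hu),
                      dtype=np.float32)
        for cx, cy, radius, z0, z1, hu in self._cylinders:
            occ2 = self._disc(cx + disp[0], cy + disp[1], radius)
            occz = _interval_occupancy(self.zs, sz, z0 + disp[2], z1 + disp[2])
            jz = np.nonzero(occz > 0)[0]
            if len(jz) == 0:
                continue
            zsl = slice(jz[0], jz[-1] + 1)
            ii = np.nonzero(occ2.any(axis=1))[0]
            jj = np.nonzero(occ2.any(axis=0))[0]
            if len(ii) == 0:
                continue
            xsl, ysl = slice(ii[0], ii[-1] + 1), slice(jj[0], jj[-1] + 1)
            occ3 = occ2[xsl, ysl, None] * occz[None, None, zsl]
            sub = vol[xsl, ysl, zsl]
            vol[xsl, ysl, zsl] = sub + occ3 * (hu - sub)
        ss = max(acq.supersampling, 4)
        off = (np.arange(ss) + 0.5) / ss - 0.5
        for cx, cy, cz, radius, hu in self._spheres:
            c = np.array([cx, cy, cz]) + disp
            ilo = [max(0, int(math.floor((c[a] - radius - self.origin[a]) / acq.voxel_spacing_mm[a])))
                   for a in range(3)]
            ihi = [min(acq.grid_shape[a] - 1,
                       int(math.ceil((c[a] + radius - self.origin[a]) / acq.voxel_spacing_mm[a])))
                   for a in range(3)]
            if any(ihi[a] < ilo[a] for a in range(3)):
                continue
            coords = [
                (self.origin[a] + acq.voxel_spacing_mm[a]
                 * np.arange(ilo[a], ihi[a] + 1))[:, None]
                + (off * acq.voxel_spacing_mm[a])[None, :] - c[a]
                for a in range(3)
            ]
            inside = (
                coords[0][:, None, None, :, None, None] ** 2
                + coords[1][None, :, None, None, :, None] ** 2
                + coords[2][None, None, :, None, None, :] ** 2
                <= radius * radius
            )
            occ3 = inside.mean(axis=(3, 4, 5)).astype(np.float32)
            sub = vol[ilo[0]:ihi[0] + 1, ilo[1]:ihi[1] + 1, ilo[2]:ihi[2] + 1]
            vol[ilo[0]:ihi[0] + 1, ilo[1]:ihi[1] + 1, ilo[2]:ihi[2] + 1] = \
                sub + occ3 * (hu - sub)
        if acq.psf_sigma_mm > 0:
            vol = gaussian_filter(
                vol, sigma=[acq.psf_sigma_mm / s for s in acq.voxel_spacing_mm],
                mode="nearest",
            )
        np.clip(vol, HU_MIN, HU_MAX, out=vol)
        return CTVolume(voxels=vol, spacing_mm=acq.voxel_spacing_mm,
                        origin_mm=self.origin, bin_label="render")


def render_phantom(geometry: PhantomGeometry, displacement,
                   acq: AcquisitionSpec) -> CTVolume:
    """One-shot noise-free render of the phantom at a rigid displacement."""
    return Renderer(geometry, acq).render(displacement)


# ---------------------------------------------------------------------------
# 4DCT simulation


def _dedupe_key(vec: np.ndarray) -> tuple:
    return tuple(round(float(v), 9) for v in vec)


def simulate_4dct(
    geometry: PhantomGeometry,
    trace: MotionTrace,
    binning: BinningSpec = BinningSpec(),
    acq: AcquisitionSpec = AcquisitionSpec(),
) -> tuple[CTVolume, Phase4DSeries, GroundTruth]:
    """Simulate a stationary reference scan plus a retrospectively binned 4DCT.

    The stationary volume is rendered at zero displacement; each bin is the
    mean of noise-free renderings at its sub-displacements (intra-bin motion
    blur) plus independent Gaussian noise seeded per (series, bin).
    Bit-reproducible for a fixed ``acq.seed``.
    """
    renderer = Renderer(geometry, acq)
    bin_disps = sample_trace_bins(trace, binning)
    cache: dict[tuple, np.ndarray] = {}

    def rendered(vec: np.ndarray) -> np.ndarray:
        key = _dedupe_key(vec)
        if key not in cache:
            cache[key] = renderer.render(vec).voxels
        return cache[key]

    children = np.random.SeedSequence(acq.seed).spawn(1 + binning.n_bins)

    def with_noise(vox: np.ndarray, seed_seq) -> np.ndarray:
        if acq.noise_sigma_hu > 0:
            rng = np.random.default_rng(seed_seq)
            vox = vox + rng.normal(0.0, acq.noise_sigma_hu, vox.shape).astype(np.float32)
            np.clip(vox, HU_MIN, HU_MAX, out=vox)
        return vox

    stationary_vox = with_noise(rendered(np.zeros(3)).copy(), children[0])
    stationary = CTVolume(
        voxels=stationary_vox, spacing_mm=acq.voxel_spacing_mm,
        origin_mm=renderer.origin, series_id="sim-stationary",
        bin_label="stationary",
    )

    volumes = []
    bin_means = []
    labels = []
    for k, disps in enumerate(bin_disps):
        acc = np.zeros(acq.grid_shape, dtype=np.float32)
        for vec in disps:
            acc += rendered(np.asarray(vec, dtype=float))
        acc /= len(disps)
        vox = with_noise(acc, children[k + 1])
        label = (phase_label(k, binning.n_bins) if binning.mode == "phase"
                 else amplitude_label(k))
        volumes.append(CTVolume(
            voxels=vox, spacing_mm=acq.voxel_spacing_mm, origin_mm=renderer.origin,
            series_id=f"sim-{binning.mode}-{k}", bin_label=label,
        ))
        bin_means.append(tuple(np.mean(np.asarray(disps, dtype=float), axis=0)))
        labels.append(label)

    series = Phase4DSeries(volumes, binning_mode=binning.mode)
    truth = GroundTruth(
        plug_dimensions_mm={
            p.plug_id: (p.diameter_mm, p.diameter_mm, p.length_mm)
            for p in geometry.plugs()
        },
        bin_mean_displacement_mm=bin_means,
        peak_to_peak_mm=tuple(trace.peak_to_peak()),
        bin_labels=labels,
    )
    return stationary, series, truth
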