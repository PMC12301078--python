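# Methods

This note documents the models, estimators and numerical choices behind
`fourdqa`: what the simulator emulates, how each QA quantity is defined
and computed, which parameters matter, and what passing the bundled tests
does and does not demonstrate about real scanner data.

## Phantom model

The phantom is described declaratively (`fourdqa.geometry`): a solid
water-equivalent cylinder (200 mm diameter, 0 HU) containing four axially
stacked modules —

| module | contents | used by |
|---|---|---|
| sensitometry | 7 plugs (Ø 12.3 × 25.0 mm; Teflon 990, Air −1000, LDPE −100, polystyrene −35, acrylic 120, Delrin 340, PMP −200 HU) on a 58.4 mm ring; 4 spherical markers on a 50 mm square | dimensions, amplitude, HU tests, distortion |
| spatial_resolution | one 2 mm high-density bead | MTF |
| low_contrast | supra-slice rods at 0.3/0.5/1.0 % contrast (1 % ≡ 10 HU), diameters 2–15 mm | detectability |
| uniformity | homogeneous section | uniformity, noise |

Model 604 differs from 504 only in the Air plug length (33.0 vs 25.0 mm).
Coordinates are right-handed, phantom-centred: X lateral, Y
anterior–posterior, Z axial (the principal motion direction). Only the
air/LDPE/acrylic expected CT numbers are canonical; plug angular
positions, marker spacing, bead placement and target sizes follow common
phantom conventions and are configuration, not algorithm — everything is
overridable through the YAML schema.

Two deliberate departures from the physical phantom, chosen for the
simulator's signal budget and documented as synthetic: the bead is 2 mm
(a real resolution bead is sub-millimetre; at 1 mm voxels and 10 HU noise
a sub-voxel bead's projected PSF would sit below the noise floor), and the
uniformity section is simply background material.

## Simulator

`fourdqa.synth` renders the geometry on a regular HU grid at arbitrary
rigid displacements. Every solid is a Z-axis cylinder or a sphere.
Cylinder occupancy is separable and computed as (in-plane disc fraction) ×
(axial cell/interval overlap): the disc fraction supersamples boundary
pixels `supersampling`² times (interior/exterior pixels are classified
analytically), and the axial overlap is exact. Spheres are supersampled in
3D. Solids are composited back-to-front by occupancy-weighted blending,
blurred with a Gaussian PSF, and clipped to [−1024, 3071] HU. Rendering is
deterministic; noise is added only when a series is assembled.

A binned 4DCT is simulated as: per bin, the mean of noise-free renderings
at the bin's sub-displacements (this models intra-bin motion blur — the
dominant motion artefact for the metrics measured here), plus independent
Gaussian noise seeded per (series, bin) from one root seed, so a fixed
seed gives bit-identical volumes. Slice-by-slice acquisition timing,
helical/cine details, tube-current modulation and reconstruction kernels
are *not* modelled; irregular-breathing binning artefacts are out of
scope.

**Binning.** Phase mode: bin *k* covers cycle fractions [k/n, (k+1)/n),
with phase 0 anchored at peak displacement (a peak-inhale analog;
`phase_offset_fraction` shifts it). Sub-displacements are sampled at
evenly spaced fractions anchored at the bin start, so with one sample per
bin the bins hit the trace extremes exactly. Amplitude mode: the
displacement range along the principal axis is split into n equal
intervals; each bin keeps evenly spaced representatives of its member
samples ordered by displacement, endpoints included, so the outer bins
retain the extremes. Inhale/exhale direction is not separated. For
sampled traces, phase binning uses the time modulo the trace's stated
dominant period.

**Patient-like trace.** Real breathing records are not bundled; the
generator ships a documented synthetic stand-in: two harmonics per axis
with small phase lags plus a slow Z drift, 3D amplitudes (3, 2, 12) mm
peak-to-peak, 5 s period, 30 s record. Expected amplitudes downstream are
always taken from the sampled extremes, never from nominal inputs.

**Defaults** (the study conditions of the bundled checks): 1×1×2 mm
voxels on a 216×216×104 grid; PSF σ = 1.0 mm — chosen no sharper than the
in-plane pitch so the PSF, and hence the MTF-10 % frequency, is resolvable
on the grid (a sharper PSF would push f10 past the measurable band of
1 mm sampling); noise σ = 10 HU, a typical lung-protocol level; 10 bins,
3 intra-bin samples; supersampling 4. Sinusoids are 15 mm peak-to-peak
along Z with periods 3/6/10 s. For a pure sinusoid the phase-binned
geometry depends only on cycle fraction, so the three periods differ only
through their noise realisations — the period is retained as a protocol
label.

## Analysis

**Pose.** Body mask = voxels above the air/background midpoint; largest
connected component; unweighted centroid gives the centre. In-plane
rotation is estimated from the four-marker constellation
(intensity-weighted marker centroids, least-squares rotation), defaulting
to 0° when markers are unresolvable.

**Plug measurement.** Threshold = half level = midpoint of plug and
background nominal HU, so segmentation and FWHM share one config-visible
level. Within a search box around the expected position (clipped to the
phantom body using the chord through the plug, so boxes near the rim or
the phantom ends cannot leak into outside air), voxels beyond the
threshold — above for dense plugs, below for Air — form the region; the
connected component at the expected position is kept (largest-component
selection alone can pick outside air in MinIP images). The centroid is the
unweighted mask centroid, refined per axis to the midpoint of the two
threshold-level crossings of the HU profile: the discrete mask centroid is
quantised at half a voxel, which would alias directly into the amplitude
metric (15 mm = 3.75 slices lands edges exactly on voxel centres).

FWHM: profiles run axis-parallel through the centroid, averaged over the
3×3 perpendicular neighbourhood to stabilise noisy bins; baseline =
background nominal HU, peak = profile extremum; crossings are linearly
interpolated, scanning outward from the extremum, with samples exactly at
the half level counted as inside (ties widen). A profile that never
returns to the half level raises a truncation error naming the axis.

HU statistics use a fixed coaxial interior ROI (70 % diameter, 60 %
length, centred on the measured centroid) rather than the eroded
segmentation region: one-voxel erosion leaves face voxels a single slice
from the half-maximum contour, where PSF and intra-bin blur contaminate
the mean by tens of HU — and differently for stationary vs moving bins,
which would corrupt the consistency deltas. The fixed interior ROI stays
in the flat core under 15 mm motion while holding ~460 voxels, giving
sub-HU precision on the plug mean.

**Known estimator bias.** The half-maximum contour of a blurred convex
object sits inside the true edge by ≈ σ²κ/2 (curvature κ = 2/d in-plane),
so a Ø 12.3 mm plug at σ ≈ 1 mm reads ~0.2 mm low in X/Y — manual
contour-based measurements of the physical phantom show the same
sub-nominal readings. Consistency tests difference this bias away.

**MTF.** The bead ROI (±10 mm in-plane, ±6 mm axially) is
background-subtracted by the ROI-shell median and summed along Z — the
projected PSF, which makes the in-plane estimate invariant to axial
motion blur. The zero-padded 2D DFT is phase-corrected to the PSF centroid
so the signal is real across each frequency ring; ring-averaging the
*complex* spectrum then averages noise down (averaging magnitudes instead
leaves a Rayleigh rectification bias of order 0.1 that can mask the 10 %
crossing). The radial profile is normalised at DC, divided by the analytic
uniform-sphere transform of the bead diameter (clamped at its 80 %-Nyquist
value to avoid noise blow-up), and the 10 % crossing is linearly
interpolated, reported in lp/cm (= 10 × cycles/mm). If the modulation
never falls to 0.10 inside the capped band, the cap frequency is returned
with a saturation flag rather than an extrapolated number. Against the
Gaussian closed form f10 = √(ln 10 / 2π²σ²) the estimator is within 1 %
for σ ∈ [0.3, 1.5] mm when the pixel pitch resolves the crossing
(f10 ≲ 0.8 × Nyquist; 0.25 mm pixels cover the whole range — at 1 mm
sampling the crossing is physically unmeasurable below σ ≈ 0.85 mm and is
flagged as saturated).

**Low contrast.** A target is detectable when
|mean(disc) − mean(annulus)| / sd(annulus) ≥ 2.0 (configurable). This
deterministic, auditable criterion replaces human reading; note it uses
the per-voxel background sd, so at 10 HU noise no 1 % (10 HU) target
clears the default threshold — the metric is meaningful for low-noise
(average CT) images and for tracking change, not as an absolute observer
model.

**Uniformity / noise.** Central ROI = 40 % of module diameter; peripheral
ROIs = 10 % diameter at 80 % radius at 12/3/6/9 o'clock (the peripheral
sizes are conventions, configurable); all on a ±5 mm slice band at the
module centre; sample sd with ddof 1.

**CNR.** "(μ_polystyrene − μ_LDPE) over the combined sd" with the
quadrature sum √(σ₁²+σ₂²) — the conventional combination of two
independent ROI noises; the literal arithmetic sum is available via
`denominator="sum"`. Noiseless input returns an infinite sentinel.

**Derived images.** Average CT = voxelwise mean (noise ↓ as 1/√N);
MIP/MinIP = voxelwise max/min; MIP ≥ average ≥ MinIP holds voxelwise by
construction. Projection dimension checks pass the amplitude as extra
search/profile margin. The measured envelope reads ~0.1–0.5 mm short of
stationary-z + amplitude because the envelope flanks are built from
intra-bin-averaged extreme bins — the same underestimation direction seen
on physical measurements.

**Amplitude.** Reported per axis as the centroid extent per plug (Teflon
and Air separately); the principal-axis component is the headline value
for 1D traces. Expected value for sampled traces is the max − min of the
trace samples, taken literally as the known platform input.

**Reporting.** `run_qa` degrades failures to per-test `error` status and
always produces the report; the test list is fixed (amplitude, surrogate
dimensions, projections, HU consistency, spatial resolution, CNR, noise,
uniformity), each appearing exactly once with pass/fail/error/skipped.
Default tolerances (±1 mm spatial, 2 HU) are labelled initial action
levels; IQ-delta tests ship without tolerances and report `skipped` until
a site configures its own from longitudinal baselines via
`compare_to_baseline`.

## Validation oracle

`fourdqa.contour_oracle` re-measures plugs the way a manual contour
workflow would: explicit marching-squares iso-contours at the same half
level, bounding extents on axial and coronal planes through the plug,
centre-of-mass centroids. It shares no profile/FWHM code with the
pipeline and serves as the independent cross-check; on simulated 4DCTs
the two agree within 0.3 mm.

## What the tests show — and don't

The commissioning suite (`tests/test_acceptance.py`,
`scripts/acceptance.py`) demonstrates that the *analysis chain* recovers
known ground truth under the simulator's conditions: ±1 mm spatial
integrity and ≤ 2 HU consistency on 15 mm sinusoids with realistic blur
and noise, exact amplitude recovery in the noiseless limit,
nominal-dimension recovery within half a voxel/slice, oracle agreement
within 1 mm, the MTF closed form within 2 %, and phase/amplitude binning
equivalence including a 3D trace. It does *not* validate scanner physics
the simulator omits (reconstruction kernels, binning artefacts from
irregular breathing, scatter, vendor phase-tag conventions beyond the
documented description tokens), and absolute image-quality values are
protocol-dependent by design — on real data the intended use is
consistency against a site baseline, not comparison to the simulator's
numbers.

## Problem sizes

Bundled studies run on the default 216×216×104 grid: one simulated 4DCT
(17 unique renders after displacement deduplication, caching in-plane
occupancy for 1D motion) takes a few seconds; the full three-trace ×
three-seed study about a minute on one CPU. Unit tests use a miniature
60 mm phantom on a 72×72×36 grid with a proportionally sharper 0.6 mm PSF
(its 12 mm plugs keep the same blur-to-size ratio as the full phantom's
25 mm plugs at 1 mm).

## Known limitations

- Rotation handling is in-plane only and the simulator never renders a
  rotated phantom; the 2° pose contract is untested against real tilt.
- Segmentation thresholds are absolute-HU-based; a global calibration
  shift comparable to a low-contrast plug's contrast (e.g. 25 HU vs
  polystyrene's 35) perturbs that plug's mask.
- The MTF noise floor still biases the curve slightly upward at high
  frequency; only the 10 % crossing inside 80 % Nyquist is reported.
- Amplitude binning ignores inhale/exhale direction (one bin per
  amplitude interval).
- HTML report output is not implemented; JSON is canonical, CSV flat.
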