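"""Shared fixtures: a compact phantom + coarse grid for fast unit tests,
and session-scoped simulated datasets reused across test modules."""

import numpy as np
import pytest

from fourdqa.geometry import (
    BeadSpec,
    LowContrastTarget,
    MarkerSpec,
    MaterialSpec,
    ModuleSpec,
    PhantomGeometry,
    PlugSpec,
    builtin_geometry,
)
from fourdqa.synth import AcquisitionSpec, BinningSpec, MotionTrace, simulate_4dct


def _mat(name, hu):
    return MaterialSpec(name, hu)


def make_small_geometry() -> PhantomGeometry:
    """A miniature phantom (60 mm diameter) with the same module roster as
    the builtin models, sized for sub-second rendering in unit tests."""
    ring = 18.0
    d, ln = 8.0, 12.0
    plugs = [
        PlugSpec("teflon", _mat("teflon", 990), d, ln, ring, 270.0,
                 roles=frozenset({"motion_surrogate"})),
        PlugSpec("air", _mat("air", -1000), d, ln, ring, 90.0,
                 roles=frozenset({"motion_surrogate", "hu_constancy"})),
        PlugSpec("ldpe", _mat("ldpe", -100), d, ln, ring, 210.0,
                 roles=frozenset({"hu_constancy", "cnr_pair_member"})),
        PlugSpec("polystyrene", _mat("polystyrene", -35), d, ln, ring, 330.0,
                 roles=frozenset({"cnr_pair_member"})),
        PlugSpec("acrylic", _mat("acrylic", 120), d, ln, ring, 30.0,
                 roles=frozenset({"hu_constancy"})),
    ]
    markers = tuple(
        MarkerSpec(sx * 5.0, sy * 5.0, 0.0, 2.5, _mat("bead", 3000))
        for sx, sy in ((1, 1), (-1, 1), (-1, -1), (1, -1))
    )
    modules = (
        ModuleSpec("sensitometry", -14.0, 14.0, plugs=tuple(plugs),
                   markers=markers, marker_nominal_spacing_mm=10.0),
        ModuleSpec("spatial_resolution", -2.0, 9.0,
                   bead=BeadSpec(0.0, 10.0, 0.0, 2.0, _mat("bead", 3000))),
        ModuleSpec("low_contrast", 7.0, 8.0, low_contrast_targets=(
            LowContrastTarget(9.0, 1.0, 14.0, 90.0),
            LowContrastTarget(5.0, 1.0, 14.0, 210.0),
            LowContrastTarget(3.0, 1.0, 14.0, 330.0),
        )),
        ModuleSpec("uniformity", 18.0, 14.0),
    )
    return PhantomGeometry(
        model=504, outer_diameter_mm=60.0,
        background=_mat("water", 0), air=_mat("air", -1000),
        modules=modules, body_z_range_mm=(-27.0, 27.0),
    )


@pytest.fixture(scope="session")
def small_geometry():
    return make_small_geometry()


@pytest.fixture(scope="session")
def small_acq():
    return AcquisitionSpec(grid_shape=(72, 72, 36), noise_sigma_hu=0.0,
                           psf_sigma_mm=0.6)


@pytest.fixture(scope="session")
def small_acq_noisy():
    return AcquisitionSpec(grid_shape=(72, 72, 36), noise_sigma_hu=10.0,
                           psf_sigma_mm=0.6, seed=7)


@pytest.fixture(scope="session")
def small_trace():
    return MotionTrace(peak_to_peak_mm=(0.0, 0.0, 6.0), period_s=6.0)


@pytest.fixture(scope="session")
def small_sim(small_geometry, small_trace, small_acq_noisy):
    """Noisy 10-bin phase-binned small-phantom 4DCT + stationary."""
    return simulate_4dct(small_geometry, small_trace, BinningSpec(),
                         small_acq_noisy)


@pytest.fixture(scope="session")
def small_sim_noiseless(small_geometry, small_trace, small_acq):
    return simulate_4dct(small_geometry, small_trace,
                         BinningSpec(intra_bin_samples=1), small_acq)


@pytest.fixture(scope="session")
def geometry_504():
    return builtin_geometry(504)


@pytest.fixture(scope="session")
def geometry_604():
    return builtin_geometry(604)


@pytest.fixture(scope="session")
def full_sim_504(geometry_504):
    """Full-size default simulation (15 mm p-p, 6 s, 10 phase bins, seed 1)."""
    trace = MotionTrace(peak_to_peak_mm=(0.0, 0.0, 15.0), period_s=6.0)
    stationary, series, truth = simulate_4dct(
        geometry_504, trace, BinningSpec(), AcquisitionSpec(seed=1))
    return stationary, series, truth, trace
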