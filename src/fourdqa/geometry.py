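"""Declarative geometry of the Catphan-style image-quality phantom.

The phantom is a solid cylinder of near-water-equivalent material containing
four axially stacked test modules:

* ``sensitometry`` -- a ring of material plugs of known nominal HU (Teflon,
  Air, LDPE, polystyrene, acrylic, Delrin, PMP) plus four point markers at a
  known pairwise spacing, used for HU constancy/consistency, plug
  dimensioning, motion-amplitude surrogacy and geometric distortion;
* ``spatial_resolution`` -- a small high-density bead whose image samples the
  scanner point-spread function (MTF measurement);
* ``low_contrast`` -- supra-slice rod targets at 0.3/0.5/1.0 % contrast;
* ``uniformity`` -- a homogeneous section for uniformity and noise ROIs.

Coordinates are right handed and phantom centred: X lateral, Y
anterior-posterior, Z axial (the table / principal motion direction).  All
lengths are millimetres, all attenuation values Hounsfield units.

Geometry is configuration, not algorithm: the builtin models 504 and 604
carry the manufacturer-nominal plug dimensions, and everything is
overridable through a YAML config file (see :func:`load_geometry`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

HU_MIN = -1024
HU_MAX = 3071

#: one percent low-contrast corresponds to 10 HU on the CT scale
HU_PER_PERCENT_CONTRAST = 10.0


class GeometryError(ValueError):
    """A phantom-geometry config violates the schema or an invariant."""


@dataclass(frozen=True)
class MaterialSpec:
    """A material with its nominal CT number."""

    name: str
    nominal_hu: int

    def __post_init__(self) -> None:
        if not (HU_MIN <= self.nominal_hu <= HU_MAX):
            raise GeometryError(
                f"material {self.name!r}: nominal_hu {self.nominal_hu} outside "
                f"[{HU_MIN}, {HU_MAX}]"
            )


@dataclass(frozen=True)
class PlugSpec:
    """A cylindrical sensitometry plug.

    Position is (radial offset mm, angle degrees, z offset mm) relative to
    the *module* centre; the plug axis is parallel to Z.
    """

    plug_id: str
    material: MaterialSpec
    diameter_mm: float
    length_mm: float
    r_mm: float
    theta_deg: float
    z_mm: float = 0.0
    roles: frozenset[str] = frozenset()

    _ALLOWED_ROLES = frozenset({"motion_surrogate", "hu_constancy", "cnr_pair_member"})

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise GeometryError(f"plug {self.plug_id!r}: diameter_mm must be > 0")
        if self.length_mm <= 0:
            raise GeometryError(f"plug {self.plug_id!r}: length_mm must be > 0")
        bad = set(self.roles) - self._ALLOWED_ROLES
        if bad:
            raise GeometryError(f"plug {self.plug_id!r}: unknown roles {sorted(bad)}")

    def center_xy(self) -> tuple[float, float]:
        th = math.radians(self.theta_deg)
        return self.r_mm * math.cos(th), self.r_mm * math.sin(th)


@dataclass(frozen=True)
class BeadSpec:
    """High-density bead for PSF/MTF sampling; z is module-relative."""

    x_mm: float
    y_mm: float
    z_mm: float
    diameter_mm: float
    material: MaterialSpec


@dataclass(frozen=True)
class MarkerSpec:
    """Spherical spatial target for geometric distortion; z is module-relative."""

    x_mm: float
    y_mm: float
    z_mm: float
    diameter_mm: float
    material: MaterialSpec


@dataclass(frozen=True)
class LowContrastTarget:
    """Supra-slice low-contrast rod: (diameter, nominal contrast %, position)."""

    diameter_mm: float
    contrast_percent: float
    r_mm: float
    theta_deg: float

    def center_xy(self) -> tuple[float, float]:
        th = math.radians(self.theta_deg)
        return self.r_mm * math.cos(th), self.r_mm * math.sin(th)


MODULE_NAMES = ("sensitometry", "uniformity", "spatial_resolution", "low_contrast")


@dataclass(frozen=True)
class ModuleSpec:
    name: str
    z_offset_mm: float
    thickness_mm: float
    plugs: tuple[PlugSpec, ...] = ()
    bead: BeadSpec | None = None
    markers: tuple[MarkerSpec, ...] = ()
    marker_nominal_spacing_mm: float | None = None
    low_contrast_targets: tuple[LowContrastTarget, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in MODULE_NAMES:
            raise GeometryError(f"unknown module name {self.name!r}")
        if self.bead is not None and self.name != "spatial_resolution":
            raise GeometryError(
                f"module {self.name!r}: bead allowed only in spatial_resolution"
            )
        if self.thickness_mm <= 0:
            raise GeometryError(f"module {self.name!r}: thickness_mm must be > 0")

    @property
    def z_range(self) -> tuple[float, float]:
        h = self.thickness_mm / 2.0
        return self.z_offset_mm - h, self.z_offset_mm + h


@dataclass(frozen=True)
class PhantomGeometry:
    model: int
    outer_diameter_mm: float
    background: MaterialSpec
    air: MaterialSpec
    modules: tuple[ModuleSpec, ...]
    body_z_range_mm: tuple[float, float] = (-90.0, 90.0)

    def __post_init__(self) -> None:
        if self.outer_diameter_mm <= 0:
            raise GeometryError("outer_diameter_mm must be > 0")
        counts = {n: sum(1 for m in self.modules if m.name == n) for n in MODULE_NAMES}
        if counts["sensitometry"] != 1 or counts["uniformity"] != 1:
            raise GeometryError(
                "geometry must contain exactly one sensitometry and one "
                f"uniformity module (got {counts})"
            )
        # module z-ranges must not overlap
        ranges = sorted((m.z_range, m.name) for m in self.modules)
        for (r1, n1), (r2, n2) in zip(ranges, ranges[1:]):
            if r2[0] < r1[1] - 1e-9:
                raise GeometryError(f"modules {n1!r} and {n2!r} overlap in z")
        radius = self.outer_diameter_mm / 2.0
        names: set[str] = set()
        ids: set[str] = set()
        for mod in self.modules:
            lo, hi = mod.z_range
            if lo < self.body_z_range_mm[0] - 1e-9 or hi > self.body_z_range_mm[1] + 1e-9:
                raise GeometryError(f"module {mod.name!r} extends beyond the phantom body")
            for plug in mod.plugs:
                if plug.r_mm + plug.diameter_mm / 2.0 > radius + 1e-9:
                    raise GeometryError(
                        f"plug {plug.plug_id!r}: radial offset {plug.r_mm} + radius "
                        f"{plug.diameter_mm / 2} exceeds phantom radius {radius}"
                    )
                if plug.plug_id in ids:
                    raise GeometryError(f"duplicate plug id {plug.plug_id!r}")
                ids.add(plug.plug_id)
                names.add(plug.material.name)
            for i, a in enumerate(mod.plugs):
                for b in mod.plugs[i + 1:]:
                    ax, ay = a.center_xy()
                    bx, by = b.center_xy()
                    if ((ax - bx) ** 2 + (ay - by) ** 2) ** 0.5 < \
                            (a.diameter_mm + b.diameter_mm) / 2.0 - 1e-9:
                        raise GeometryError(
                            f"plugs {a.plug_id!r} and {b.plug_id!r} overlap in-plane"
                        )
        names |= {self.background.name, self.air.name}
        # material names unique per nominal HU: same name must mean same HU
        seen: dict[str, int] = {}
        for mat in self.materials().values():
            if mat.name in seen and seen[mat.name] != mat.nominal_hu:
                raise GeometryError(f"material {mat.name!r} defined with two HU values")
            seen[mat.name] = mat.nominal_hu

    # -- lookups ---------------------------------------------------------

    def module(self, name: str) -> ModuleSpec:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def sensitometry(self) -> ModuleSpec:
        return self.module("sensitometry")

    @property
    def uniformity_module(self) -> ModuleSpec:
        return self.module("uniformity")

    def plugs(self) -> tuple[PlugSpec, ...]:
        return tuple(p for m in self.modules for p in m.plugs)

    def plug(self, plug_id: str) -> PlugSpec:
        for p in self.plugs():
            if p.plug_id == plug_id:
                return p
        raise KeyError(plug_id)

    def plug_module(self, plug_id: str) -> ModuleSpec:
        for m in self.modules:
            if any(p.plug_id == plug_id for p in m.plugs):
                return m
        raise KeyError(plug_id)

    def plug_center(self, plug: PlugSpec | str) -> tuple[float, float, float]:
        """Plug centre in phantom coordinates (mm)."""
        if isinstance(plug, str):
            plug = self.plug(plug)
        mod = self.plug_module(plug.plug_id)
        x, y = plug.center_xy()
        return x, y, mod.z_offset_mm + plug.z_mm

    def surrogate_plugs(self) -> tuple[PlugSpec, ...]:
        return tuple(p for p in self.plugs() if "motion_surrogate" in p.roles)

    def materials(self) -> dict[str, MaterialSpec]:
        mats = {self.background.name: self.background, self.air.name: self.air}
        for m in self.modules:
            for p in m.plugs:
                mats[p.material.name] = p.material
            if m.bead is not None:
                mats[m.bead.material.name] = m.bead.material
            for mk in m.markers:
                mats[mk.material.name] = mk.material
        return mats


# ---------------------------------------------------------------------------
# builtin geometries

#: default nominal HU per material; only air/LDPE/acrylic carry the canonical
#: expected CT numbers used by the HU-constancy test, the rest are
#: conventional defaults and overridable via config.
DEFAULT_MATERIAL_HU = {
    "air": -1000,
    "ldpe": -100,
    "acrylic": 120,
    "teflon": 990,
    "polystyrene": -35,
    "delrin": 340,
    "pmp": -200,
    "water": 0,
    "bead": 3000,
}

_SENSITOMETRY_RING_MM = 58.4
_PLUG_DIAMETER_MM = 12.3
_PLUG_LENGTH_MM = 25.0
_PLUG_ANGLES = {
    # every 30 deg on the sensitometry ring; assignment is conventional
    "air": 90.0,
    "delrin": 30.0,
    "pmp": 150.0,
    "ldpe": 210.0,
    "teflon": 270.0,  # diametrically opposite Air
    "polystyrene": 300.0,
    "acrylic": 330.0,
}
_MARKER_SPACING_MM = 50.0
_LOW_CONTRAST_DIAMETERS_MM = (15.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0)


def _material(name: str) -> MaterialSpec:
    return MaterialSpec(name, DEFAULT_MATERIAL_HU[name])


def _builtin_modules(model: int) -> tuple[ModuleSpec, ...]:
    plugs = []
    for mat_name, angle in _PLUG_ANGLES.items():
        length = _PLUG_LENGTH_MM
        if model == 604 and mat_name == "air":
            length = 33.0  # model 604 carries a longer Air plug
        roles = set()
        if mat_name in ("teflon", "air"):
            roles.add("motion_surrogate")
        if mat_name in ("air", "ldpe", "acrylic"):
            roles.add("hu_constancy")
        if mat_name in ("polystyrene", "ldpe"):
            roles.add("cnr_pair_member")
        plugs.append(
            PlugSpec(
                plug_id=mat_name,
                material=_material(mat_name),
                diameter_mm=_PLUG_DIAMETER_MM,
                length_mm=length,
                r_mm=_SENSITOMETRY_RING_MM,
                theta_deg=angle,
                roles=frozenset(roles),
            )
        )
    half = _MARKER_SPACING_MM / 2.0
    markers = tuple(
        MarkerSpec(sx * half, sy * half, 0.0, 3.0, _material("bead"))
        for sx, sy in ((1, 1), (-1, 1), (-1, -1), (1, -1))
    )
    lc_targets = []
    n = len(_LOW_CONTRAST_DIAMETERS_MM)
    for i, d in enumerate(_LOW_CONTRAST_DIAMETERS_MM):
        lc_targets.append(LowContrastTarget(d, 1.0, 50.0, 90.0 + 360.0 * i / n))
    for i, d in enumerate((15.0, 9.0)):
        lc_targets.append(LowContrastTarget(d, 0.5, 25.0, 90.0 + 120.0 * i))
        lc_targets.append(LowContrastTarget(d, 0.3, 25.0, 270.0 + 120.0 * i))
    return (
        ModuleSpec(
            name="sensitometry",
            z_offset_mm=-60.0,
            thickness_mm=40.0,
            plugs=tuple(plugs),
            markers=markers,
            marker_nominal_spacing_mm=_MARKER_SPACING_MM,
        ),
        ModuleSpec(
            name="spatial_resolution",
            z_offset_mm=-25.0,
            thickness_mm=30.0,
            # 2 mm bead: large enough that the projected PSF signal clears
            # the image noise floor, small enough for the sphere-aperture
            # correction to stay well conditioned in the measurable band
            bead=BeadSpec(0.0, 25.0, 0.0, 2.0, _material("bead")),
        ),
        ModuleSpec(
            name="low_contrast",
            z_offset_mm=10.0,
            thickness_mm=40.0,
            low_contrast_targets=tuple(lc_targets),
        ),
        ModuleSpec(name="uniformity", z_offset_mm=65.0, thickness_mm=50.0),
    )


def builtin_geometry(model: int) -> PhantomGeometry:
    """Packaged phantom geometry for model 504 or 604.

    Both models share the sensitometry layout with manufacturer-nominal plug
    dimensions (12.3 mm diameter, 25.0 mm length); model 604's Air plug is
    33.0 mm long.  Pure function: repeated calls return equal geometries.
    """
    if model not in (504, 604):
        raise ValueError(f"unknown phantom model {model!r}; supported: 504, 604")
    return PhantomGeometry(
        model=model,
        outer_diameter_mm=200.0,
        background=_material("water"),
        air=_material("air"),
        modules=_builtin_modules(model),
    )


# ---------------------------------------------------------------------------
# config round-trip


def geometry_to_dict(geom: PhantomGeometry) -> dict:
    d = asdict(geom)
    # frozensets are not YAML friendly
    for mod in d["modules"]:
        for plug in mod["plugs"]:
            plug["roles"] = sorted(plug["roles"])
    d["body_z_range_mm"] = list(d["body_z_range_mm"])
    return d


def save_geometry(geom: PhantomGeometry, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(geometry_to_dict(geom), sort_keys=False))


def geometry_from_dict(d: dict) -> PhantomGeometry:
    try:
        def mat(md: dict) -> MaterialSpec:
            return MaterialSpec(md["name"], int(md["nominal_hu"]))

        modules = []
        for md in d["modules"]:
            plugs = tuple(
                PlugSpec(
                    plug_id=p["plug_id"],
                    material=mat(p["material"]),
                    diameter_mm=float(p["diameter_mm"]),
                    length_mm=float(p["length_mm"]),
                    r_mm=float(p["r_mm"]),
                    theta_deg=float(p["theta_deg"]),
                    z_mm=float(p.get("z_mm", 0.0)),
                    roles=frozenset(p.get("roles", ())),
                )
                for p in md.get("plugs", ())
            )
            bead = md.get("bead")
            if bead is not None:
                bead = BeadSpec(
                    bead["x_mm"], bead["y_mm"], bead["z_mm"],
                    bead["diameter_mm"], mat(bead["material"]),
                )
            markers = tuple(
                MarkerSpec(m["x_mm"], m["y_mm"], m["z_mm"], m["diameter_mm"],
                           mat(m["material"]))
                for m in md.get("markers", ())
            )
            targets = tuple(
                LowContrastTarget(t["diameter_mm"], t["contrast_percent"],
                                  t["r_mm"], t["theta_deg"])
                for t in md.get("low_contrast_targets", ())
            )
            modules.append(
                ModuleSpec(
                    name=md["name"],
                    z_offset_mm=float(md["z_offset_mm"]),
                    thickness_mm=float(md["thickness_mm"]),
                    plugs=plugs,
                    bead=bead,
                    markers=markers,
                    marker_nominal_spacing_mm=md.get("marker_nominal_spacing_mm"),
                    low_contrast_targets=targets,
                )
            )
        return PhantomGeometry(
            model=int(d["model"]),
            outer_diameter_mm=float(d["outer_diameter_mm"]),
            background=mat(d["background"]),
            air=mat(d["air"]),
            modules=tuple(modules),
            body_z_range_mm=tuple(d.get("body_z_range_mm", (-90.0, 90.0))),
        )
    except KeyError as exc:
        raise GeometryError(f"geometry config: missing field {exc}") from exc
    except (TypeError, ValueError) as exc:
        if isinstance(exc, GeometryError):
            raise
        raise GeometryError(f"geometry config: {exc}") from exc


def load_geometry(path: str | Path) -> PhantomGeometry:
    """Load and validate a phantom geometry from a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise GeometryError(f"{path}: expected a mapping at top level")
    return geometry_from_dict(data)
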