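"""CT volume containers and DICOM series input/output.

Internal axis order is fixed as ``voxels[ix, iy, iz]`` with Z the slice
axis; DICOM row/column/slice ordering is normalised on read so every metric
downstream can assume axial slices on a regular grid.  HU round-trips
losslessly for integer HU in [-1024, 3071] (stored as signed 16-bit with
rescale slope 1 / intercept 0).

Bin roles are encoded in the DICOM series description with a documented
token convention (``stationary``, ``phase 30%``, ``amplitude bin 3``,
``average``, ``MIP``, ``MinIP``); an optional ``manifest.json`` beside the
files overrides the convention because vendor 4DCT phase tags differ.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

HU_MIN = -1024
HU_MAX = 3071
_SPACING_TOL = 0.01  # mm; max allowed slice-spacing jitter within a series


class FormatError(ValueError):
    """Inconsistent or malformed CT series."""


class EmptyInputError(FormatError):
    """No CT images found under the given path."""


@dataclass
class CTVolume:
    """A 3D HU grid with geometry metadata.

    ``voxels[ix, iy, iz]`` in HU; ``origin_mm`` is the world position of the
    centre of voxel (0, 0, 0); world = origin + index * spacing (identity
    orientation, axial slices).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    series_id: str = ""
    bin_label: str = "stationary"

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise FormatError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise FormatError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Nearest voxel index of a world point (clipped to bounds)."""
        idx = []
        for ax in range(3):
            i = round((point_mm[ax] - self.origin_mm[ax]) / self.spacing_mm[ax])
            idx.append(int(np.clip(i, 0, self.shape[ax] - 1)))
        return tuple(idx)

    def with_voxels(self, voxels: np.ndarray, bin_label: str | None = None) -> "CTVolume":
        return replace(
            self, voxels=voxels,
            bin_label=self.bin_label if bin_label is None else bin_label,
        )

    def same_grid(self, other: "CTVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=1e-6)
            and np.allclose(self.origin_mm, other.origin_mm, atol=1e-6)
        )


@dataclass
class Phase4DSeries:
    """Ordered binned 4DCT volumes sharing one grid."""

    volumes: list[CTVolume]
    binning_mode: str = "phase"  # "phase" | "amplitude"

    def __post_init__(self) -> None:
        if not self.volumes:
            raise FormatError("Phase4DSeries requires at least one volume")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if not v.same_grid(ref):
                raise FormatError("4D series member volumes must share grid/spacing/origin")
        labels = [v.bin_label for v in self.volumes]
        if len(set(labels)) != len(labels):
            raise FormatError(f"duplicate bin labels in 4D series: {labels}")
        self.volumes = sorted(self.volumes, key=lambda v: _label_sort_key(v.bin_label))

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self):
        return iter(self.volumes)

    @property
    def n_bins(self) -> int:
        return len(self.volumes)


# ---------------------------------------------------------------------------
# bin-label convention

_PHASE_RE = re.compile(r"phase\s*(\d+)\s*%", re.IGNORECASE)
_AMP_RE = re.compile(r"amplitude\s*bin\s*(\d+)", re.IGNORECASE)
_DERIVED = {"average", "mip", "minip"}


def phase_label(k: int, n_bins: int) -> str:
    return f"phase {round(100 * k / n_bins):02d}%"


def amplitude_label(k: int) -> str:
    return f"amplitude bin {k}"


def classify_label(description: str) -> tuple[str, str]:
    """Map a series description to (role, canonical label).

    role is one of 'stationary', 'bin', 'derived', 'unknown'.
    """
    desc = description.strip().lower()
    if "stationary" in desc:
        return "stationary", "stationary"
    m = _PHASE_RE.search(desc)
    if m:
        return "bin", f"phase {int(m.group(1)):02d}%"
    m = _AMP_RE.search(desc)
    if m:
        return "bin", f"amplitude bin {int(m.group(1))}"
    for token in _DERIVED:
        if token in desc:
            return "derived", {"mip": "MIP", "minip": "MinIP"}.get(token, token)
    return "unknown", description.strip()


def _label_sort_key(label: str):
    m = _PHASE_RE.search(label)
    if m:
        return (0, int(m.group(1)))
    m = _AMP_RE.search(label)
    if m:
        return (1, int(m.group(1)))
    return (2, label)


# ---------------------------------------------------------------------------
# writing


def write_volume(volume: CTVolume, out_dir: str | Path, series_description: str,
                 series_uid: str | None = None) -> list[Path]:
    """Write one volume as a DICOM CT image series, one file per slice."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    sx, sy, sz = volume.spacing_mm
    vox = np.clip(np.rint(volume.voxels), HU_MIN, HU_MAX).astype(np.int16)
    nx, ny, nz = volume.shape
    paths = []
    for iz in range(nz):
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.SeriesDescription = series_description
        ds.PatientName = "QA^Phantom"
        ds.PatientID = "4DCT-QA"
        ds.InstanceNumber = iz + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        z = volume.origin_mm[2] + iz * sz
        ds.ImagePositionPatient = [volume.origin_mm[0], volume.origin_mm[1], z]
        ds.SliceThickness = sz
        ds.PixelSpacing = [sy, sx]  # DICOM order: row (y), column (x)
        ds.Rows = ny
        ds.Columns = nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.RescaleType = "HU"
        # rows = y, columns = x
        ds.PixelData = np.ascontiguousarray(vox[:, :, iz].T).tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        path = out_dir / f"{series_description.replace(' ', '_').replace('%','pct')}_{iz:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_series(stationary: CTVolume | None,
                 series: Phase4DSeries | None,
                 out_dir: str | Path,
                 derived: dict[str, CTVolume] | None = None) -> None:
    """Write a QA dataset tree: stationary + per-bin + derived volumes."""
    out_dir = Path(out_dir)
    manifest = {"series": []}
    if stationary is not None:
        write_volume(stationary, out_dir / "stationary", "stationary")
        manifest["series"].append({"description": "stationary", "role": "stationary"})
    if series is not None:
        for vol in series:
            desc = vol.bin_label
            write_volume(vol, out_dir / desc.replace(" ", "_").replace("%", "pct"), desc)
            manifest["series"].append(
                {"description": desc, "role": "bin", "binning_mode": series.binning_mode}
            )
    for label, vol in (derived or {}).items():
        write_volume(vol, out_dir / label, label)
        manifest["series"].append({"description": label, "role": "derived"})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


# ---------------------------------------------------------------------------
# reading


def _read_one_series(datasets: list[pydicom.Dataset]) -> CTVolume:
    def zpos(ds):
        return float(ds.ImagePositionPatient[2])

    datasets = sorted(datasets, key=zpos)
    zs = np.array([zpos(ds) for ds in datasets])
    if len(zs) > 1:
        dz = np.diff(zs)
        if dz.max() - dz.min() > _SPACING_TOL:
            gap = int(np.argmax(dz))
            raise FormatError(
                "non-uniform slice spacing in series "
                f"{datasets[0].SeriesInstanceUID}: z-gap of {dz[gap]:.3f} mm "
                f"between z={zs[gap]:.3f} and z={zs[gap + 1]:.3f}"
            )
        sz = float(dz.mean())
    else:
        sz = float(getattr(datasets[0], "SliceThickness", 1.0))
    ref = datasets[0]
    sy, sx = (float(v) for v in ref.PixelSpacing)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # stored as (row=y, col=x) per slice -> transpose to (x, y)
    vox = np.stack([s.T for s in slices], axis=2)
    origin = (
        float(ref.ImagePositionPatient[0]),
        float(ref.ImagePositionPatient[1]),
        float(zs[0]),
    )
    return CTVolume(
        voxels=vox,
        spacing_mm=(sx, sy, sz),
        origin_mm=origin,
        series_id=str(ref.SeriesInstanceUID),
        bin_label=str(getattr(ref, "SeriesDescription", "")),
    )


def read_series_tree(path: str | Path):
    """Read a QA dataset tree of DICOM CT series.

    Returns ``(stationary, series, derived)`` where ``stationary`` is a
    :class:`CTVolume` or None, ``series`` a :class:`Phase4DSeries` or None,
    and ``derived`` a dict of label -> volume.  Grouping is by
    SeriesInstanceUID; role classification uses the series-description token
    convention, overridable by a ``manifest.json``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    groups: dict[str, list[pydicom.Dataset]] = {}
    for f in sorted(path.rglob("*")):
        if not f.is_file() or f.name == "manifest.json":
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if getattr(ds, "Modality", "CT") != "CT" or not hasattr(ds, "PixelData"):
            continue
        groups.setdefault(str(ds.SeriesInstanceUID), []).append(ds)
    if not groups:
        raise EmptyInputError(f"no CT images found under {path}")

    manifest: dict[str, dict] = {}
    binning_mode = "phase"
    mpath = path / "manifest.json"
    if mpath.exists():
        data = json.loads(mpath.read_text())
        for entry in data.get("series", []):
            manifest[entry["description"]] = entry
            if entry.get("binning_mode"):
                binning_mode = entry["binning_mode"]

    stationary = None
    bins: list[CTVolume] = []
    derived: dict[str, CTVolume] = {}
    for uid, dsets in groups.items():
        vol = _read_one_series(dsets)
        desc = vol.bin_label
        entry = manifest.get(desc)
        if entry is not None:
            role = entry["role"]
            label = entry.get("label", classify_label(desc)[1])
        else:
            role, label = classify_label(desc)
        vol.bin_label = label
        if role == "stationary":
            if stationary is not None:
                raise FormatError("multiple stationary series found")
            stationary = vol
        elif role == "bin":
            bins.append(vol)
        elif role == "derived":
            derived[label] = vol
        # unknown series: single unlabelled series counts as stationary
        elif len(groups) == 1:
            vol.bin_label = "stationary"
            stationary = vol

    series = None
    if bins:
        labels = [v.bin_label for v in bins]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise FormatError(f"duplicate bin labels across series: {dupes}")
        mode = "amplitude" if any("amplitude" in l for l in labels) else binning_mode
        series = Phase4DSeries(bins, binning_mode=mode)
    return stationary, series, derived
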