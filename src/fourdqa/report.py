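"""End-to-end QA orchestration, tolerance evaluation and report output.

:func:`run_qa` executes the full analysis: localisation of every volume,
spatial-integrity tests against the stationary baseline, derived images
(average CT, MIP, MinIP), the image-quality suite on the stationary scan,
every bin and the average CT, and per-test pass/fail against a
:class:`ToleranceSet`.  Partial failures degrade to per-test ``error``
status; the report is always produced.

Default tolerances are seeded from observed multi-scanner behaviour
(plug-dimension, amplitude and projection deltas within +/-1 mm; per-plug
HU deltas within 2 HU) and are labelled *initial*: sites are expected to
derive their own action limits from longitudinal baselines.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dicomio import CTVolume, Phase4DSeries, read_series_tree
from .geometry import PhantomGeometry
from .localize import locate_phantom, detect_plug, measure_plug_dimensions
from .quality import IQMetrics, iq_suite, iq_summary, hu_consistency_per_plug
from .spatial import (
    PROJECTION_PAIRS,
    average_ct,
    dimension_consistency,
    intensity_projection,
    motion_amplitude,
    projection_dimension_check,
)
from .synth import MotionTrace


class BaselineMissingError(RuntimeError):
    """The stationary reference series is required and was not found."""


class ComparabilityError(RuntimeError):
    """Two reports cannot be compared (different geometry or test lists)."""


@dataclass
class ToleranceSet:
    """Per-test tolerances (all > 0); ``None`` disables a check."""

    dimension_delta_mm: float = 1.0
    amplitude_delta_mm: float = 1.0
    projection_delta_mm: float = 1.0
    hu_consistency_hu: float = 2.0
    iq_delta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("dimension_delta_mm", "amplitude_delta_mm",
                     "projection_delta_mm", "hu_consistency_hu"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"tolerance {name} must be > 0")
        for k, v in self.iq_delta.items():
            if v <= 0:
                raise ValueError(f"tolerance iq_delta[{k!r}] must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "ToleranceSet":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


#: the canonical report test list (one report section per imaging test)
TEST_NAMES = (
    "motion_amplitude",
    "surrogate_dimensions",
    "projection_dimensions",
    "hu_value_consistency",
    "spatial_resolution",
    "low_contrast_cnr",
    "noise",
    "uniformity",
)

_IQ_TEST_FIELD = {
    "spatial_resolution": "mtf10_lp_per_cm",
    "low_contrast_cnr": "cnr_low_contrast",
    "noise": "noise_hu",
    "uniformity": "uniformity_hu",
}


def _iq_dict(m: IQMetrics) -> dict:
    return {
        "bin_label": m.bin_label,
        "geometric_distortion_mm": m.geometric_distortion_mm,
        "mtf10_lp_per_cm": m.mtf10_lp_per_cm,
        "mtf_saturated": m.mtf_saturated,
        "contrast_detectability_mm": m.contrast_detectability_mm,
        "contrast_none_detected": m.contrast_none_detected,
        "hu_constancy_hu": m.hu_constancy_hu,
        "uniformity_hu": m.uniformity_hu,
        "noise_hu": m.noise_hu,
        "cnr_low_contrast": None if m.cnr_low_contrast is not None
        and not np.isfinite(m.cnr_low_contrast) else m.cnr_low_contrast,
        "plug_mean_hu": m.plug_mean_hu,
        "errors": m.errors,
    }


def run_qa(
    source: str | Path | tuple[CTVolume, Phase4DSeries | None],
    geometry: PhantomGeometry,
    trace: MotionTrace | None = None,
    tolerances: ToleranceSet | None = None,
    include_iq: bool = True,
) -> dict:
    """Run the full 4DCT QA analysis and return the report as a dict.

    ``source`` is either a directory tree of DICOM series or an in-memory
    ``(stationary, series)`` pair.  A stationary baseline is mandatory;
    motion tests are ``skipped`` when no 4D series (or no trace for the
    expected amplitude) is available.
    """
    tol = tolerances or ToleranceSet()
    if isinstance(source, (str, Path)):
        stationary, series, _derived = read_series_tree(source)
        source_name = str(source)
    else:
        stationary, series = source
        source_name = "<in-memory>"
    if stationary is None:
        raise BaselineMissingError(
            "no stationary reference series found; the QA analysis requires "
            "a stationary baseline"
        )

    report: dict = {
        "schema_version": 1,
        "tool": {"name": "fourdqa", "version": __version__},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "dataset": {
            "source": source_name,
            "phantom_model": geometry.model,
            "binning_mode": series.binning_mode if series else None,
            "n_bins": series.n_bins if series else 0,
        },
        "tests": {},
        "spatial_integrity": {},
        "image_quality": {},
    }
    tests = report["tests"]
    for name in TEST_NAMES:
        tests[name] = {"status": "skipped", "value": None, "tolerance": None,
                       "detail": None}

    surrogates = geometry.surrogate_plugs()
    sens_plugs = geometry.sensitometry.plugs

    pose_st = locate_phantom(stationary, geometry)
    stat_dim = {}
    stat_hu = {}
    for plug in sens_plugs:
        try:
            if plug in surrogates:
                stat_dim[plug.plug_id] = measure_plug_dimensions(
                    stationary, pose_st, plug, geometry)
                stat_hu[plug.plug_id] = stat_dim[plug.plug_id]
            else:
                stat_hu[plug.plug_id] = detect_plug(stationary, pose_st, plug, geometry)
        except Exception as exc:
            tests["hu_value_consistency"].update(
                status="error", detail=f"stationary plug {plug.plug_id}: {exc}")

    bin_dim: dict[str, list] = {p.plug_id: [] for p in surrogates}
    bin_hu: dict[str, list] = {p.plug_id: [] for p in sens_plugs}
    bin_errors: list[str] = []
    iq_bins: list[IQMetrics] = []
    if series is not None:
        for vol in series:
            try:
                pose = locate_phantom(vol, geometry)
                for plug in sens_plugs:
                    if plug in surrogates:
                        m = measure_plug_dimensions(vol, pose, plug, geometry)
                        bin_dim[plug.plug_id].append(m)
                    else:
                        m = detect_plug(vol, pose, plug, geometry)
                    bin_hu[plug.plug_id].append(m)
                if include_iq:
                    iq_bins.append(iq_suite(vol, pose, geometry))
            except Exception as exc:
                bin_errors.append(f"{vol.bin_label}: {type(exc).__name__}: {exc}")

    # ---- surrogate dimensions ------------------------------------------
    dim_section = {}
    worst_dim = None
    try:
        for pid, meas_list in bin_dim.items():
            if not meas_list or pid not in stat_dim:
                continue
            deltas = dimension_consistency(meas_list, stat_dim[pid])
            dim_section[pid] = {
                d.axis: {
                    "per_bin_fwhm_mm": d.per_bin_fwhm_mm,
                    "mean_fwhm_mm": d.mean_fwhm_mm,
                    "stationary_fwhm_mm": d.stationary_fwhm_mm,
                    "delta_mm": d.delta_mm,
                } for d in deltas
            }
            cand = max(abs(d.delta_mm) for d in deltas)
            worst_dim = cand if worst_dim is None else max(worst_dim, cand)
        if dim_section:
            tests["surrogate_dimensions"].update(
                status=_status(worst_dim, tol.dimension_delta_mm),
                value=worst_dim, tolerance=tol.dimension_delta_mm,
                detail="max |mean-over-bins - stationary| FWHM over plugs/axes")
    except Exception as exc:
        tests["surrogate_dimensions"].update(status="error", detail=str(exc))
    report["spatial_integrity"]["dimension_deltas"] = dim_section

    # ---- motion amplitude ----------------------------------------------
    amp_section = {}
    if trace is not None:
        try:
            worst_amp = None
            axis = trace.principal_axis()
            for pid, meas_list in bin_dim.items():
                if len(meas_list) < 2:
                    continue
                res = motion_amplitude(meas_list, trace)
                amp_section[pid] = {
                    "extent_mm": res.extent_mm,
                    "expected_mm": res.expected_mm,
                    "delta_mm": res.delta_mm,
                    "per_bin_centroid_mm": res.per_bin_centroid_mm,
                }
                d = abs(res.delta_mm[axis])
                worst_amp = d if worst_amp is None else max(worst_amp, d)
            if amp_section:
                tests["motion_amplitude"].update(
                    status=_status(worst_amp, tol.amplitude_delta_mm),
                    value=worst_amp, tolerance=tol.amplitude_delta_mm,
                    detail="max |centroid extent - input amplitude| along the "
                           "principal motion axis")
        except Exception as exc:
            tests["motion_amplitude"].update(status="error", detail=str(exc))
    report["spatial_integrity"]["amplitude"] = amp_section

    # ---- MIP / MinIP ----------------------------------------------------
    proj_section = []
    derived_iq = {}
    if series is not None:
        avg = mip = minip = None
        try:
            avg = average_ct(series)
            mip = intensity_projection(series, "MIP")
            minip = intensity_projection(series, "MinIP")
        except Exception as exc:
            tests["projection_dimensions"].update(status="error", detail=str(exc))
        if trace is not None and mip is not None:
            try:
                worst_proj = None
                for pid, kind in PROJECTION_PAIRS.items():
                    if pid not in stat_dim:
                        continue
                    plug = geometry.plug(pid)
                    proj_vol = mip if kind == "MIP" else minip
                    res = projection_dimension_check(
                        proj_vol, stat_dim[pid], trace, plug, geometry)
                    proj_section.append({
                        "plug_id": pid, "kind": kind,
                        "measured_z_fwhm_mm": res.measured_z_fwhm_mm,
                        "expected_mm": res.expected_mm,
                        "delta_mm": res.delta_mm,
                    })
                    d = abs(res.delta_mm)
                    worst_proj = d if worst_proj is None else max(worst_proj, d)
                if proj_section:
                    tests["projection_dimensions"].update(
                        status=_status(worst_proj, tol.projection_delta_mm),
                        value=worst_proj, tolerance=tol.projection_delta_mm,
                        detail="max |measured - (stationary z + amplitude)| over "
                               "Teflon/MIP and Air/MinIP")
            except Exception as exc:
                tests["projection_dimensions"].update(status="error", detail=str(exc))
        if include_iq and avg is not None:
            try:
                pose_avg = locate_phantom(avg, geometry)
                derived_iq["average"] = _iq_dict(iq_suite(avg, pose_avg, geometry))
            except Exception as exc:
                derived_iq["average"] = {"error": str(exc)}
    report["spatial_integrity"]["projections"] = proj_section

    # ---- HU consistency -------------------------------------------------
    hu_section = {}
    try:
        usable = {pid: lst for pid, lst in bin_hu.items()
                  if lst and pid in stat_hu}
        if usable:
            deltas = hu_consistency_per_plug(
                usable, {pid: stat_hu[pid] for pid in usable})
            hu_section = {
                pid: {
                    "delta_hu": dv,
                    "stationary_mean_hu": stat_hu[pid].mean_hu,
                    "per_bin_mean_hu": [m.mean_hu for m in bin_hu[pid]],
                } for pid, dv in deltas.items()
            }
            worst_hu = max(abs(v) for v in deltas.values())
            tests["hu_value_consistency"].update(
                status=_status(worst_hu, tol.hu_consistency_hu),
                value=worst_hu, tolerance=tol.hu_consistency_hu,
                detail="max |mean-over-bins - stationary| plug HU")
    except Exception as exc:
        tests["hu_value_consistency"].update(status="error", detail=str(exc))
    report["spatial_integrity"]["hu_consistency"] = hu_section

    # ---- image quality ---------------------------------------------------
    if include_iq:
        try:
            iq_stat = iq_suite(stationary, pose_st, geometry)
            report["image_quality"]["stationary"] = _iq_dict(iq_stat)
        except Exception as exc:
            iq_stat = None
            report["image_quality"]["stationary"] = {"error": str(exc)}
        report["image_quality"]["bins"] = [_iq_dict(m) for m in iq_bins]
        summary = iq_summary(iq_bins) if iq_bins else {}
        report["image_quality"]["summary_mean_sd"] = summary
        report["image_quality"].update(derived_iq and {"derived": derived_iq} or {})
        for test, fieldname in _IQ_TEST_FIELD.items():
            tol_v = tol.iq_delta.get(fieldname)
            stat_v = getattr(iq_stat, fieldname, None) if iq_stat else None
            if fieldname in summary and stat_v is not None:
                delta = abs(summary[fieldname][0] - stat_v)
                tests[test].update(
                    value=delta, tolerance=tol_v,
                    detail="|mean-over-bins - stationary|",
                    status=_status(delta, tol_v) if tol_v is not None else "skipped",
                )
    if bin_errors:
        report["bin_errors"] = bin_errors
        for name in ("surrogate_dimensions", "motion_amplitude",
                     "hu_value_consistency"):
            if tests[name]["status"] in ("pass", "fail"):
                tests[name]["detail"] = (
                    (tests[name]["detail"] or "")
                    + f"; {len(bin_errors)} bin(s) errored: {bin_errors}"
                )
    return report


def _status(value, tolerance) -> str:
    if value is None:
        return "error"
    if tolerance is None:
        return "skipped"
    return "pass" if abs(value) <= tolerance else "fail"


# ---------------------------------------------------------------------------
# output / comparison


def flat_metrics(report: dict) -> dict[str, float]:
    """Flatten a QA report into scalar metric name -> value."""
    out = {}
    for name, t in report.get("tests", {}).items():
        if t.get("value") is not None:
            out[f"test.{name}"] = t["value"]
    iq = report.get("image_quality", {})
    stat = iq.get("stationary", {})
    for k, v in stat.items():
        if isinstance(v, (int, float)) and not isinstance(v, bool):
            out[f"stationary.{k}"] = v
    for k, (mean, sd) in iq.get("summary_mean_sd", {}).items():
        out[f"4d_mean.{k}"] = mean
        out[f"4d_sd.{k}"] = sd
    return out


def write_report(report: dict, json_path: str | Path,
                 csv_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=1, default=float))
    if csv_path is not None:
        flat = flat_metrics(report)
        pd.DataFrame(
            {"metric": list(flat), "value": list(flat.values())}
        ).to_csv(csv_path, index=False)


def compare_to_baseline(current: dict, baseline: dict,
                        tolerances: dict[str, float] | None = None) -> dict:
    """Metric-by-metric current - baseline deltas with tolerance flags."""
    if current["dataset"].get("phantom_model") != baseline["dataset"].get("phantom_model"):
        raise ComparabilityError("reports use different phantom models")
    if set(current.get("tests", {})) != set(baseline.get("tests", {})):
        raise ComparabilityError("reports carry different test lists")
    tolerances = tolerances or {}
    cur = flat_metrics(current)
    base = flat_metrics(baseline)
    rows = {}
    all_pass = True
    for name in sorted(set(cur) | set(base)):
        if name not in cur or name not in base:
            rows[name] = {"status": "skipped", "delta": None,
                          "current": cur.get(name), "baseline": base.get(name)}
            continue
        delta = cur[name] - base[name]
        tol = tolerances.get(name)
        status = "pass" if tol is None or abs(delta) <= tol else "fail"
        all_pass = all_pass and status == "pass"
        rows[name] = {"status": status, "delta": delta,
                      "current": cur[name], "baseline": base[name],
                      "tolerance": tol}
    return {"metrics": rows, "all_pass": all_pass}
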