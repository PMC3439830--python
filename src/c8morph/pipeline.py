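"""End-to-end orchestration: three para-midsagittal slices, median aggregation.

The full measurement (extraction -> median line -> thickness -> partitions)
runs independently on the midsagittal slice and the two parasagittal
slices at x = +/-1 mm; the final derived quantities are elementwise
medians over the three slices, which discounts a failure (e.g., a fornix
adhesion) confined to a single slice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import C8Config
from .extraction import ExtractionError, extract_callosum, orientation_filter, \
    refined_ap_extent
from .image_io import WMVolume, extract_parasagittal_slices
from .median_geometry import build_median_line, cast_radial_rays, compute_centroid, median_length
from .partitions import SCHEMES, compartment_areas, compartment_mean_thickness, \
    partition_boundaries
from .thickness import thickness_profile

log = logging.getLogger(__name__)

__all__ = ["SliceResult", "MorphometryReport", "run_c8", "write_report", "read_report"]


@dataclass
class SliceResult:
    """All derived quantities for one para-midsagittal slice."""

    x_offset_mm: float
    n_voxels: int
    ap_extent_mm: tuple[float, float]
    length_mm: float
    length_native_mm: float
    profile_mm: np.ndarray
    profile_native_mm: np.ndarray
    chosen_angles_deg: np.ndarray
    anchors_mm: np.ndarray
    # scheme -> {labels, areas_mm2, areas_native_mm2, mean_thickness_mm, ...}
    compartments: dict[str, dict] = field(default_factory=dict)
    total_area_mm2: float = float("nan")
    total_area_native_mm2: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "x_offset_mm": self.x_offset_mm,
            "n_voxels": self.n_voxels,
            "ap_extent_mm": list(self.ap_extent_mm),
            "length_mm": self.length_mm,
            "length_native_mm": self.length_native_mm,
            "profile_mm": self.profile_mm.tolist(),
            "profile_native_mm": self.profile_native_mm.tolist(),
            "chosen_angles_deg": self.chosen_angles_deg.tolist(),
            "anchors_mm": self.anchors_mm.tolist(),
            "compartments": self.compartments,
            "total_area_mm2": self.total_area_mm2,
            "total_area_native_mm2": self.total_area_native_mm2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SliceResult":
        return cls(x_offset_mm=d["x_offset_mm"], n_voxels=d["n_voxels"],
                   ap_extent_mm=tuple(d["ap_extent_mm"]), length_mm=d["length_mm"],
                   length_native_mm=d["length_native_mm"],
                   profile_mm=np.asarray(d["profile_mm"]),
                   profile_native_mm=np.asarray(d["profile_native_mm"]),
                   chosen_angles_deg=np.asarray(d["chosen_angles_deg"]),
                   anchors_mm=np.asarray(d["anchors_mm"]),
                   compartments=d["compartments"],
                   total_area_mm2=d["total_area_mm2"],
                   total_area_native_mm2=d["total_area_native_mm2"])


def aggregate_slices(results: list[SliceResult]) -> dict:
    """Elementwise median of every derived quantity over the measured slices."""
    med = lambda vals: np.nanmedian(np.asarray(vals, dtype=float), axis=0)
    agg: dict = {
        "n_slices": len(results),
        "length_mm": float(med([r.length_mm for r in results])),
        "length_native_mm": float(med([r.length_native_mm for r in results])),
        "profile_mm": med([r.profile_mm for r in results]).tolist(),
        "profile_native_mm": med([r.profile_native_mm for r in results]).tolist(),
        "anchors_mm": med([r.anchors_mm for r in results]).tolist(),
        "total_area_mm2": float(med([r.total_area_mm2 for r in results])),
        "total_area_native_mm2": float(med([r.total_area_native_mm2 for r in results])),
        "compartments": {},
    }
    for scheme in results[0].compartments:
        per = [r.compartments[scheme] for r in results]
        agg["compartments"][scheme] = {
            "labels": per[0]["labels"],
            "areas_mm2": med([p["areas_mm2"] for p in per]).tolist(),
            "areas_native_mm2": med([p["areas_native_mm2"] for p in per]).tolist(),
            "mean_thickness_mm": med([p["mean_thickness_mm"] for p in per]).tolist(),
            "mean_thickness_native_mm": med(
                [p["mean_thickness_native_mm"] for p in per]).tolist(),
        }
    return agg


@dataclass
class MorphometryReport:
    per_slice: list[SliceResult]
    aggregated: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"per_slice": [r.to_dict() for r in self.per_slice],
                "aggregated": self.aggregated, "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "MorphometryReport":
        return cls(per_slice=[SliceResult.from_dict(s) for s in d["per_slice"]],
                   aggregated=d["aggregated"], provenance=d["provenance"])


def measure_slice(slc, native_affine: np.ndarray, config: C8Config) -> SliceResult:
    """Run the complete single-slice measurement chain."""
    cluster = extract_callosum(slc, box=config.bounding_box,
                               wm_threshold=config.wm_threshold,
                               connectivity=config.connectivity,
                               midbody_y_range_mm=config.midbody_y_range_mm)
    centroid = compute_centroid(cluster, splenium_fraction=config.splenium_fraction)
    fan = cast_radial_rays(slc, cluster, centroid, step_deg=config.ray_step_deg,
                           sample_step_mm=config.ray_sample_step_mm,
                           wm_threshold=config.wm_threshold, dilate_mm=config.dilate_mm)
    line = build_median_line(fan, cluster, n_anchors=config.n_anchors)
    profile = thickness_profile(slc, line, native_affine=native_affine, cluster=cluster,
                                params=config.traversal_params, dilate_mm=config.dilate_mm)
    len_mni, len_native = median_length(line, native_affine)
    result = SliceResult(x_offset_mm=slc.x_offset_mm, n_voxels=cluster.n_voxels,
                         ap_extent_mm=cluster.ap_extent_mm,
                         length_mm=len_mni, length_native_mm=len_native,
                         profile_mm=profile.values_mm,
                         profile_native_mm=profile.values_native_mm,
                         chosen_angles_deg=profile.chosen_angles_deg,
                         anchors_mm=line.anchors)
    ap_refined = refined_ap_extent(cluster, dilate_mm=config.dilate_mm)
    for name in config.schemes:
        scheme = SCHEMES[name]
        cuts = partition_boundaries(ap_refined, scheme)
        areas = compartment_areas(slc, cluster, cuts, native_affine=native_affine,
                                  scheme=scheme, dilate_mm=config.dilate_mm)
        t_mni, t_native = compartment_mean_thickness(profile, line, cuts)
        result.compartments[name] = {
            "labels": list(scheme.labels),
            "cuts_y_mm": cuts,
            "areas_mm2": areas.areas_mm2.tolist(),
            "areas_native_mm2": areas.areas_native_mm2.tolist(),
            "mean_thickness_mm": t_mni.tolist(),
            "mean_thickness_native_mm": t_native.tolist(),
        }
        result.total_area_mm2 = areas.total_area_mm2
        result.total_area_native_mm2 = areas.total_area_native_mm2
    return result


def run_c8(vol: WMVolume, config: C8Config | None = None,
           input_path: str | None = None) -> MorphometryReport:
    """Measure the callosum on three para-midsagittal slices and aggregate.

    A slice whose measurement fails is dropped with a warning as long as at
    least two slices succeed; two or more failures abort the run.
    """
    config = config or C8Config()
    if config.orientation_filter_enabled:
        vol = orientation_filter(vol, max_angle_deg=config.orientation_max_angle_deg,
                                 wm_threshold=config.wm_threshold,
                                 probe_radius_mm=config.orientation_probe_radius_mm)
    slices = extract_parasagittal_slices(vol, offsets_mm=config.slice_offsets_mm)
    results, failures = [], []
    for slc in slices:
        try:
            results.append(measure_slice(slc, vol.native_affine, config))
            log.info("slice x=%+.1f mm: measured %d voxels", slc.x_offset_mm,
                     results[-1].n_voxels)
        except (ExtractionError, ValueError, RuntimeError) as exc:
            failures.append((slc.x_offset_mm, str(exc)))
            log.warning("slice x=%+.1f mm failed: %s", slc.x_offset_mm, exc)
    if len(failures) >= 2 or not results or len(results) < len(slices) - 1:
        raise ExtractionError(f"too many slice failures: {failures}")
    provenance = {"version": __version__, "config_hash": config.hash(),
                  "config": config.to_dict(), "input_path": input_path,
                  "slice_failures": failures}
    return MorphometryReport(per_slice=results, aggregated=aggregate_slices(results),
                             provenance=provenance)


def write_report(report: MorphometryReport, out_dir, qc_slices=None) -> list[Path]:
    """Serialize a report: full JSON, compartment CSV, 50-anchor profile CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    json_path = out / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    written.append(json_path)

    rows = []
    sources = [("median", report.aggregated["compartments"])] + [
        (f"x={r.x_offset_mm:+.0f}mm", r.compartments) for r in report.per_slice]
    for source, comps in sources:
        for scheme, c in comps.items():
            for i, label in enumerate(c["labels"]):
                rows.append({"source": source, "scheme": scheme, "compartment": label,
                             "area_mm2": c["areas_mm2"][i],
                             "area_native_mm2": c["areas_native_mm2"][i],
                             "mean_thickness_mm": c["mean_thickness_mm"][i],
                             "mean_thickness_native_mm": c["mean_thickness_native_mm"][i]})
    comp_path = out / "compartments.csv"
    pd.DataFrame(rows).to_csv(comp_path, index=False)
    written.append(comp_path)

    agg = report.aggregated
    anchors = np.asarray(agg["anchors_mm"])
    profile = pd.DataFrame({
        "anchor": np.arange(len(agg["profile_mm"])),
        "y_mm": anchors[:, 0], "z_mm": anchors[:, 1],
        "thickness_mm": agg["profile_mm"],
        "thickness_native_mm": agg["profile_native_mm"],
    })
    prof_path = out / "profile.csv"
    profile.to_csv(prof_path, index=False)
    written.append(prof_path)

    if qc_slices:
        from .qc import plot_slice_qc
        for slc, slice_result in qc_slices:
            png = out / f"qc_x{slice_result.x_offset_mm:+.0f}mm.png"
            plot_slice_qc(slc, slice_result, png)
            written.append(png)
    return written


def read_report(path) -> MorphometryReport:
    with open(path) as fh:
        return MorphometryReport.from_dict(json.load(fh))
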