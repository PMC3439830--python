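"""Run configuration: every tunable of the morphometry pipeline in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .extraction import BoundingBox
from .thickness import TraversalParams


@dataclass(frozen=True)
class C8Config:
    """Tunable parameters of the full pipeline (all lengths in MNI mm).

    The WM threshold of 0.5 is the natural probability decision boundary;
    the mid-body y-range covers where the fornix attaches; the 11.55 deg
    wedge is a symmetric 7-ray stencil at 1.65 deg ray spacing.
    """

    wm_threshold: float = 0.5
    connectivity: int = 8
    bounding_box: BoundingBox = field(default_factory=BoundingBox)
    midbody_y_range_mm: tuple[float, float] = (-30.0, 10.0)
    orientation_filter_enabled: bool = True
    orientation_max_angle_deg: float = 45.0
    orientation_probe_radius_mm: float = 3.0
    slice_offsets_mm: tuple[float, ...] = (-1.0, 0.0, 1.0)
    ray_step_deg: float = 1.65
    wedge_deg: float = 11.55
    n_anchors: int = 50
    ray_sample_step_mm: float = 0.25
    splenium_fraction: float = 0.2
    sweep_step_deg: float = 1.0
    ds_mm: float = 0.1
    exit_run: int = 10
    max_chord_mm: float = 25.0
    dilate_mm: float = 2.0
    schemes: tuple[str, ...] = ("hofer_frahm", "witelson_grouped")

    @property
    def traversal_params(self) -> TraversalParams:
        return TraversalParams(sweep_step_deg=self.sweep_step_deg, ds_mm=self.ds_mm,
                               wm_threshold=self.wm_threshold, exit_run=self.exit_run,
                               max_chord_mm=self.max_chord_mm)

    def to_dict(self) -> dict:
        """JSON-canonical dict (tuples as lists, so round trips compare equal)."""
        d = asdict(self)
        d["bounding_box"] = {"y_range_mm": list(self.bounding_box.y_range_mm),
                             "z_range_mm": list(self.bounding_box.z_range_mm)}
        for key in ("midbody_y_range_mm", "slice_offsets_mm", "schemes"):
            d[key] = list(d[key])
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "C8Config":
        d = dict(d)
        if "bounding_box" in d and isinstance(d["bounding_box"], dict):
            bb = d["bounding_box"]
            d["bounding_box"] = BoundingBox(y_range_mm=tuple(bb["y_range_mm"]),
                                            z_range_mm=tuple(bb["z_range_mm"]))
        for key in ("midbody_y_range_mm", "slice_offsets_mm", "schemes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "C8Config":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def with_overrides(self, **kwargs) -> "C8Config":
        return replace(self, **kwargs)
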