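"""Synthetic WM probability phantoms with analytic callosal ground truth.

The generator emulates the arched midsagittal callosal cross-section as an
annular sector band (optionally thickness-tapered), extruded along x so
that para-midsagittal slices and the 3D orientation filter are exercised,
then Gaussian-blurred (partial-volume emulation) and perturbed with
clipped additive Gaussian noise. Ground truth (thickness profile, area,
midline length, compartment areas) is computed from the analytic geometry
before blur; blurring is mass-preserving, so probabilistic areas are
invariant up to edge truncation.

A descending "fornix" stub can be attached to the inferior arc, with an
optional sub-threshold gap row to exercise inferior-branch pruning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import WMVolume
from .partitions import SCHEMES, _compartment_of, partition_boundaries

__all__ = [
    "FornixStub",
    "PhantomSpec",
    "GroundTruth",
    "make_arch_phantom",
    "make_fornix_phantom",
    "repeat_with_noise",
]


@dataclass(frozen=True)
class FornixStub:
    """A thin WM branch descending from the inferior arc of the band.

    Defaults mimic the fornix: a ~1.5 mm wide (in y) column attaching
    under the posterior body (not the apex), descending a few millimetres
    into the callosal concavity, and — unlike the callosum itself —
    laterally narrow (~2 mm in x). Lateral narrowness is what the
    mediolateral orientation filter exploits, and it confines residual
    adhesions to a subset of the three para-midsagittal slices, the
    regime the median-over-slices aggregation is designed for.
    """

    attach_angle_deg: float = 120.0
    length_mm: float = 6.0
    width_mm: float = 1.5
    x_extent_mm: float = 2.0
    gap_probability: float | None = None  # sub-threshold rows at the attachment


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and degradation parameters of an arch phantom.

    Defaults follow the adult midsagittal callosum at MNI scale: a 4 mm
    thick band at ~10 mm mid-radius arching over its inferior concavity,
    0.5 mm partial-volume blur at 1 mm isotropic voxels.
    """

    inner_radius_mm: float = 8.0
    outer_radius_mm: float = 12.0
    angular_span_deg: tuple[float, float] = (0.0, 180.0)
    center_mni: tuple[float, float] = (0.0, 15.0)  # (y, z)
    x_extrusion_mm: float = 20.0
    taper: tuple[float, float] | None = None  # thickness at span start/end
    fornix_stub: FornixStub | None = None
    blur_sigma_mm: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0
    voxel_mm: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError("need 0 < inner radius < outer radius")
        a0, a1 = self.angular_span_deg
        if not (0 <= a0 < a1 <= 360):
            raise ValueError("angular span must satisfy 0 <= start < end <= 360")
        if self.blur_sigma_mm < 0 or self.noise_sd < 0 or self.voxel_mm <= 0:
            raise ValueError("blur, noise and voxel size must be non-negative/positive")

    @property
    def mid_radius_mm(self) -> float:
        return 0.5 * (self.inner_radius_mm + self.outer_radius_mm)

    def thickness_at(self, angle_deg) -> np.ndarray:
        """Analytic band thickness as a function of angle within the span."""
        a0, a1 = self.angular_span_deg
        base = self.outer_radius_mm - self.inner_radius_mm
        if self.taper is None:
            return np.full_like(np.asarray(angle_deg, dtype=float), base)
        t0, t1 = self.taper
        frac = (np.asarray(angle_deg, dtype=float) - a0) / (a1 - a0)
        return t0 + (t1 - t0) * frac


@dataclass
class GroundTruth:
    """Analytic reference values for an arch phantom (band only, stub excluded)."""

    thickness_angles_deg: np.ndarray
    thickness_mm: np.ndarray
    total_area_mm2: float
    midline_length_mm: float
    compartment_areas: dict[str, list[float]]
    ap_extent_mm: tuple[float, float]
    stub_voxel_mask: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path) -> None:
        payload = {
            "thickness_angles_deg": self.thickness_angles_deg.tolist(),
            "thickness_mm": self.thickness_mm.tolist(),
            "total_area_mm2": self.total_area_mm2,
            "midline_length_mm": self.midline_length_mm,
            "compartment_areas": self.compartment_areas,
            "ap_extent_mm": list(self.ap_extent_mm),
            "n_stub_voxels": None if self.stub_voxel_mask is None
            else int(self.stub_voxel_mask.sum()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _band_mask(spec: PhantomSpec, yy: np.ndarray, zz: np.ndarray) -> np.ndarray:
    cy, cz = spec.center_mni
    r = np.hypot(yy - cy, zz - cz)
    theta = np.rad2deg(np.arctan2(zz - cz, yy - cy)) % 360.0
    a0, a1 = spec.angular_span_deg
    in_span = (theta >= a0) & (theta <= a1)
    half = spec.thickness_at(np.clip(theta, a0, a1)) / 2.0
    in_band = np.abs(r - spec.mid_radius_mm) <= half
    return in_span & in_band


def _analytic_truth(spec: PhantomSpec, fine_mm: float = 0.05) -> GroundTruth:
    a0, a1 = spec.angular_span_deg
    angles = np.linspace(a0, a1, 721)
    t = spec.thickness_at(angles)
    span_rad = np.deg2rad(a1 - a0)
    mid = spec.mid_radius_mm
    # Exact annular geometry: area element ((mid+t/2)^2-(mid-t/2)^2)/2 dtheta = mid*t dtheta.
    total_area = float(np.trapezoid(mid * t, np.deg2rad(angles)))
    midline_length = mid * span_rad
    # Compartment areas by fine-grid summation of the analytic band (0.05 mm).
    cy, cz = spec.center_mni
    rmax = mid + t.max() / 2 + 1.0
    ys = np.arange(cy - rmax, cy + rmax, fine_mm) + fine_mm / 2
    zs = np.arange(cz - rmax, cz + rmax, fine_mm) + fine_mm / 2
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    band = _band_mask(spec, yy, zz)
    y_in = yy[band]
    ap = (float(y_in.min()), float(y_in.max()))
    comp_areas: dict[str, list[float]] = {}
    for name, scheme in SCHEMES.items():
        cuts = partition_boundaries(ap, scheme)
        comp = _compartment_of(y_in, cuts)
        areas = np.zeros(len(cuts) + 1)
        np.add.at(areas, comp, fine_mm ** 2)
        comp_areas[name] = areas.tolist()
    return GroundTruth(thickness_angles_deg=angles, thickness_mm=t,
                       total_area_mm2=total_area, midline_length_mm=midline_length,
                       compartment_areas=comp_areas, ap_extent_mm=ap)


def _grid(spec: PhantomSpec):
    cy, cz = spec.center_mni
    margin = 8.0 + 4.0 * spec.blur_sigma_mm
    r_out = spec.mid_radius_mm + spec.thickness_at(
        np.asarray(spec.angular_span_deg)).max() / 2
    stub_drop = 0.0
    if spec.fornix_stub is not None:
        stub_drop = spec.fornix_stub.length_mm
    v = spec.voxel_mm
    x_axis = np.arange(-spec.x_extrusion_mm / 2 - margin, spec.x_extrusion_mm / 2 + margin, v)
    y_axis = np.arange(cy - r_out - margin, cy + r_out + margin, v)
    z_axis = np.arange(cz - r_out - margin - stub_drop, cz + r_out + margin, v)
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = [x_axis[0], y_axis[0], z_axis[0]]
    return x_axis, y_axis, z_axis, affine


def _coverage2d(spec: PhantomSpec, y_axis: np.ndarray, z_axis: np.ndarray,
                supersample: int = 4):
    """In-plane coverage fractions of the band and the stub per pixel.

    Shapes are rasterized on a ``supersample``-times finer subgrid and
    block-averaged, emulating partial voluming at structure boundaries.
    """
    v, ss = spec.voxel_mm, supersample
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    y_fine = (y_axis[:, None] + sub[None, :] * v).ravel()
    z_fine = (z_axis[:, None] + sub[None, :] * v).ravel()
    yy, zz = np.meshgrid(y_fine, z_fine, indexing="ij")
    pool = lambda m: m.reshape(y_axis.size, ss, z_axis.size, ss).mean(axis=(1, 3))
    band_cov = pool(_band_mask(spec, yy, zz))
    stub_cov = None
    if spec.fornix_stub is not None:
        stub_cov = pool(_stub_region(spec, yy, zz))
    return band_cov, stub_cov


def _x_coverage(x_axis: np.ndarray, half_mm: float, voxel_mm: float) -> np.ndarray:
    """Fraction of each voxel's x extent inside [-half_mm, +half_mm]."""
    lo = np.maximum(x_axis - voxel_mm / 2, -half_mm)
    hi = np.minimum(x_axis + voxel_mm / 2, half_mm)
    return np.clip(hi - lo, 0.0, voxel_mm) / voxel_mm


def make_arch_phantom(spec: PhantomSpec) -> tuple[WMVolume, GroundTruth]:
    """Annular-sector band, extruded along x, blurred, noise-perturbed.

    Rasterization uses sub-voxel coverage fractions, so the discrete
    probability mass matches the analytic band area to well under 1%.
    """
    x_axis, y_axis, z_axis, affine = _grid(spec)
    band_cov, stub_cov = _coverage2d(spec, y_axis, z_axis)
    in_x = _x_coverage(x_axis, spec.x_extrusion_mm / 2, spec.voxel_mm)
    data = in_x[:, None, None] * band_cov[None, :, :]
    truth = _analytic_truth(spec)
    if spec.fornix_stub is not None:
        # The stub is laterally narrow: its own x coverage, not the band's.
        stub_x = _x_coverage(x_axis, spec.fornix_stub.x_extent_mm / 2, spec.voxel_mm)
        data = np.maximum(data, stub_x[:, None, None] * stub_cov[None, :, :])
        stub2d = (stub_cov >= 0.5) & ~(band_cov >= 0.5)
        gap = spec.fornix_stub.gap_probability
        if gap is not None:
            # Two sub-threshold rows per column fully separate the stub from
            # the band even where the oblique arc boundary steps between
            # columns (8-connectivity cannot bridge a 2-row gap).
            gap2d = np.zeros_like(stub2d)
            for iy in np.flatnonzero(stub2d.any(axis=1)):
                top = np.flatnonzero(stub2d[iy])[-2:]
                gap2d[iy, top] = True
            data = np.where((stub_x[:, None, None] > 0) & gap2d[None, :, :],
                            np.minimum(gap, data), data)
            stub2d = stub2d & ~gap2d
        truth.stub_voxel_mask = (stub_x[:, None, None] >= 0.5) & stub2d[None, :, :]
    if spec.blur_sigma_mm > 0:
        data = gaussian_filter(data, sigma=spec.blur_sigma_mm / spec.voxel_mm)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 1.0)
    return WMVolume(data=data, affine=affine), truth


def _stub_region(spec: PhantomSpec, yy: np.ndarray, zz: np.ndarray) -> np.ndarray:
    """Analytic stub rectangle descending from the inner (inferior) arc edge."""
    stub = spec.fornix_stub
    a0, a1 = spec.angular_span_deg
    if not a0 < stub.attach_angle_deg < a1:
        raise ValueError("stub must attach within the band's angular span")
    cy, cz = spec.center_mni
    t = float(spec.thickness_at(np.asarray(stub.attach_angle_deg)))
    r_in = spec.mid_radius_mm - t / 2
    th = np.deg2rad(stub.attach_angle_deg)
    pa = np.array([cy + r_in * np.cos(th), cz + r_in * np.sin(th)])
    in_y = np.abs(yy - pa[0]) <= stub.width_mm / 2
    in_z = (zz >= pa[1] - stub.length_mm) & (zz <= pa[1] + 1.0)
    return in_y & in_z


def make_fornix_phantom(spec: PhantomSpec) -> tuple[WMVolume, GroundTruth]:
    """Arch phantom with a descending fornix-surrogate stub attached."""
    if spec.fornix_stub is None:
        spec = replace(spec, fornix_stub=FornixStub())
    return make_arch_phantom(spec)


def repeat_with_noise(spec: PhantomSpec, n: int) -> list[WMVolume]:
    """n volumes differing only in the noise realization (seeds seed..seed+n-1)."""
    if n < 2:
        raise ValueError("need n >= 2 repetitions")
    return [make_arch_phantom(replace(spec, seed=spec.seed + i))[0] for i in range(n)]
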