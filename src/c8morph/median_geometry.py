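"""Radial weighted-median centerline of the callosum and internal length.

A fan of radial rays (default every 1.65 deg) is cast from a centroid placed
halfway along the anterior-posterior extent, at the height of the most
inferior extent of the splenium. On each ray the median WM location is
computed with squared segmentation probabilities as median weights, pooled
over an 11.55 deg angular neighborhood (a symmetric 7-ray stencil at the
default spacing). Interpolating these median points at 50 equal-angle
positions between the refined anterior and posterior tips yields the
median line; summing the anchor-to-anchor gaps yields internal length.

Angles are measured in the sagittal plane: 0 deg points anterior (+y),
increasing through superior (+z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extraction import CallosalCluster
from .image_io import WMSliceMap, apply_affine

__all__ = [
    "Centroid",
    "RadialRay",
    "RayFan",
    "MedianLine",
    "compute_centroid",
    "cast_radial_rays",
    "weighted_median_point",
    "build_median_line",
    "median_length",
]


@dataclass(frozen=True)
class Centroid:
    y_mm: float
    z_mm: float

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.y_mm, self.z_mm])


def _direction(angle_deg) -> np.ndarray:
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return np.stack([np.cos(a), np.sin(a)], axis=-1)


def _circular_distance_deg(a, b) -> np.ndarray:
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def compute_centroid(cluster: CallosalCluster, splenium_fraction: float = 0.2) -> Centroid:
    """Ray-fan origin: AP midpoint, at the inferior extent of the splenium.

    The splenium is taken as the posterior ``splenium_fraction`` of the
    cluster's anterior-posterior extent (posterior = smaller MNI y); the
    centroid z is the minimum z over its voxels. This origin sits slightly
    superior to a full-structure center of mass, keeping the inferior
    concavity below the ray fan.
    """
    if not 0 < splenium_fraction <= 1:
        raise ValueError("splenium_fraction must be in (0, 1]")
    y_min, y_max = cluster.ap_extent_mm
    y_cut = y_min + splenium_fraction * (y_max - y_min)
    iy, iz = np.nonzero(cluster.mask)
    ys = cluster.slice_ref.y_axis[iy]
    posterior = ys <= y_cut + 1e-9
    if not posterior.any():
        raise ValueError("posterior splenium region contains no cluster voxels")
    z_mm = float(cluster.slice_ref.z_axis[iz[posterior]].min())
    return Centroid(y_mm=float(0.5 * (y_min + y_max)), z_mm=z_mm)


@dataclass(frozen=True)
class RadialRay:
    """Samples of WM probability along one radial direction."""

    angle_deg: float
    radii_mm: np.ndarray
    probabilities: np.ndarray

    @property
    def intersects(self) -> bool:
        return bool(self.probabilities.max() >= self._threshold)

    _threshold: float = 0.5


class RayFan:
    """A full 360 deg fan of radial rays from the centroid.

    Acts as a sequence of :class:`RadialRay`; also retains the masked slice
    probabilities so that probability can be sampled along arbitrary
    (off-grid) ray angles for tip refinement.
    """

    def __init__(self, slc: WMSliceMap, masked_data: np.ndarray, centroid: Centroid,
                 angles_deg: np.ndarray, radii_mm: np.ndarray, probabilities: np.ndarray,
                 wm_threshold: float):
        self.slice_ref = slc
        self.masked_data = masked_data
        self.centroid = centroid
        self.angles_deg = angles_deg
        self.radii_mm = radii_mm
        self.probabilities = probabilities  # (n_angles, n_radii)
        self.wm_threshold = wm_threshold

    def __len__(self) -> int:
        return self.angles_deg.size

    def __getitem__(self, i: int) -> RadialRay:
        return RadialRay(angle_deg=float(self.angles_deg[i]), radii_mm=self.radii_mm,
                         probabilities=self.probabilities[i], _threshold=self.wm_threshold)

    @property
    def step_deg(self) -> float:
        return float(self.angles_deg[1] - self.angles_deg[0])

    @property
    def intersects(self) -> np.ndarray:
        return self.probabilities.max(axis=1) >= self.wm_threshold

    def sample_ray(self, angle_deg: float) -> np.ndarray:
        """Probabilities along an arbitrary-angle ray at the fan's radii."""
        d = _direction(angle_deg)
        pts = self.centroid.as_array[None, :] + self.radii_mm[:, None] * d[None, :]
        return self.slice_ref.sample(pts[:, 0], pts[:, 1], data=self.masked_data)


def cast_radial_rays(slc: WMSliceMap, cluster: CallosalCluster, centroid: Centroid,
                     step_deg: float = 1.65, sample_step_mm: float = 0.25,
                     wm_threshold: float = 0.5, dilate_mm: float = 2.0) -> RayFan:
    """Cast the 360 deg radial ray fan, sampling bilinear probabilities.

    Probabilities are taken from the slice masked to the cluster's support
    (plus a partial-volume rim), so detached structures elsewhere on the
    slice cannot perturb the medians. Rays whose maximum sampled
    probability stays below ``wm_threshold`` are marked non-intersecting.
    """
    if not (slc.y_axis[0] <= centroid.y_mm <= slc.y_axis[-1]
            and slc.z_axis[0] <= centroid.z_mm <= slc.z_axis[-1]):
        raise ValueError("centroid lies outside the slice grid")
    masked = cluster.support_probabilities(dilate_mm=dilate_mm)
    corners = np.array([[slc.y_axis[i], slc.z_axis[j]] for i in (0, -1) for j in (0, -1)])
    max_radius = float(np.linalg.norm(corners - centroid.as_array, axis=1).max())
    radii = np.arange(sample_step_mm, max_radius + sample_step_mm, sample_step_mm)
    angles = np.arange(0.0, 360.0, step_deg)
    dirs = _direction(angles)  # (n_angles, 2)
    pts = centroid.as_array[None, None, :] + radii[None, :, None] * dirs[:, None, :]
    probs = slc.sample(pts[..., 0].ravel(), pts[..., 1].ravel(), data=masked)
    probs = probs.reshape(angles.size, radii.size)
    return RayFan(slc, masked, centroid, angles, radii, probs, wm_threshold)


def weighted_median_point(fan: RayFan, center_angle_deg: float,
                          wedge_deg: float = 11.55) -> tuple[float, float]:
    """Squared-probability weighted-median WM location on the center ray.

    Samples of all fan rays within ``center_angle_deg`` +/- ``wedge_deg``/2
    are pooled; each sample is weighted by its probability squared; the
    returned point lies on the center ray at the weighted median radius
    (ties resolved to the smaller radius).
    """
    sel = _circular_distance_deg(fan.angles_deg, center_angle_deg) <= wedge_deg / 2 + 1e-9
    if not sel.any():
        raise ValueError("no rays inside the angular wedge")
    radii = np.tile(fan.radii_mm, int(sel.sum()))
    weights = (fan.probabilities[sel] ** 2).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("no WM probability mass inside the angular wedge")
    order = np.argsort(radii, kind="stable")
    cum = np.cumsum(weights[order])
    r_med = float(radii[order][np.searchsorted(cum, total / 2.0)])
    point = np.asarray(
        [fan.centroid.y_mm, fan.centroid.z_mm]) + r_med * _direction(center_angle_deg)
    return float(point[0]), float(point[1])


@dataclass
class MedianLine:
    """Ordered median-line anchors from the anterior to the posterior tip."""

    anchors: np.ndarray          # (n, 2) of (y_mm, z_mm)
    anchor_angles_deg: np.ndarray
    tangents: np.ndarray         # (n, 2) unit vectors
    centroid: Centroid
    x_offset_mm: float

    @property
    def n_anchors(self) -> int:
        return self.anchors.shape[0]


def _longest_circular_run(flags: np.ndarray) -> tuple[int, int]:
    """(start index, length) of the longest circular run of True values."""
    n = flags.size
    doubled = np.concatenate([flags, flags])
    best_start, best_len, run = 0, 0, 0
    for i in range(2 * n):
        if doubled[i]:
            run += 1
            if run > best_len and i - run + 1 < n:
                best_len, best_start = min(run, n), i - run + 1
        else:
            run = 0
    return best_start, best_len


def _refine_tip(fan: RayFan, inside_deg: float, outside_deg: float, tol: float = 0.01) -> float:
    """Bisect for the angle where the ray's max probability crosses threshold."""
    g = lambda a: fan.sample_ray(a).max() - fan.wm_threshold
    lo, hi = inside_deg, outside_deg  # g(lo) >= 0 > g(hi)
    if g(hi) >= 0:
        return hi
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) >= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_median_line(fan: RayFan, cluster: CallosalCluster, n_anchors: int = 50) -> MedianLine:
    """Interpolate weighted-median points at equal-angle anchor positions.

    Tip angles are the first/last intersecting ray angles refined by
    bisection on interpolated probability; anchors are ``n_anchors``
    equally spaced angles from the anterior tip to the posterior tip, with
    positions linearly interpolated from the per-ray weighted medians.
    """
    flags = fan.intersects
    n_hit = int(flags.sum())
    if n_hit < 3:
        raise ValueError(f"only {n_hit} rays intersect the callosum; need at least 3")
    if flags.all():
        raise ValueError("all rays intersect: no tips found (closed annulus?)")
    start, length = _longest_circular_run(flags)
    step = fan.step_deg
    run_angles = fan.angles_deg[start] + np.arange(length) * step  # unwrapped, increasing
    # Anterior end (larger +y direction cosine) first.
    if np.cos(np.deg2rad(run_angles[0])) < np.cos(np.deg2rad(run_angles[-1])):
        run_angles = run_angles[::-1]
    sign = np.sign(run_angles[-1] - run_angles[0]) or 1.0
    tip_ant = _refine_tip(fan, run_angles[0], run_angles[0] - sign * step)
    tip_post = _refine_tip(fan, run_angles[-1], run_angles[-1] + sign * step)
    support_angles = np.concatenate([[tip_ant], run_angles, [tip_post]])
    points = np.array([weighted_median_point(fan, a) for a in support_angles])
    anchor_angles = np.linspace(tip_ant, tip_post, n_anchors)
    xp = support_angles if sign > 0 else support_angles[::-1]
    fp = points if sign > 0 else points[::-1]
    xq = anchor_angles if sign > 0 else anchor_angles[::-1]
    ys = np.interp(xq, xp, fp[:, 0])
    zs = np.interp(xq, xp, fp[:, 1])
    if sign < 0:
        ys, zs = ys[::-1], zs[::-1]
    anchors = np.column_stack([ys, zs])
    grad = np.gradient(anchors, axis=0)
    norms = np.linalg.norm(grad, axis=1)
    tangents = grad / np.where(norms > 0, norms, 1.0)[:, None]
    return MedianLine(anchors=anchors, anchor_angles_deg=anchor_angles, tangents=tangents,
                      centroid=fan.centroid, x_offset_mm=fan.slice_ref.x_offset_mm)


def median_length(line: MedianLine, native_affine: np.ndarray | None = None
                  ) -> tuple[float, float]:
    """Internal callosal length: sum of gaps between consecutive anchors.

    Returns ``(mni_mm, native_mm)``; native length maps the anchors
    (embedded at the slice's x offset) through the inverse of the
    native->MNI affine before summing.
    """
    gaps = np.diff(line.anchors, axis=0)
    mni = float(np.linalg.norm(gaps, axis=1).sum())
    if native_affine is None:
        return mni, mni
    pts3 = np.column_stack([np.full(line.n_anchors, line.x_offset_mm), line.anchors])
    native_pts = apply_affine(np.linalg.inv(native_affine), pts3)
    native = float(np.linalg.norm(np.diff(native_pts, axis=0), axis=1).sum())
    return mni, native
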