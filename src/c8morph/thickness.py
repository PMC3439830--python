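"""Callosal thickness as the minimum probabilistic traversal distance.

Thickness at a median-line anchor is the length of the shortest line
segment across the callosum that passes through that anchor, where the
length of a segment is the 1D sum of interpolated WM probabilities along
it (times the sampling step). Summing probabilities sidesteps sub-voxel
boundary delineation, at the cost of a slight, reproducible underestimate
on blurred boundaries. The definition is fully local — no perpendicularity
constraint to the boundaries or the median line is imposed — and the
minimal segment tends to avoid residual fornix or vessel attachments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .extraction import CallosalCluster
from .image_io import WMSliceMap, apply_affine
from .median_geometry import MedianLine

log = logging.getLogger(__name__)

__all__ = [
    "TraversalParams",
    "ThicknessProfile",
    "traversal_length",
    "min_traversal_thickness",
    "thickness_profile",
]


@dataclass(frozen=True)
class TraversalParams:
    """Numerical controls of the traversal march and angular sweep.

    ``exit_threshold`` defaults to half the WM threshold; a march direction
    terminates only after ``exit_run`` consecutive sub-exit samples, so the
    partial-volume tail keeps being integrated before stopping. The default
    confirmation run of 10 samples (1 mm at the default step) integrates a
    Gaussian partial-volume tail of sigma <= 1 mm essentially completely
    (truncating at 3 samples was measured to bias thickness by about -2%
    at 0.5 mm blur), while still terminating inside any true gap wider
    than ``exit_run * ds_mm``.
    """

    sweep_step_deg: float = 1.0
    ds_mm: float = 0.1
    wm_threshold: float = 0.5
    exit_threshold: float | None = None
    exit_run: int = 10
    max_chord_mm: float = 25.0

    @property
    def exit_level(self) -> float:
        return self.wm_threshold / 2 if self.exit_threshold is None else self.exit_threshold

    @property
    def sweep_angles_deg(self) -> np.ndarray:
        return np.arange(0.0, 180.0, self.sweep_step_deg)


def _march(slc: WMSliceMap, data: np.ndarray, point: np.ndarray, dirs: np.ndarray,
           params: TraversalParams) -> tuple[np.ndarray, np.ndarray]:
    """March along +/- each direction, returning (sums, reach) per direction.

    ``sums`` holds the accumulated probability*ds for each half-segment
    (including the terminating sub-exit run); ``reach`` the distance
    marched. Non-terminating directions (no sub-exit run within
    ``max_chord_mm``) get NaN.
    """
    n_steps = int(np.ceil(params.max_chord_mm / params.ds_mm))
    t = (np.arange(n_steps) + 1) * params.ds_mm
    pts = point[None, None, :] + t[None, :, None] * dirs[:, None, :]
    probs = slc.sample(pts[..., 0].ravel(), pts[..., 1].ravel(), data=data)
    probs = probs.reshape(dirs.shape[0], n_steps)
    below = probs < params.exit_level
    run = below.astype(np.int32).copy()
    for k in range(1, params.exit_run):
        run[:, k:] += below[:, :-k]
    hit = run >= params.exit_run
    stop = np.argmax(hit, axis=1)  # index of last sample of the first sub-exit run
    ok = hit[np.arange(dirs.shape[0]), stop]
    cum = np.cumsum(probs, axis=1) * params.ds_mm
    sums = np.where(ok, cum[np.arange(dirs.shape[0]), stop], np.nan)
    reach = np.where(ok, t[stop], np.nan)
    return sums, reach


def _segment_lengths(slc: WMSliceMap, data: np.ndarray, point: np.ndarray,
                     angles_deg: np.ndarray, params: TraversalParams
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.deg2rad(angles_deg)
    dirs = np.stack([np.cos(a), np.sin(a)], axis=-1)
    p0 = float(slc.sample(point[0], point[1], data=data)[0])
    fwd, reach_f = _march(slc, data, point, dirs, params)
    bwd, reach_b = _march(slc, data, point, -dirs, params)
    lengths = fwd + bwd + p0 * params.ds_mm
    return lengths, reach_f, reach_b


def traversal_length(slc: WMSliceMap, point: tuple[float, float], angle_deg: float,
                     params: TraversalParams | None = None,
                     data: np.ndarray | None = None) -> float:
    """Probability-sum length of the segment through ``point`` at ``angle_deg``.

    The march proceeds in both directions at ``ds_mm`` steps, accumulating
    bilinear probability times step, and each direction terminates once the
    probability stays below the exit level for ``exit_run`` consecutive
    samples.
    """
    params = params or TraversalParams()
    src = slc.data if data is None else data
    pt = np.asarray(point, dtype=float)
    lengths, _, _ = _segment_lengths(slc, src, pt, np.atleast_1d(float(angle_deg)), params)
    if np.isnan(lengths[0]):
        raise RuntimeError(
            f"traversal at {angle_deg} deg did not terminate within {params.max_chord_mm} mm")
    return float(lengths[0])


def min_traversal_thickness(slc: WMSliceMap, anchor: tuple[float, float],
                            params: TraversalParams | None = None,
                            data: np.ndarray | None = None,
                            sweep_angles_deg: np.ndarray | None = None
                            ) -> tuple[float, float, np.ndarray]:
    """Minimum traversal length over the angular sweep through an anchor.

    Returns ``(thickness_mm, minimizing_angle_deg, endpoints)`` where
    ``endpoints`` is the (2, 2) array of the minimizing segment's reach
    points, used for native-space rescaling.
    """
    params = params or TraversalParams()
    src = slc.data if data is None else data
    pt = np.asarray(anchor, dtype=float)
    angles = params.sweep_angles_deg if sweep_angles_deg is None else sweep_angles_deg
    lengths, reach_f, reach_b = _segment_lengths(slc, src, pt, angles, params)
    if np.all(np.isnan(lengths)):
        raise RuntimeError("no traversal direction terminated within max_chord_mm")
    i = int(np.nanargmin(lengths))
    a = np.deg2rad(angles[i])
    d = np.array([np.cos(a), np.sin(a)])
    endpoints = np.array([pt + reach_f[i] * d, pt - reach_b[i] * d])
    return float(lengths[i]), float(angles[i]), endpoints


@dataclass
class ThicknessProfile:
    """Per-anchor minimum traversal thickness, in MNI and native space."""

    values_mm: np.ndarray
    values_native_mm: np.ndarray
    chosen_angles_deg: np.ndarray
    line: MedianLine = field(repr=False)

    @property
    def n_anchors(self) -> int:
        return self.values_mm.size


def thickness_profile(slc: WMSliceMap, line: MedianLine,
                      native_affine: np.ndarray | None = None,
                      cluster: CallosalCluster | None = None,
                      params: TraversalParams | None = None,
                      dilate_mm: float = 2.0,
                      max_failed_fraction: float = 0.1) -> ThicknessProfile:
    """Minimum traversal thickness at every median-line anchor.

    Native values rescale each minimizing segment by the ratio of its
    endpoint separation after and before mapping through the inverse of
    the native->MNI affine, applied to the probability-weighted length.
    Anchors whose sweep fails entirely become NaN; the profile aborts if
    more than ``max_failed_fraction`` of anchors fail.
    """
    params = params or TraversalParams()
    data = slc.data if cluster is None else cluster.support_probabilities(dilate_mm=dilate_mm)
    n = line.n_anchors
    values = np.full(n, np.nan)
    native = np.full(n, np.nan)
    angles = np.full(n, np.nan)
    inv_native = None if native_affine is None else np.linalg.inv(native_affine)
    for i in range(n):
        try:
            val, ang, endpoints = min_traversal_thickness(slc, line.anchors[i], params, data)
        except RuntimeError as exc:
            log.warning("anchor %d: %s", i, exc)
            continue
        values[i], angles[i] = val, ang
        if inv_native is None:
            native[i] = val
        else:
            pts3 = np.column_stack([np.full(2, line.x_offset_mm), endpoints])
            mapped = apply_affine(inv_native, pts3)
            mni_sep = np.linalg.norm(endpoints[1] - endpoints[0])
            nat_sep = np.linalg.norm(mapped[1] - mapped[0])
            native[i] = val * (nat_sep / mni_sep if mni_sep > 0 else 1.0)
    n_failed = int(np.isnan(values).sum())
    if n_failed > max_failed_fraction * n:
        raise RuntimeError(f"{n_failed}/{n} anchors failed thickness measurement")
    return ThicknessProfile(values_mm=values, values_native_mm=native,
                            chosen_angles_deg=angles, line=line)
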