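"""Isolation of the callosal white-matter cluster on a sagittal slice.

The callosum is found inside an MNI-space bounding box by dropping seed
points from the superior surface, growing supra-threshold connected
components, keeping the largest/longest cluster, and erasing inferior
branches (fornix, pericallosal artery remnants) under the mid body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image_io import WMSliceMap, WMVolume, apply_affine

log = logging.getLogger(__name__)

__all__ = [
    "BoundingBox",
    "CallosalCluster",
    "ExtractionError",
    "orientation_filter",
    "find_seeds",
    "grow_clusters",
    "select_callosal_cluster",
    "prune_inferior_branches",
    "extract_callosum",
]


class ExtractionError(RuntimeError):
    """Raised when no plausible callosal cluster can be isolated."""


@dataclass(frozen=True)
class BoundingBox:
    """MNI-space search window for the midsagittal callosum (mm).

    The default is a generous envelope of the callosal footprint in MNI
    space; it stands in for a probabilistic location prior.
    """

    y_range_mm: tuple[float, float] = (-55.0, 50.0)
    z_range_mm: tuple[float, float] = (-5.0, 40.0)

    def __post_init__(self) -> None:
        if self.y_range_mm[0] >= self.y_range_mm[1] or self.z_range_mm[0] >= self.z_range_mm[1]:
            raise ValueError("bounding box ranges must satisfy min < max")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


@dataclass
class CallosalCluster:
    """A connected set of supra-threshold voxels on one sagittal slice."""

    mask: np.ndarray
    slice_ref: WMSliceMap
    wm_threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.slice_ref.data.shape:
            raise ValueError("cluster mask shape does not match slice")
        if not self.mask.any():
            raise ValueError("cluster mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def member_probabilities(self) -> np.ndarray:
        return self.slice_ref.data[self.mask]

    @property
    def probability_mass(self) -> float:
        return float(self.member_probabilities.sum())

    @property
    def ap_extent_mm(self) -> tuple[float, float]:
        ys = self.slice_ref.y_axis[np.any(self.mask, axis=1)]
        return float(ys.min()), float(ys.max())

    @property
    def is_extent_mm(self) -> tuple[float, float]:
        zs = self.slice_ref.z_axis[np.any(self.mask, axis=0)]
        return float(zs.min()), float(zs.max())

    @property
    def ap_length_mm(self) -> float:
        lo, hi = self.ap_extent_mm
        return hi - lo

    def support_probabilities(self, dilate_mm: float = 2.0) -> np.ndarray:
        """Slice probabilities masked to the cluster plus a partial-volume rim.

        Sub-threshold boundary voxels adjacent to the cluster carry genuine
        partial-volume probability mass; a small dilation keeps it while
        still excluding detached structures.
        """
        dy, dz = self.slice_ref.spacing
        if dilate_mm <= 0:
            support = self.mask
        else:
            it = max(int(np.ceil(dilate_mm / min(dy, dz))), 1)
            support = ndimage.binary_dilation(self.mask, structure=_structure(8), iterations=it)
        return np.where(support, self.slice_ref.data, 0.0)


def _cone_directions(max_angle_deg: float, n_polar: int = 3, n_azimuth: int = 8) -> np.ndarray:
    """Unit directions quantizing the cone about the left-right (x) axis."""
    dirs = [np.array([1.0, 0.0, 0.0])]
    for theta in np.linspace(max_angle_deg / n_polar, max_angle_deg, n_polar):
        t = np.deg2rad(theta)
        for phi in np.linspace(0.0, 2 * np.pi, n_azimuth, endpoint=False):
            dirs.append(np.array([np.cos(t), np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi)]))
    return np.array(dirs)


def orientation_filter(vol: WMVolume, max_angle_deg: float = 45.0,
                       wm_threshold: float = 0.5, probe_radius_mm: float = 3.0) -> WMVolume:
    """Suppress WM voxels that cannot lie on a near-mediolateral fiber path.

    Callosal fibers cross the midline left-to-right, so every genuine
    callosal voxel sits on a locally linear supra-threshold path within
    ``max_angle_deg`` of the x axis. For each supra-threshold voxel,
    straight line probes of radius ``probe_radius_mm`` are tested over a
    quantized set of cone directions; the voxel is kept if any probe's mean
    probability reaches ``wm_threshold``.
    """
    if vol.data.ndim != 3:
        raise ValueError("orientation filter requires a 3D volume")
    if not 0 < max_angle_deg <= 90:
        raise ValueError("max_angle_deg must be in (0, 90]")
    idx = np.argwhere(vol.data >= wm_threshold)
    if idx.size == 0:
        return replace(vol, data=vol.data.copy())
    world = apply_affine(vol.affine, idx.astype(float))
    inv = np.linalg.inv(vol.affine)
    step = min(vol.voxel_spacing.min(), 1.0)
    offsets = np.arange(-probe_radius_mm, probe_radius_mm + step / 2, step)
    keep = np.zeros(len(idx), dtype=bool)
    for d in _cone_directions(max_angle_deg):
        todo = ~keep
        if not todo.any():
            break
        pts = world[todo, None, :] + offsets[None, :, None] * d[None, None, :]
        vox = apply_affine(inv, pts.reshape(-1, 3))
        probs = ndimage.map_coordinates(vol.data, vox.T, order=1, mode="constant", cval=0.0)
        means = probs.reshape(todo.sum(), offsets.size).mean(axis=1)
        keep[np.flatnonzero(todo)[means >= wm_threshold]] = True
    data = vol.data.copy()
    removed = idx[~keep]
    data[removed[:, 0], removed[:, 1], removed[:, 2]] = 0.0
    if removed.size:
        log.debug("orientation filter removed %d of %d supra-threshold voxels",
                  len(removed), len(idx))
    return replace(vol, data=data)


def find_seeds(slc: WMSliceMap, box: BoundingBox, wm_threshold: float) -> list[tuple[int, int]]:
    """Drop one seed per grid column from the superior edge of the box.

    Scanning downward from the box top, the first supra-threshold voxel in
    each column (fixed y) becomes a seed; columns with no supra-threshold
    voxel yield none.
    """
    if not 0 < wm_threshold < 1:
        raise ValueError("wm_threshold must be in (0, 1)")
    ysel = (slc.y_axis >= box.y_range_mm[0]) & (slc.y_axis <= box.y_range_mm[1])
    zsel = (slc.z_axis >= box.z_range_mm[0]) & (slc.z_axis <= box.z_range_mm[1])
    if not ysel.any() or not zsel.any():
        raise ValueError("bounding box does not intersect the slice grid")
    z_idx = np.flatnonzero(zsel)[::-1]  # superior -> inferior
    seeds = []
    for iy in np.flatnonzero(ysel):
        col = slc.data[iy, z_idx] >= wm_threshold
        hit = np.argmax(col)
        if col[hit]:
            seeds.append((int(iy), int(z_idx[hit])))
    return seeds


def grow_clusters(slc: WMSliceMap, seeds: list[tuple[int, int]], wm_threshold: float,
                  connectivity: int = 8) -> list[CallosalCluster]:
    """Grow seeded connected components of the supra-threshold mask.

    Multiple clusters are possible (disease, malformation, or a thin
    isthmus splitting the callosum in two); all seeded components are
    returned in scan order.
    """
    if not seeds:
        raise ValueError("no seed points supplied")
    mask = slc.data >= wm_threshold
    labels, _ = ndimage.label(mask, structure=_structure(connectivity))
    seed_labels = []
    for iy, iz in seeds:
        lab = labels[iy, iz]
        if lab and lab not in seed_labels:
            seed_labels.append(lab)
    return [CallosalCluster(mask=labels == lab, slice_ref=slc, wm_threshold=wm_threshold)
            for lab in seed_labels]


def select_callosal_cluster(clusters: list[CallosalCluster]) -> CallosalCluster:
    """Pick the longest (anterior-posterior), then largest, seeded cluster.

    Lexicographic key: AP extent length, voxel count, probability mass;
    remaining ties resolve to scan order.
    """
    if not clusters:
        raise ExtractionError("no callosum found in bounding box")
    best, best_key = None, None
    for c in clusters:  # first wins ties: strict comparison
        key = (c.ap_length_mm, c.n_voxels, c.probability_mass)
        if best is None or key > best_key:
            best, best_key = c, key
    return best


def _column_runs(col: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index runs of True values in a 1D mask."""
    padded = np.diff(np.concatenate([[0], col.astype(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def prune_inferior_branches(cluster: CallosalCluster,
                            midbody_y_range_mm: tuple[float, float] = (-30.0, 10.0),
                            connectivity: int = 8) -> CallosalCluster:
    """Erase branch runs hanging below the main body within the mid-body range.

    Within columns whose y falls in ``midbody_y_range_mm``: when a column's
    supra-threshold voxels split into two or more runs separated by
    sub-threshold gaps, every run strictly inferior to the superior-most run
    is removed (fornix adhesions attach from below). Connectivity is then
    re-checked and the main component kept. Branches outside the stated
    range are retained — a documented limitation.
    """
    slc = cluster.slice_ref
    mask = cluster.mask.copy()
    ysel = (slc.y_axis >= midbody_y_range_mm[0]) & (slc.y_axis <= midbody_y_range_mm[1])
    n_removed = 0
    for iy in np.flatnonzero(ysel):
        runs = _column_runs(mask[iy])
        if len(runs) >= 2:
            for start, stop in runs[:-1]:  # all runs below the superior-most
                mask[iy, start:stop] = False
                n_removed += stop - start
    if n_removed == 0:
        return cluster
    log.debug("pruned %d inferior-branch voxels", n_removed)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        raise ExtractionError("inferior-branch pruning removed the entire cluster")
    counts = np.bincount(labels.ravel())[1:]
    main = int(np.argmax(counts)) + 1
    return CallosalCluster(mask=labels == main, slice_ref=slc, wm_threshold=cluster.wm_threshold)


def refined_ap_extent(cluster: CallosalCluster, dilate_mm: float = 2.0) -> tuple[float, float]:
    """Sub-voxel anterior-posterior extent of the cluster.

    The per-column probability maximum is linearly interpolated to locate
    where it crosses the WM threshold at each end. This decouples the
    extent — and the partition cuts derived from it — from the voxel grid,
    so compartment boundaries stay put across resolutions and noise
    realizations.
    """
    slc = cluster.slice_ref
    probs = cluster.support_probabilities(dilate_mm=dilate_mm)
    m = probs.max(axis=1)
    thr = cluster.wm_threshold
    above = np.flatnonzero(m >= thr)
    if above.size == 0:
        raise ExtractionError("cluster has no supra-threshold columns")
    y = slc.y_axis

    def crossing(i_in: int, direction: int) -> float:
        i_out = i_in + direction
        if not 0 <= i_out < m.size or m[i_out] >= thr:
            return float(y[i_in])
        frac = (m[i_in] - thr) / (m[i_in] - m[i_out])
        return float(y[i_in] + frac * (y[i_out] - y[i_in]))

    return crossing(int(above[0]), -1), crossing(int(above[-1]), +1)


def extract_callosum(slc: WMSliceMap, box: BoundingBox | None = None,
                     wm_threshold: float = 0.5, connectivity: int = 8,
                     midbody_y_range_mm: tuple[float, float] = (-30.0, 10.0)) -> CallosalCluster:
    """Full in-plane extraction: seeds, growing, selection, branch pruning."""
    box = box or BoundingBox()
    seeds = find_seeds(slc, box, wm_threshold)
    if not seeds:
        raise ExtractionError("no supra-threshold voxels under the bounding box")
    clusters = grow_clusters(slc, seeds, wm_threshold, connectivity=connectivity)
    best = select_callosal_cluster(clusters)
    return prune_inferior_branches(best, midbody_y_range_mm, connectivity=connectivity)
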