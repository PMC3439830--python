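"""NIfTI I/O, affine handling, resampling and para-midsagittal slice extraction.

World coordinates are MNI millimetres, RAS+ (x right, y anterior, z superior).
Voxel indices are 0-based and world positions refer to voxel centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

log = logging.getLogger(__name__)

__all__ = [
    "WMVolume",
    "WMSliceMap",
    "load_wm_probability_volume",
    "save_wm_probability_volume",
    "load_affine_text",
    "resample_to_isotropic",
    "extract_parasagittal_slices",
]


@dataclass
class WMVolume:
    """A 3D white-matter probability volume in MNI space.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Per-voxel WM posterior probability, clamped to [0, 1].
    affine : ndarray, shape (4, 4)
        Voxel-index -> MNI-mm map.
    native_affine : ndarray, shape (4, 4)
        Native-mm -> MNI-mm affine spatial normalization transform. Identity
        when the image was acquired in (or rigidly aligned to) MNI space.
    """

    data: np.ndarray
    affine: np.ndarray
    native_affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.native_affine = np.asarray(self.native_affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim}D")
        _check_invertible(self.affine)
        _check_invertible(self.native_affine)

    @property
    def voxel_spacing(self) -> np.ndarray:
        """Column norms of the linear part: per-axis voxel size in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_bounds(self) -> np.ndarray:
        """(2, 3) array of min/max world coordinates over the voxel-center grid."""
        nx, ny, nz = self.data.shape
        corners = np.array(
            [[i, j, k] for i in (0, nx - 1) for j in (0, ny - 1) for k in (0, nz - 1)],
            dtype=float,
        )
        world = apply_affine(self.affine, corners)
        return np.vstack([world.min(axis=0), world.max(axis=0)])


@dataclass
class WMSliceMap:
    """A 2D sagittal probability map sampled at a fixed MNI x offset.

    ``data[i, j]`` is the WM probability at world position
    ``(x_offset_mm, y_axis[i], z_axis[j])``.
    """

    data: np.ndarray
    x_offset_mm: float
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.y_axis = np.asarray(self.y_axis, dtype=np.float64)
        self.z_axis = np.asarray(self.z_axis, dtype=np.float64)
        if self.data.shape != (self.y_axis.size, self.z_axis.size):
            raise ValueError("slice data shape does not match axes")
        if np.any(np.diff(self.y_axis) <= 0) or np.any(np.diff(self.z_axis) <= 0):
            raise ValueError("slice axes must be strictly increasing")

    @property
    def spacing(self) -> tuple[float, float]:
        return float(self.y_axis[1] - self.y_axis[0]), float(self.z_axis[1] - self.z_axis[0])

    @property
    def pixel_area_mm2(self) -> float:
        dy, dz = self.spacing
        return dy * dz

    def world_to_index(self, y_mm, z_mm) -> tuple[np.ndarray, np.ndarray]:
        """Continuous grid indices of world in-plane coordinates."""
        dy, dz = self.spacing
        iy = (np.asarray(y_mm, dtype=float) - self.y_axis[0]) / dy
        iz = (np.asarray(z_mm, dtype=float) - self.z_axis[0]) / dz
        return iy, iz

    def sample(self, y_mm, z_mm, data: np.ndarray | None = None) -> np.ndarray:
        """Bilinear probability at arbitrary in-plane world positions.

        Points outside the grid read as 0.
        """
        iy, iz = self.world_to_index(y_mm, z_mm)
        src = self.data if data is None else data
        return map_coordinates(src, [np.atleast_1d(iy), np.atleast_1d(iz)],
                               order=1, mode="constant", cval=0.0)


def _check_invertible(mat: np.ndarray) -> None:
    if mat.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if not np.all(np.isfinite(mat)) or np.linalg.cond(mat) > 1e12:
        raise ValueError("affine is singular or ill-conditioned")


def apply_affine(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a homogeneous 4x4 transform to an (n, 3) point array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ affine[:3, :3].T + affine[:3, 3]


def load_affine_text(path) -> np.ndarray:
    """Read a whitespace-separated 4x4 affine from a plain-text file."""
    mat = np.loadtxt(path)
    if mat.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}, got shape {mat.shape}")
    _check_invertible(mat)
    return mat


def load_wm_probability_volume(path, native_affine_path=None) -> WMVolume:
    """Load a WM probability NIfTI volume, normalizing values into [0, 1].

    Integer-scaled maps (values up to 255) are rescaled by 1/255 whenever the
    maximum exceeds 1.5; small interpolation overshoots are clamped.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several header/format errors
        raise IOError(f"unreadable NIfTI: {path}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D probability volume, got {data.ndim}D: {path}")
    if np.nanmax(data) > 1.5:
        log.info("rescaling %s by 1/255 (max value %.3g)", path, np.nanmax(data))
        data = data / 255.0
    n_out = int(np.count_nonzero((data < 0) | (data > 1)))
    if n_out > 0.01 * data.size:
        log.warning("%s: %.1f%% of voxels outside [0,1] were clamped",
                    path, 100.0 * n_out / data.size)
    data = np.clip(data, 0.0, 1.0)
    native = np.eye(4) if native_affine_path is None else load_affine_text(native_affine_path)
    return WMVolume(data=data, affine=np.asarray(img.affine), native_affine=native)


def save_wm_probability_volume(vol: WMVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def resample_to_isotropic(vol: WMVolume, spacing_mm: float) -> WMVolume:
    """Reslice onto an axis-aligned isotropic MNI grid by trilinear interpolation."""
    if spacing_mm <= 0:
        raise ValueError(f"spacing must be positive, got {spacing_mm}")
    lo, hi = vol.world_bounds()
    n = np.maximum(np.floor((hi - lo) / spacing_mm).astype(int) + 1, 1)
    new_affine = np.eye(4)
    new_affine[:3, :3] = np.eye(3) * spacing_mm
    new_affine[:3, 3] = lo
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in n), indexing="ij")
    world = apply_affine(new_affine, np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]))
    vox = apply_affine(np.linalg.inv(vol.affine), world)
    new_data = map_coordinates(vol.data, vox.T, order=1, mode="constant", cval=0.0)
    new_data = np.clip(new_data.reshape(tuple(n)), 0.0, 1.0)
    return replace(vol, data=new_data, affine=new_affine)


def extract_parasagittal_slices(vol: WMVolume, offsets_mm=(-1.0, 0.0, 1.0)) -> list[WMSliceMap]:
    """Sample para-midsagittal slices at stated MNI x offsets.

    Each slice is trilinearly resampled onto a regular (y, z) grid at the
    volume's in-plane spacing, so oblique affines are handled uniformly.
    """
    lo, hi = vol.world_bounds()
    _, dy, dz = vol.voxel_spacing
    y_axis = np.arange(lo[1], hi[1] + dy / 2, dy)
    z_axis = np.arange(lo[2], hi[2] + dz / 2, dz)
    inv = np.linalg.inv(vol.affine)
    yy, zz = np.meshgrid(y_axis, z_axis, indexing="ij")
    out = []
    for x0 in offsets_mm:
        if not (lo[0] - 1e-9 <= x0 <= hi[0] + 1e-9):
            raise ValueError(
                f"slice offset x={x0} mm outside volume x-range [{lo[0]:.1f}, {hi[0]:.1f}]")
        world = np.column_stack([np.full(yy.size, x0), yy.ravel(), zz.ravel()])
        vox = apply_affine(inv, world)
        data = map_coordinates(vol.data, vox.T, order=1, mode="constant", cval=0.0)
        data = np.clip(data.reshape(yy.shape), 0.0, 1.0)
        out.append(WMSliceMap(data=data, x_offset_mm=float(x0), y_axis=y_axis, z_axis=z_axis))
    return out
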