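"""Volume container, NIfTI I/O, grid geometry and resampling.

Every image in the package is an :class:`ImageVolume`: a 3D scalar array on
an axis-aligned grid in a RAS-like world (x = left->right, y =
posterior->anterior, z = inferior->superior, mm).  Inputs are reoriented to
this convention on load so the three orthogonal acquisitions share one
coordinate frame.  Voxel centers define grid coordinates; the world
position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .transforms import RigidTransform

AXES_RAS = ("X", "Y", "Z")

_INTERP_ORDERS = {"nearest": 0, "trilinear": 1, "cubic": 3}


class FormatError(ValueError):
    """Raised for unreadable or unsupported image files."""


@dataclass
class GridSpec:
    """Regular 3D voxel grid: counts, mm spacing and mm origin per axis."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be >= 1 per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge length per axis in mm (shape x spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-center world coordinates."""
        return tuple(self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                     for a in range(3))

    def center(self) -> np.ndarray:
        """World coordinate of the grid center (mm)."""
        return np.array([self.origin[a] + self.spacing[a] * (self.shape[a] - 1) / 2.0
                         for a in range(3)])

    @classmethod
    def like(cls, vol: "ImageVolume") -> "GridSpec":
        return cls(shape=vol.data.shape, spacing=vol.spacing, origin=vol.origin)

    def isotropic(self, spacing: float) -> "GridSpec":
        """Isotropic grid covering the same physical extent (voxel-edge aligned)."""
        ext = self.extent
        shape = tuple(max(1, int(np.floor(e / spacing + 1e-9))) for e in ext)
        # first fine edge is at origin - old_spacing/2; center first new voxel there
        origin = tuple(self.origin[a] - self.spacing[a] / 2.0 + spacing / 2.0
                       for a in range(3))
        return GridSpec(shape=shape, spacing=(spacing,) * 3, origin=origin)


@dataclass
class ImageVolume:
    """3D scalar image on an axis-aligned RAS grid.

    Attributes
    ----------
    data : ndarray
        Intensities (arbitrary units; non-negative for magnitude images).
    spacing : tuple of float
        Voxel size in mm per array axis.
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    axes : tuple of str
        Mapping of array axes to anatomical axes; always ``("X","Y","Z")``
        after loading, kept for interface completeness.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: tuple[str, str, str] = AXES_RAS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"volume must be 3D, got {self.data.ndim}D shape {self.data.shape}")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"every axis needs >= 1 voxel, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if sorted(self.axes) != sorted(AXES_RAS):
            raise ValueError(f"axes must be a permutation of {AXES_RAS}, got {self.axes}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.like(self)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points of shape (3, N)."""
        pts = np.asarray(points, dtype=float)
        o = np.asarray(self.origin)[:, None]
        s = np.asarray(self.spacing)[:, None]
        return (pts - o) / s

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data=data, spacing=self.spacing,
                           origin=self.origin, axes=self.axes)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_nifti(path) -> ImageVolume:
    """Read a 3D NIfTI-1 file and reorient it to the internal RAS convention.

    The header affine fully determines geometry; images stored in other
    orientations (e.g. LPS) are flipped/permuted on load so a world point
    refers to the same tissue regardless of on-disk layout.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise FormatError(
            f"expected a 3D image, got {img.ndim}D shape {img.shape} in {path}")
    img = nib.as_closest_canonical(img)
    affine = img.affine
    rot = affine[:3, :3]
    spacing = np.sqrt((rot ** 2).sum(axis=0))
    if np.max(np.abs(rot - np.diag(np.diag(rot)))) > 1e-3 * spacing.min():
        raise FormatError(
            f"oblique affines are not supported (off-diagonal terms in {path})")
    data = np.asarray(img.dataobj, dtype=np.float32)
    return ImageVolume(data=data,
                       spacing=tuple(float(s) for s in np.diag(rot)[:3]),
                       origin=tuple(float(v) for v in affine[:3, 3]))


def write_nifti(vol: ImageVolume, path) -> None:
    """Write a volume as single-file NIfTI-1 (32-bit float)."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm")
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write NIfTI file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(vol: ImageVolume,
             transform: RigidTransform,
             target: GridSpec,
             interpolation: str = "trilinear",
             ) -> tuple[ImageVolume, np.ndarray]:
    """Resample ``vol`` onto ``target``, pulling intensities through ``transform``.

    ``transform`` maps target-grid world points into the source volume's
    world frame: ``out(x) = vol(transform(x))``.  Voxels that map outside
    the source extent are zero-filled and flagged False in the returned
    validity mask so downstream averaging and fitting can exclude them.

    Returns
    -------
    (ImageVolume, ndarray of bool)
        The resampled volume on ``target`` and its validity mask.
    """
    if interpolation not in _INTERP_ORDERS:
        raise ValueError(
            f"unknown interpolation {interpolation!r}; "
            f"expected one of {sorted(_INTERP_ORDERS)}")
    order = _INTERP_ORDERS[interpolation]

    xs, ys, zs = target.world_coordinates()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()])
    src_pts = transform.apply(pts)
    idx = vol.world_to_index(src_pts)

    shape = np.asarray(vol.data.shape, dtype=float)
    inside = np.ones(idx.shape[1], dtype=bool)
    for a in range(3):
        inside &= (idx[a] >= -1e-6) & (idx[a] <= shape[a] - 1 + 1e-6)
        # a round-off hair outside the grid would otherwise be cval-filled
        np.clip(idx[a], 0.0, shape[a] - 1, out=idx[a])

    out = map_coordinates(np.asarray(vol.data, dtype=np.float64), idx,
                          order=order, mode="constant", cval=0.0,
                          prefilter=(order > 1))
    out[~inside] = 0.0
    out = out.reshape(target.shape)
    mask = inside.reshape(target.shape)
    res = ImageVolume(data=out, spacing=target.spacing, origin=target.origin)
    return res, mask
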