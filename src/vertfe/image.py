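"""CT-like scalar volumes and label masks on a regular grid.

Grid convention
---------------
A volume is a 3D array of Hounsfield units (HU) on a regular grid with
per-axis spacing (mm) and an origin (mm).  The world coordinate of the
*center* of voxel ``(i, j, k)`` is ``origin + (i + 0.5, j + 0.5, k + 0.5) *
spacing``; voxel ``(i, j, k)`` therefore occupies the axis-aligned box
``[origin + (i,j,k)*spacing, origin + (i+1,j+1,k+1)*spacing]``.  Axis 2 (z)
is the superior–inferior axis of the vertebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "element_mean_hu",
]


@dataclass
class ImageVolume:
    """3D scalar field of Hounsfield units with grid geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.values.copy(), self.spacing, self.origin)


@dataclass
class LabelMask:
    """Integer labels on the same grid as a paired :class:`ImageVolume`.

    0 = background, 1 = vertebral body, 2 = posterior elements.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={self.labels.ndim}")
        if self.labels.dtype.kind not in "iu":
            raise ValueError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def check_grid(self, img: ImageVolume) -> None:
        if self.shape != img.shape:
            raise ValueError(f"mask shape {self.shape} != image shape {img.shape}")

    def copy(self) -> "LabelMask":
        return LabelMask(self.labels.copy(), self.spacing, self.origin)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(img: ImageVolume, path) -> None:
    """Write a volume as NIfTI with spacing/origin encoded in the affine."""
    nii = nib.Nifti1Image(img.values.astype(np.float64), _affine(img.spacing, img.origin))
    nii.header.set_zooms(img.spacing)
    nib.save(nii, str(path))


def read_volume(path) -> ImageVolume:
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, file has ndim={data.ndim}")
    zooms = tuple(float(z) for z in nii.header.get_zooms()[:3])
    origin = tuple(float(o) for o in nii.affine[:3, 3])
    return ImageVolume(np.asarray(data, dtype=np.float64), zooms, origin)


def write_mask(mask: LabelMask, path) -> None:
    nii = nib.Nifti1Image(mask.labels.astype(np.uint8), _affine(mask.spacing, mask.origin))
    nii.header.set_zooms(mask.spacing)
    nib.save(nii, str(path))


def read_mask(path) -> LabelMask:
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, file has ndim={data.ndim}")
    zooms = tuple(float(z) for z in nii.header.get_zooms()[:3])
    origin = tuple(float(o) for o in nii.affine[:3, 3])
    return LabelMask(np.asarray(data).astype(np.uint8), zooms, origin)


def _tet_volume(verts: np.ndarray) -> float:
    d = verts[1:] - verts[0]
    return float(np.linalg.det(d)) / 6.0


def element_mean_hu(img: ImageVolume, tet_vertices: np.ndarray) -> float:
    """Mean HU of voxels whose centers fall inside a tetrahedron.

    Falls back to the HU at the voxel nearest the centroid when no voxel
    center is contained (elements smaller than one voxel).  Raises on
    degenerate (zero-volume) tetrahedra and on tetrahedra that extend
    outside the image bounds (a symptom of a meshing bug, not clamped).
    """
    verts = np.asarray(tet_vertices, dtype=np.float64)
    if verts.shape != (4, 3):
        raise ValueError(f"expected 4x3 vertex array, got {verts.shape}")
    scale = max(np.ptp(verts, axis=0).max(), 1e-30)
    if abs(_tet_volume(verts)) < 1e-12 * scale**3:
        raise ValueError("degenerate (zero-volume) tetrahedron")

    origin = np.asarray(img.origin)
    spacing = np.asarray(img.spacing)
    shape = np.asarray(img.shape)
    lo_world = origin
    hi_world = origin + shape * spacing
    eps = 1e-9 * spacing
    if np.any(verts < lo_world - eps) or np.any(verts > hi_world + eps):
        raise ValueError("tetrahedron extends outside the image bounds")

    bb_lo = verts.min(axis=0)
    bb_hi = verts.max(axis=0)
    i_lo = np.maximum(np.floor((bb_lo - origin) / spacing - 0.5).astype(int), 0)
    i_hi = np.minimum(np.ceil((bb_hi - origin) / spacing - 0.5).astype(int), shape - 1)

    if np.all(i_lo <= i_hi):
        ii, jj, kk = np.meshgrid(
            np.arange(i_lo[0], i_hi[0] + 1),
            np.arange(i_lo[1], i_hi[1] + 1),
            np.arange(i_lo[2], i_hi[2] + 1),
            indexing="ij",
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        centers = origin + (idx + 0.5) * spacing
        lam = np.linalg.solve(
            (verts[1:] - verts[0]).T, (centers - verts[0]).T
        ).T  # barycentric coords w.r.t. vertices 1..3
        tol = 1e-12
        inside = np.all(lam >= -tol, axis=1) & (lam.sum(axis=1) <= 1.0 + tol)
        if inside.any():
            sel = idx[inside]
            return float(img.values[sel[:, 0], sel[:, 1], sel[:, 2]].mean())

    centroid = verts.mean(axis=0)
    near = np.clip(np.round((centroid - origin) / spacing - 0.5).astype(int), 0, shape - 1)
    return float(img.values[near[0], near[1], near[2]])
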