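"""Volumetric grid container and NIfTI-1 I/O.

Conventions used throughout the package (stated once, enforced here):

* voxel indices are 0-based and ordered ``(i, j, k)`` = ``(x, y, z)``;
* physical coordinates are in millimetres and follow the NIfTI affine
  (here always a diagonal scaling plus origin — no oblique orientations);
* the anterior direction is +y, so the chest wall is a surface of the
  form ``y = f(x, z)`` and the breasts extend toward larger ``y``;
* all masks live on the pre-contrast grid and are never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = ["VolumeGrid", "read_volume", "write_volume", "dice"]


@dataclass
class VolumeGrid:
    """A 3-D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz)``; finite values.
    spacing:
        Voxel size in mm per axis, strictly positive.
    origin:
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def same_grid(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data, self.spacing, self.origin)

    # --- physical-coordinate helpers -------------------------------------
    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    # --- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        # SimpleITK's array interface is (z, y, x); ours is (x, y, z).
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VolumeGrid":
        data = sitk.GetArrayFromImage(img).T
        return cls(np.ascontiguousarray(data), tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def read_volume(path: str | Path) -> VolumeGrid:
    """Load a NIfTI volume; spacing and origin are taken from the affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    return VolumeGrid(data, spacing, origin)


def write_volume(volume: VolumeGrid, path: str | Path, dtype=np.float32) -> Path:
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        img = nib.Nifti1Image(volume.data.astype(dtype), volume.affine)
        nib.save(img, str(path))
    except OSError as exc:  # surface the offending path
        raise OSError(f"failed to write volume to {path}: {exc}") from exc
    return path


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
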