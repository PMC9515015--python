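"""Axis-aligned 3D image volumes (activity, attenuation, labels, reconstructions).

Array index (i, j, k) maps to world millimetres as
``world = origin + index * spacing`` (voxel centers; axes never rotated —
rigid alignment is carried by explicit :class:`~facemoco.transforms.RigidTransform`
objects, not by the volume header).  NIfTI I/O keeps spacing/origin in the
affine.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .transforms import RigidTransform

__all__ = ["ImageVolume", "centered_origin"]


def centered_origin(shape: Sequence[int], spacing: Sequence[float]) -> np.ndarray:
    """Origin that centers the grid on the world origin (isocenter)."""
    shape = np.asarray(shape, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    return -(shape - 1.0) / 2.0 * spacing


@dataclasses.dataclass
class ImageVolume:
    values: np.ndarray
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray   # (3,) mm, world position of voxel (0,0,0) center

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D array, got ndim={self.values.ndim}")
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("non-finite voxel values")

    # -- geometry ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def voxel_center_grid(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world coordinates of all voxel centers."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy_with(self, values: np.ndarray) -> "ImageVolume":
        return ImageVolume(values, self.spacing.copy(), self.origin.copy())

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    # -- sampling ------------------------------------------------------

    def sample_world(self, pts: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate values at world points (trilinear by default, zero outside)."""
        idx = self.world_to_index(np.atleast_2d(pts)).T
        return ndimage.map_coordinates(
            self.values.astype(float), idx, order=order, mode="constant", cval=0.0
        )

    def resample_like(
        self,
        target: "ImageVolume",
        transform: RigidTransform | None = None,
        order: int = 1,
    ) -> "ImageVolume":
        """Resample onto ``target``'s grid, optionally under a rigid transform.

        ``transform`` maps *this* volume's world frame into the target world
        frame (value looked up at transform^-1 of each target voxel center).
        Nearest-neighbour (``order=0``) is appropriate for label volumes.
        """
        Tinv = np.eye(4) if transform is None else transform.inverse().matrix
        # target index -> target world -> source world -> source index
        A = np.diag(np.append(self.spacing, 1.0))
        A[:3, 3] = self.origin
        B = np.diag(np.append(target.spacing, 1.0))
        B[:3, 3] = target.origin
        M = np.linalg.inv(A) @ Tinv @ B  # target idx -> source idx
        out = ndimage.affine_transform(
            self.values.astype(float),
            M[:3, :3],
            offset=M[:3, 3],
            output_shape=target.shape,
            order=order,
            mode="constant",
            cval=0.0,
        )
        if order == 0:
            out = out.astype(self.values.dtype)
        return ImageVolume(out, target.spacing.copy(), target.origin.copy())

    # -- I/O -----------------------------------------------------------

    def to_nifti(self, path: str) -> None:
        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)
        img.header.set_zooms(tuple(self.spacing))
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "ImageVolume":
        img = nib.load(path)
        affine = img.affine
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        return cls(np.asarray(img.dataobj, dtype=np.float32), spacing, affine[:3, 3])
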