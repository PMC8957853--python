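"""Voxel-grid containers shared across the pipeline.

A :class:`LabelVolume` is a 3D integer label grid together with the affine
that maps 0-based voxel indices to world coordinates in RAS millimetres.
All grids produced by this package use axis-aligned (diagonal, positive)
affines; general affines are accepted on input but some operations
(sectioning, voxel volumetry) require the axis-aligned form and say so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["LabelVolume", "make_grid", "read_label_volume", "write_label_volume"]


@dataclass
class LabelVolume:
    """3D integer label grid with voxel-to-world affine (RAS mm).

    Parameters
    ----------
    labels : ndarray of int, shape (nx, ny, nz)
        Structure labels; 0 is background.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-mm affine. Must be invertible.
    space_id : str
        Identifier of the coordinate space the world coordinates live in
        (e.g. a subject id for native histological space, or the name of
        the common reference space).
    """

    labels: np.ndarray
    affine: np.ndarray
    space_id: str = "native"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    # -- geometry helpers -------------------------------------------------

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def is_axis_aligned(self) -> bool:
        lin = self.affine[:3, :3]
        return bool(np.allclose(lin, np.diag(np.diag(lin))) and np.all(np.diag(lin) > 0))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis (axis-aligned grids)."""
        if not self.is_axis_aligned:
            raise ValueError("axis_coordinates requires an axis-aligned affine")
        n = self.labels.shape[axis]
        return self.affine[axis, 3] + self.affine[axis, axis] * np.arange(n)

    def mask(self, labels: int | list[int]) -> np.ndarray:
        """Binary mask of one label or the union of several."""
        labs = np.atleast_1d(labels)
        return np.isin(self.labels, labs)


def make_grid(
    origin: tuple[float, float, float],
    shape: tuple[int, int, int],
    voxel_size: float | tuple[float, float, float],
    space_id: str = "native",
    dtype=np.int16,
) -> LabelVolume:
    """Allocate an empty axis-aligned label grid.

    ``origin`` is the world coordinate of the centre of voxel (0, 0, 0).
    """
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if np.any(vs <= 0):
        raise ValueError("voxel_size must be positive")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = origin
    return LabelVolume(np.zeros(shape, dtype=dtype), affine, space_id)


def write_label_volume(volume: LabelVolume, path) -> None:
    """Write a label volume as NIfTI-1 (int16, RAS affine)."""
    img = nib.Nifti1Image(volume.labels.astype(np.int16), volume.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_label_volume(path, space_id: str = "native") -> LabelVolume:
    """Read a NIfTI-1 label image into a :class:`LabelVolume`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: voxel values are not integer labels")
        data = rounded.astype(np.int16)
    return LabelVolume(data, img.affine, space_id)
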