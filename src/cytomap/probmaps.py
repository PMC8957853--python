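"""3D reconstruction from sparse sections and probabilistic overlap maps.

The delineations of a structure exist only on every k-th section; this
module rebuilds a full 3D binary volume from such a sparse stack (either by
block-filling each sampled slab or by shape-based interpolation of signed
distance transforms), resamples the per-subject volumes into a common
reference grid through the known subject-to-reference affines, and
superimposes the cohort into a voxel-wise overlap map: the percentage of
subjects whose delineation covers each reference voxel (0-100%). For ten
subjects the map takes values 0, 10, ..., 100 — 10% means a single brain,
100% means all ten.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grid import LabelVolume, make_grid
from .sectioning import SectionStack

__all__ = [
    "ProbabilityMap",
    "CenterOfMass",
    "stack_to_volume",
    "to_reference",
    "compute_probability_map",
    "center_of_mass",
    "threshold_map",
    "write_probability_map",
    "read_probability_map",
]


@dataclass
class ProbabilityMap:
    """Voxel-wise overlap map of one structure over ``n_subjects`` brains.

    ``counts`` stores the exact per-voxel subject counts; the integer
    percent grid is derived on access so that no rounding error accumulates
    internally.
    """

    structure: str
    counts: np.ndarray       # int grid, 0..n_subjects
    n_subjects: int
    affine: np.ndarray
    space_id: str = "reference"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.counts.min() < 0 or self.counts.max() > self.n_subjects:
            raise ValueError("counts must lie in [0, n_subjects]")

    @property
    def fraction(self) -> np.ndarray:
        """Exact overlap fraction in [0, 1]."""
        return self.counts / self.n_subjects

    @property
    def percent(self) -> np.ndarray:
        """Integer overlap percentage 0-100 (rounded)."""
        return np.rint(100.0 * self.counts / self.n_subjects).astype(np.uint8)


@dataclass
class CenterOfMass:
    structure: str
    hemisphere: str          # "left" | "right" | "both"
    x: int
    y: int
    z: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.x, self.y, self.z)


def _signed_distance(mask: np.ndarray, sampling) -> np.ndarray:
    """Signed distance in mm: negative inside the mask, positive outside."""
    big = float(np.sum(np.asarray(mask.shape) * np.asarray(sampling)))
    if not mask.any():
        return np.full(mask.shape, big)
    if mask.all():
        return np.full(mask.shape, -big)
    outside = ndimage.distance_transform_edt(~mask, sampling=sampling)
    inside = ndimage.distance_transform_edt(mask, sampling=sampling)
    return outside - inside


def stack_to_volume(stack: SectionStack,
                    interpolation: str = "block") -> LabelVolume:
    """Rebuild a full binary label volume from a sparse section stack.

    ``block`` assigns every elementary section the mask of its nearest
    sampled section (each sampled mask fills the d-thick slab it
    represents). ``shape_based`` linearly blends the signed distance
    transforms of consecutive sampled masks and thresholds at zero,
    recovering smoothly varying boundaries between sections. The output
    grid has one plane per elementary section (pitch = stack thickness).
    """
    if interpolation not in ("block", "shape_based"):
        raise ValueError("interpolation must be 'block' or 'shape_based'")
    if not stack.sections:
        raise ValueError("cannot reconstruct from a stack with no sections")
    if interpolation == "shape_based" and len(stack.sections) == 1:
        warnings.warn("single-section stack: shape_based interpolation "
                      "falls back to block", stacklevel=2)
        interpolation = "block"

    sampled_idx = np.array([s.index for s in stack.sections])
    masks = [s.mask for s in stack.sections]
    inplane_shape = masks[0].shape
    n_planes = int(sampled_idx[-1] - sampled_idx[0]) + 1
    first = int(sampled_idx[0])

    planes = np.zeros((n_planes,) + inplane_shape, dtype=bool)
    if interpolation == "block":
        for j in range(n_planes):
            i = first + j
            nearest = int(np.argmin(np.abs(sampled_idx - i)))
            planes[j] = masks[nearest]
    else:
        sdfs = [_signed_distance(m, stack.pixel_size) for m in masks]
        empty = [not m.any() for m in masks]
        for seg in range(len(masks) - 1):
            i0, i1 = int(sampled_idx[seg]), int(sampled_idx[seg + 1])
            if empty[seg] != empty[seg + 1]:
                # the structure ends inside this gap; a blend against the
                # empty section's unbounded distance would extinguish it
                # immediately, so fill block-wise (nearest mask) instead
                for i in range(i0, i1 + 1):
                    nearest = seg if (i - i0) <= (i1 - i) else seg + 1
                    planes[i - first] = masks[nearest]
                continue
            for i in range(i0, i1 + 1):
                w = (i - i0) / (i1 - i0)
                sdf = (1.0 - w) * sdfs[seg] + w * sdfs[seg + 1]
                planes[i - first] = sdf < 0
        planes[0] = masks[0]
        planes[-1] = masks[-1]

    # assemble the 3D grid: elementary-plane axis back into position
    axis = stack.axis
    labels = np.moveaxis(planes, 0, axis).astype(np.int16)
    inplane_axes = [a for a in range(3) if a != axis]
    vs = np.empty(3)
    vs[axis] = stack.thickness
    vs[inplane_axes[0]], vs[inplane_axes[1]] = stack.pixel_size
    origin = np.empty(3)
    origin[axis] = stack.plane_origin + first * stack.thickness
    origin[inplane_axes[0]], origin[inplane_axes[1]] = stack.inplane_origin
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = origin
    return LabelVolume(labels, affine, stack.space_id)


def to_reference(volume: LabelVolume,
                 transform: np.ndarray,
                 reference_grid: LabelVolume,
                 labels: int | list[int] | None = None) -> np.ndarray:
    """Resample a structure mask into the reference grid (nearest neighbour).

    Each reference voxel centre is pulled back through the inverse of
    ``transform`` (subject mm -> reference mm) into the subject grid and
    assigned the label of the nearest subject voxel — label identity is
    never blended. Returns a boolean mask on the reference grid.
    """
    transform = np.asarray(transform, dtype=float)
    if abs(np.linalg.det(transform)) < 1e-12:
        raise ValueError("transform must be invertible")
    mask = volume.mask(labels) if labels is not None else volume.labels > 0

    shape = reference_grid.labels.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world_ref = reference_grid.index_to_world(idx)
    inv = np.linalg.inv(transform)
    world_subj = world_ref @ inv[:3, :3].T + inv[:3, 3]
    subj_idx = np.rint(volume.world_to_index(world_subj)).astype(int)
    inb = np.all((subj_idx >= 0) & (subj_idx < np.asarray(volume.labels.shape)),
                 axis=1)
    out = np.zeros(idx.shape[0], dtype=bool)
    sel = subj_idx[inb]
    out[inb] = mask[sel[:, 0], sel[:, 1], sel[:, 2]]
    out = out.reshape(shape)
    if mask.any() and not out.any():
        raise ValueError(
            f"structure of {volume.space_id} maps entirely outside the "
            "reference grid")
    return out


def compute_probability_map(masks: list[np.ndarray | LabelVolume],
                            reference_grid: LabelVolume,
                            structure: str = "structure") -> ProbabilityMap:
    """Superimpose per-subject reference-space masks into an overlap map.

    ``percent(v) = round(100 * count of masks containing v / n)``.
    """
    if not masks:
        raise ValueError("need at least one subject mask")
    arrs = []
    for m in masks:
        if isinstance(m, LabelVolume):
            if m.labels.shape != reference_grid.labels.shape or \
                    not np.allclose(m.affine, reference_grid.affine):
                raise ValueError("all masks must share the reference grid")
            arrs.append(m.labels > 0)
        else:
            a = np.asarray(m)
            if a.shape != reference_grid.labels.shape:
                raise ValueError("all masks must share the reference grid")
            arrs.append(a.astype(bool))
    counts = np.sum(arrs, axis=0).astype(np.int32)
    return ProbabilityMap(structure=structure, counts=counts,
                          n_subjects=len(arrs), affine=reference_grid.affine,
                          space_id=reference_grid.space_id)


def _hemisphere_selector(pmap: ProbabilityMap, hemisphere: str | None):
    shape = pmap.counts.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    world = idx @ pmap.affine[:3, :3].T + pmap.affine[:3, 3]
    if hemisphere is None or hemisphere == "both":
        keep = np.ones(world.shape[0], dtype=bool)
    elif hemisphere == "left":
        keep = world[:, 0] < 0
    elif hemisphere == "right":
        keep = world[:, 0] > 0
    else:
        raise ValueError("hemisphere must be 'left', 'right' or 'both'")
    return world, keep


def center_of_mass(pmap: ProbabilityMap, hemisphere: str | None = None,
                   weighted: bool = True) -> CenterOfMass:
    """Overlap-weighted mean world coordinate of the map, rounded to mm.

    With ``weighted=False`` every covered voxel (overlap > 0) counts
    equally (binarised centre).
    """
    world, keep = _hemisphere_selector(pmap, hemisphere)
    w = pmap.fraction.reshape(-1).astype(float)
    if not weighted:
        w = (w > 0).astype(float)
    w = w * keep
    total = w.sum()
    if total == 0:
        raise ValueError(
            f"probability map of {pmap.structure} is empty in "
            f"hemisphere={hemisphere!r}")
    com = (world * w[:, None]).sum(axis=0) / total
    x, y, z = (int(np.rint(c)) for c in com)
    return CenterOfMass(structure=pmap.structure,
                        hemisphere=hemisphere or "both", x=x, y=y, z=z)


def threshold_map(pmap: ProbabilityMap, t_percent: float) -> np.ndarray:
    """Binary mask of voxels with overlap >= t_percent (0 keeps any overlap
    and 100 keeps only the intersection of all subjects)."""
    if not 0 <= t_percent <= 100:
        raise ValueError("threshold must lie in [0, 100]")
    if t_percent == 0:
        return pmap.counts > 0
    return 100.0 * pmap.fraction >= t_percent


def write_probability_map(pmap: ProbabilityMap, path) -> None:
    """Export as NIfTI-1 uint8 percent map with the reference affine."""
    img = nib.Nifti1Image(pmap.percent, pmap.affine)
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = f"{pmap.structure} overlap % of {pmap.n_subjects}"
    nib.save(img, str(path))


def read_probability_map(path, n_subjects: int,
                         structure: str = "structure") -> ProbabilityMap:
    """Read a percent map written by :func:`write_probability_map`.

    Counts are recovered from the integer percents; exact for the n-step
    percent lattice produced by :func:`compute_probability_map`.
    """
    img = nib.load(str(path))
    percent = np.asarray(img.dataobj).astype(float)
    counts = np.rint(percent * n_subjects / 100.0).astype(np.int32)
    return ProbabilityMap(structure=structure, counts=counts,
                          n_subjects=n_subjects, affine=img.affine)
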