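"""Serial sectioning of label volumes and sparse section sampling.

Real histological processing cuts the paraffin-embedded brain into serial
coronal sections of 20 μm thickness and stains/delineates every 15th one,
i.e. delineations sit on a lattice with inter-section distance
d = k * T = 15 * 0.020 mm = 0.300 mm. This module emulates that design on a
voxel grid: sections are modelled as infinitesimally thin planes placed at
multiples of the section thickness along the slicing axis, and the mask of
each *sampled* plane is extracted by nearest-neighbour lookup into the
label volume (the documented resampling when T does not equal the voxel
pitch). Empty sampled planes are retained with zero area — they carry
information for the Cavalieri estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import LabelVolume

__all__ = [
    "Section",
    "SectionStack",
    "slice_volume",
    "section_area",
    "section_spacing",
    "save_stack",
    "load_stack",
]

CORONAL_AXIS = 1  # anterior-posterior world axis (y) in RAS


def section_spacing(thickness: float, interval: int) -> float:
    """Distance d = k * T between consecutive sampled sections, in mm."""
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if interval < 1:
        raise ValueError("interval must be >= 1")
    return interval * thickness


@dataclass
class Section:
    """One sampled section: its serial index and the binary delineation mask."""

    index: int
    mask: np.ndarray
    pixel_size: tuple[float, float]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("section mask must be 2D")
        if min(self.pixel_size) <= 0:
            raise ValueError("pixel_size must be positive")


def section_area(section: Section) -> float:
    """Profile area A_i of one section in mm^2 (pixel count x pixel area)."""
    return float(section.mask.sum()) * section.pixel_size[0] * section.pixel_size[1]


@dataclass
class SectionStack:
    """Ordered sparse stack of delineation masks for one structure.

    ``plane_origin`` is the world coordinate (mm, along ``axis``) of serial
    section 0; section ``i`` sits at ``plane_origin + i * thickness``.
    ``inplane_origin`` holds the world coordinates of pixel (0, 0) centres
    on the two in-plane axes (in increasing-axis order).
    """

    subject_id: str
    structure: str
    sections: list[Section]
    thickness: float
    sampling_interval: int
    axis: int = CORONAL_AXIS
    offset: int = 0
    plane_origin: float = 0.0
    inplane_origin: tuple[float, float] = (0.0, 0.0)
    space_id: str = "native"
    hemisphere: str | None = None

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.sampling_interval < 1:
            raise ValueError("sampling_interval must be >= 1")
        if not 0 <= self.offset < self.sampling_interval:
            raise ValueError("offset must satisfy 0 <= offset < sampling_interval")
        idx = [s.index for s in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("section indices must be strictly increasing")
        if any(b - a != self.sampling_interval for a, b in zip(idx, idx[1:])):
            raise ValueError(
                "consecutive sampled sections must differ by the sampling interval")
        shapes = {s.mask.shape for s in self.sections}
        sizes = {s.pixel_size for s in self.sections}
        if len(shapes) > 1 or len(sizes) > 1:
            raise ValueError("all sections must share mask shape and pixel size")

    @property
    def spacing(self) -> float:
        """Inter-section distance d = k * T in mm."""
        return section_spacing(self.thickness, self.sampling_interval)

    @property
    def pixel_size(self) -> tuple[float, float]:
        return self.sections[0].pixel_size if self.sections else (np.nan, np.nan)

    def areas(self) -> np.ndarray:
        """Profile areas of all sampled sections, mm^2."""
        return np.array([section_area(s) for s in self.sections])


def slice_volume(
    volume: LabelVolume,
    labels: int | list[int],
    thickness: float = 0.020,
    interval: int = 15,
    offset: int = 0,
    axis: int = CORONAL_AXIS,
    hemisphere: str | None = None,
    structure: str | None = None,
) -> SectionStack:
    """Section a label volume into a sparse stack of delineation masks.

    Parameters
    ----------
    volume : LabelVolume
        Axis-aligned label grid in subject space.
    labels : int or list of int
        Structure label(s); their union defines the delineated structure.
    thickness : float
        Section thickness T in mm (microtome default 0.020).
    interval : int
        Sampling interval k — every k-th section is delineated (default 15).
    offset : int
        Serial index of the first sampled section, 0 <= offset < k.
    hemisphere : {"left", "right"}, optional
        Restrict masks to world x < 0 (left) or x > 0 (right).
    """
    if not volume.is_axis_aligned:
        raise ValueError("slice_volume requires an axis-aligned label volume")
    if not 0 <= offset < interval:
        raise ValueError("offset must satisfy 0 <= offset < interval")
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    labs = [int(l) for l in np.atleast_1d(labels)]
    present = np.isin(volume.labels, labs)
    if not present.any():
        raise ValueError(f"labels {labs} absent from volume {volume.space_id}")

    pitch = float(volume.voxel_size[axis])
    n_axis = volume.labels.shape[axis]
    coords = volume.axis_coordinates(axis)
    # serial section 0 sits at the centre of the first voxel along the axis;
    # planes cover the full grid extent
    plane_origin = float(coords[0])
    n_sections = int(np.floor((coords[-1] - coords[0]) / thickness)) + 1

    inplane_axes = [a for a in range(3) if a != axis]
    px = tuple(float(volume.voxel_size[a]) for a in inplane_axes)
    inplane_origin = tuple(float(volume.affine[a, 3]) for a in inplane_axes)

    hemi_keep = None
    if hemisphere is not None:
        if hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if axis == 0:
            raise ValueError("cannot restrict hemisphere when slicing along x")
        x_axis_pos = inplane_axes.index(0)
        x_coords = volume.axis_coordinates(0)
        keep_1d = x_coords < 0 if hemisphere == "left" else x_coords > 0
        if x_axis_pos == 0:
            hemi_keep = keep_1d[:, None]
        else:
            hemi_keep = keep_1d[None, :]

    sections: list[Section] = []
    for i in range(offset, n_sections, interval):
        y = plane_origin + i * thickness
        j = int(np.rint((y - coords[0]) / pitch))
        j = min(max(j, 0), n_axis - 1)
        mask = np.take(present, j, axis=axis)
        if hemi_keep is not None:
            mask = mask & hemi_keep
        sections.append(Section(index=i, mask=mask, pixel_size=px))

    return SectionStack(
        subject_id=volume.space_id,
        structure=structure or "+".join(str(l) for l in labs),
        sections=sections,
        thickness=thickness,
        sampling_interval=interval,
        axis=axis,
        offset=offset,
        plane_origin=plane_origin,
        inplane_origin=inplane_origin,
        space_id=volume.space_id,
        hemisphere=hemisphere,
    )


def save_stack(stack: SectionStack, out_dir) -> list[str]:
    """Serialise a stack as one PNG mask per section plus a JSON sidecar."""
    import json
    import os

    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for s in stack.sections:
        path = os.path.join(out_dir, f"section_{s.index:05d}.png")
        iio.imwrite(path, (s.mask.astype(np.uint8) * 255))
        written.append(path)
    sidecar = {
        "subject_id": stack.subject_id,
        "structure": stack.structure,
        "thickness_mm": stack.thickness,
        "sampling_interval": stack.sampling_interval,
        "axis": stack.axis,
        "offset": stack.offset,
        "plane_origin_mm": stack.plane_origin,
        "inplane_origin_mm": list(stack.inplane_origin),
        "pixel_size_mm": list(stack.pixel_size),
        "space_id": stack.space_id,
        "hemisphere": stack.hemisphere,
        "section_indices": [s.index for s in stack.sections],
    }
    meta = os.path.join(out_dir, "stack.json")
    with open(meta, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    written.append(meta)
    return written


def load_stack(in_dir) -> SectionStack:
    """Read a stack written by :func:`save_stack`; validates the invariants."""
    import json
    import os

    import imageio.v3 as iio

    with open(os.path.join(in_dir, "stack.json")) as fh:
        meta = json.load(fh)
    px = tuple(meta["pixel_size_mm"])
    sections = []
    for i in meta["section_indices"]:
        arr = iio.imread(os.path.join(in_dir, f"section_{i:05d}.png"))
        sections.append(Section(index=i, mask=arr > 127, pixel_size=px))
    return SectionStack(
        subject_id=meta["subject_id"],
        structure=meta["structure"],
        sections=sections,
        thickness=meta["thickness_mm"],
        sampling_interval=meta["sampling_interval"],
        axis=meta["axis"],
        offset=meta["offset"],
        plane_origin=meta["plane_origin_mm"],
        inplane_origin=tuple(meta["inplane_origin_mm"]),
        space_id=meta["space_id"],
        hemisphere=meta["hemisphere"],
    )
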