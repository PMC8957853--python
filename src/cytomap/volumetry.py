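"""Stereological and voxel-based volumetry with shrinkage correction.

The Cavalieri estimator turns the profile areas A_i measured on equidistant
parallel sections into an unbiased volume estimate V = d * sum(A_i), with d
the inter-section distance. Volumes measured in processed (fixed, embedded)
tissue are smaller than in fresh tissue; a per-brain multiplicative
shrinkage factor f >= 1 converts them back to fresh scale
(V_corr = V_raw * f). For cross-subject comparability, corrected volumes
are further normalised by the subject's total fresh brain volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid import LabelVolume
from .sectioning import SectionStack

__all__ = [
    "VolumeEstimate",
    "cavalieri_volume",
    "correct_shrinkage",
    "normalize_volume",
    "voxel_count_volume",
    "sum_structures",
    "combine_hemispheres",
    "estimate_from_stack",
    "estimates_to_frame",
]


@dataclass
class VolumeEstimate:
    """Raw / shrinkage-corrected / normalised volume for one structure of
    one subject hemisphere. ``proportion`` is V_corr / total brain volume."""

    subject_id: str
    structure: str
    hemisphere: str          # "left" | "right" | "both"
    V_raw: float             # mm^3, in-tissue (shrunken)
    V_corr: float            # mm^3, shrinkage-corrected
    proportion: float | None = None
    method: str = "cavalieri"  # "cavalieri" | "voxel_count" | "mesh"

    def __post_init__(self):
        if self.V_raw < 0:
            raise ValueError("V_raw must be >= 0")
        if self.V_corr < self.V_raw - 1e-9:
            raise ValueError("V_corr must be >= V_raw (shrinkage factor >= 1)")
        if self.proportion is not None and not 0 <= self.proportion < 1:
            raise ValueError("proportion must lie in [0, 1)")


def cavalieri_volume(stack: SectionStack) -> float:
    """Cavalieri volume estimate d * sum(A_i) over all sampled sections, mm^3.

    Empty masks contribute zero area; an entirely empty *stack* (no sections
    at all) is an error — it carries no sampling design.
    """
    if not stack.sections:
        raise ValueError("cannot estimate volume from a stack with no sections")
    return float(stack.spacing * stack.areas().sum())


def correct_shrinkage(v_raw: float, f: float) -> float:
    """Fresh-scale volume V_raw * f. Shrinkage factors inflate, so f >= 1."""
    if f < 1:
        raise ValueError(f"shrinkage factor must be >= 1, got {f}")
    return v_raw * f


def normalize_volume(v_corr: float, brain_volume: float) -> float:
    """Proportion of the total brain volume occupied by the structure."""
    if brain_volume <= 0:
        raise ValueError("brain_volume must be positive")
    return v_corr / brain_volume


def voxel_count_volume(volume: LabelVolume, labels: int | list[int],
                       f: float = 1.0) -> float:
    """Volume from voxel count x physical voxel size x shrinkage factor.

    Requires a shear-free affine: with shear the per-voxel volume element is
    ill-defined without a polar decomposition.
    """
    lin = volume.affine[:3, :3]
    gram = lin.T @ lin
    if not np.allclose(gram, np.diag(np.diag(gram)), atol=1e-9):
        raise ValueError("voxel_count_volume requires a shear-free affine")
    if f < 1:
        raise ValueError(f"shrinkage factor must be >= 1, got {f}")
    labs = [int(l) for l in np.atleast_1d(labels)]
    mask = np.isin(volume.labels, labs)
    if not mask.any():
        raise ValueError(f"labels {labs} absent from volume {volume.space_id}")
    return float(mask.sum()) * volume.voxel_volume * f


def sum_structures(estimates: list[VolumeEstimate],
                   structure: str = "sum") -> VolumeEstimate:
    """Component-wise sum over subdivisions of one subject hemisphere
    (the "sum of subdivisions" row of a subdivision volume table)."""
    if not estimates:
        raise ValueError("cannot sum an empty list of estimates")
    first = estimates[0]
    for e in estimates[1:]:
        if (e.subject_id, e.hemisphere, e.method) != (
                first.subject_id, first.hemisphere, first.method):
            raise ValueError(
                "sum_structures requires a single subject, hemisphere and method")
    props = [e.proportion for e in estimates]
    prop = float(np.sum(props)) if all(p is not None for p in props) else None
    return VolumeEstimate(
        subject_id=first.subject_id, structure=structure,
        hemisphere=first.hemisphere,
        V_raw=float(np.sum([e.V_raw for e in estimates])),
        V_corr=float(np.sum([e.V_corr for e in estimates])),
        proportion=prop, method=first.method)


def combine_hemispheres(left: VolumeEstimate,
                        right: VolumeEstimate) -> VolumeEstimate:
    """Bilateral volume: left + right hemisphere of the same structure."""
    if {left.hemisphere, right.hemisphere} != {"left", "right"}:
        raise ValueError("expected one left and one right estimate")
    if (left.subject_id, left.structure, left.method) != (
            right.subject_id, right.structure, right.method):
        raise ValueError("hemisphere estimates must share subject, structure, method")
    prop = (left.proportion + right.proportion
            if left.proportion is not None and right.proportion is not None
            else None)
    return VolumeEstimate(
        subject_id=left.subject_id, structure=left.structure, hemisphere="both",
        V_raw=left.V_raw + right.V_raw, V_corr=left.V_corr + right.V_corr,
        proportion=prop, method=left.method)


def estimate_from_stack(stack: SectionStack, f: float,
                        brain_volume: float | None = None) -> VolumeEstimate:
    """Full Cavalieri pipeline for one stack: estimate, correct, normalise."""
    v_raw = cavalieri_volume(stack)
    v_corr = correct_shrinkage(v_raw, f)
    prop = (normalize_volume(v_corr, brain_volume)
            if brain_volume is not None else None)
    return VolumeEstimate(
        subject_id=stack.subject_id, structure=stack.structure,
        hemisphere=stack.hemisphere or "both",
        V_raw=v_raw, V_corr=v_corr, proportion=prop, method="cavalieri")


def estimates_to_frame(estimates: list[VolumeEstimate],
                       sex_by_subject: dict[str, str] | None = None) -> pd.DataFrame:
    """Tidy table: subject_id, sex, structure, hemisphere, method,
    V_raw_mm3, V_corr_mm3, proportion."""
    rows = []
    for e in estimates:
        rows.append({
            "subject_id": e.subject_id,
            "sex": (sex_by_subject or {}).get(e.subject_id),
            "structure": e.structure,
            "hemisphere": e.hemisphere,
            "method": e.method,
            "V_raw_mm3": e.V_raw,
            "V_corr_mm3": e.V_corr,
            "proportion": e.proportion,
        })
    return pd.DataFrame(rows)
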