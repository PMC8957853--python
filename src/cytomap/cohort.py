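"""Synthetic cohort of paired subcortical nuclei with known ground truth.

Emulates a postmortem-brain cohort for validating the mapping and volumetry
pipeline: each subject carries the medial geniculate body (MGB, split into
its ventral, dorsal and medial subdivisions MGBv/MGBd/MGBm) and the lateral
geniculate body (LGB) in both hemispheres, modelled as axis-aligned
ellipsoids in a common fresh-tissue reference frame, mirrored about the
midsagittal plane (x = 0).

Per subject the generator draws

* an isotropic biological size factor (lognormal, unit mean, configurable
  coefficient of variation of the *volume*) — this produces the roughly
  two-fold inter-subject volume variability seen in real cohorts;
* independent per-structure position jitter (biological variability of the
  nucleus location);
* a shrinkage factor ``f`` (histological processing shrinks the tissue; a
  measured volume is corrected by multiplying with ``f``);
* a subject-to-reference affine composed of the inverse-shrinkage scaling
  and a small rigid + isotropic-scale jitter (the registration the real
  pipeline would estimate; here it is known exactly and returned).

The subject label volume is rasterised in the subject's own (shrunken,
jittered) space; the ground-truth table records the realised analytic
ellipsoid volumes so that downstream estimators can be validated against a
closed-form oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import LabelVolume, make_grid

__all__ = [
    "NucleusSpec",
    "TransformJitter",
    "CohortSpec",
    "SubjectRecord",
    "GroundTruth",
    "DEFAULT_GEOMETRY",
    "MGB_SUBDIVISIONS",
    "ellipsoid_volume",
    "generate_cohort",
    "sample_volume_table",
    "write_cohort",
]

MGB_SUBDIVISIONS = ("MGBv", "MGBd", "MGBm")
HEMISPHERES = ("left", "right")


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Closed-form ellipsoid volume (4/3)*pi*a*b*c in mm^3."""
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("semi-axes must be positive")
    return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class NucleusSpec:
    """One structure: integer label, right-hemisphere centre (mm, x > 0),
    and ellipsoid semi-axes (mm) in the fresh-tissue reference frame."""

    label: int
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self):
        if self.label <= 0:
            raise ValueError("label must be a positive integer")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")


# Centres echo the caudoventral thalamic location of the metathalamus
# (MGB medial at |x|~15, LGB lateral at |x|~24, both around y=-24..-30,
# z=-11..-4 mm); sizes give per-hemisphere MGB ~133 mm^3 and LGB ~166 mm^3,
# the scale of real shrinkage-corrected measurements.
DEFAULT_GEOMETRY: dict[str, NucleusSpec] = {
    "MGBv": NucleusSpec(1, (15.0, -30.0, -10.0), (2.2, 1.9, 1.5)),
    "MGBd": NucleusSpec(2, (15.0, -26.0, -4.5), (3.0, 2.5, 1.9)),
    "MGBm": NucleusSpec(3, (15.0, -22.0, -11.0), (2.7, 2.3, 1.8)),
    "LGB": NucleusSpec(4, (24.0, -24.0, -9.0), (4.2, 3.5, 2.7)),
}

# Sex sequence and ages mirror the structure of a 5 female / 5 male
# postmortem cohort aged 30-85 years.
_DEFAULT_SEXES = ("female", "male", "female", "male", "female",
                  "female", "female", "male", "male", "male")
_DEFAULT_AGES = (79, 75, 59, 37, 72, 79, 85, 39, 65, 30)


@dataclass(frozen=True)
class TransformJitter:
    """Spread of the subject-to-reference registration jitter."""

    rotation_sd_deg: float = 2.0
    scale_sd: float = 0.02
    translation_sd_mm: float = 1.0

    def __post_init__(self):
        if min(self.rotation_sd_deg, self.scale_sd, self.translation_sd_mm) < 0:
            raise ValueError("jitter standard deviations must be >= 0")


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``volume_cv`` is the coefficient of variation of the per-subject
    isotropic *volume* scale factor (lognormal, unit mean); semi-axes are
    scaled by its cube root. ``sex_volume_effect`` / ``hemisphere_volume_effect``
    multiply male / left-hemisphere volumes and default to 1 (null generator).
    """

    n_subjects: int = 10
    sex_assignment: tuple[str, ...] | None = None
    nucleus_geometry: dict[str, NucleusSpec] = field(
        default_factory=lambda: dict(DEFAULT_GEOMETRY))
    volume_cv: float = 0.25
    position_jitter_sd: float = 0.3
    transform_jitter: TransformJitter = field(default_factory=TransformJitter)
    brain_volume_mean_sd: tuple[float, float] = (1.25e6, 1.4e5)
    shrinkage_factor_mean_sd: tuple[float, float] = (1.93, 0.06)
    voxel_size: float = 0.5
    seed: int = 0
    sex_volume_effect: float = 1.0
    hemisphere_volume_effect: float = 1.0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.sex_assignment is None:
            base = _DEFAULT_SEXES
            self.sex_assignment = tuple(
                base[i % len(base)] for i in range(self.n_subjects))
        self.sex_assignment = tuple(self.sex_assignment)
        if len(self.sex_assignment) != self.n_subjects:
            raise ValueError("sex_assignment length must equal n_subjects")
        if any(s not in ("female", "male") for s in self.sex_assignment):
            raise ValueError("sex_assignment entries must be 'female' or 'male'")
        if min(self.volume_cv, self.position_jitter_sd) < 0:
            raise ValueError("volume_cv and position_jitter_sd must be >= 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.brain_volume_mean_sd[0] <= 0 or self.brain_volume_mean_sd[1] < 0:
            raise ValueError("brain volume mean must be > 0, sd >= 0")
        if self.shrinkage_factor_mean_sd[0] < 1 or self.shrinkage_factor_mean_sd[1] < 0:
            raise ValueError("shrinkage factor mean must be >= 1, sd >= 0")
        for name, spec in self.nucleus_geometry.items():
            if not isinstance(spec, NucleusSpec):
                raise TypeError(f"nucleus_geometry[{name!r}] must be a NucleusSpec")


@dataclass
class SubjectRecord:
    """Metadata for one synthetic subject."""

    subject_id: str
    sex: str
    age: float
    brain_volume: float            # fresh mm^3
    shrinkage_factor: float        # f >= 1; corrected = measured * f
    transform_to_reference: np.ndarray  # 4x4 affine, subject mm -> reference mm

    def __post_init__(self):
        if self.brain_volume <= 0:
            raise ValueError("brain_volume must be positive")
        if self.shrinkage_factor < 1:
            raise ValueError("shrinkage_factor must be >= 1")
        self.transform_to_reference = np.asarray(self.transform_to_reference, float)
        if abs(np.linalg.det(self.transform_to_reference)) < 1e-12:
            raise ValueError("transform_to_reference must be invertible")


class GroundTruth:
    """Realised per subject x structure x hemisphere geometry and volumes.

    The table holds, per row: the realised semi-axes, the structure centre
    in subject space and in the reference frame, the analytic raw
    (in-tissue) volume and the analytic shrinkage-corrected volume
    ``volume_corr_mm3`` — the fresh-scale oracle downstream estimators are
    validated against.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"subject_id", "structure", "hemisphere",
                    "volume_raw_mm3", "volume_corr_mm3"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"ground-truth table missing columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)

    def analytic_volume(self, structure: str, subject_id: str,
                        hemisphere: str | None = None) -> float:
        """Closed-form shrinkage-corrected volume (mm^3) for the realised
        per-subject semi-axes; both hemispheres summed if none is given."""
        sel = self.table[(self.table.structure == structure)
                         & (self.table.subject_id == subject_id)]
        if hemisphere is not None:
            sel = sel[sel.hemisphere == hemisphere]
        if sel.empty:
            raise KeyError(
                f"no ground truth for structure={structure!r}, "
                f"subject={subject_id!r}, hemisphere={hemisphere!r}")
        return float(sel.volume_corr_mm3.sum())


def _rotation_matrix(angles_rad: np.ndarray) -> np.ndarray:
    """Rotation from intrinsic x-y-z Euler angles."""
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _lognormal_unit_mean(rng: np.random.Generator, cv: float) -> float:
    """Lognormal draw with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2)))


def _mirror(center: tuple[float, float, float], hemisphere: str) -> np.ndarray:
    c = np.asarray(center, float)
    if hemisphere == "left":
        c = c * np.array([-1.0, 1.0, 1.0])
    return c


@dataclass
class _SubjectDraw:
    """All random quantities of one subject, before rasterisation."""

    record: SubjectRecord
    volume_scale: float
    scale_jitter: float
    # per (structure, hemisphere): realised fresh centre and fresh semi-axes
    fresh_geometry: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]


def _draw_subject(spec: CohortSpec, index: int,
                  rng: np.random.Generator) -> _SubjectDraw:
    sex = spec.sex_assignment[index]
    age = (_DEFAULT_AGES[index] if index < len(_DEFAULT_AGES)
           else int(rng.integers(30, 86)))
    bv_mean, bv_sd = spec.brain_volume_mean_sd
    brain_volume = max(0.5 * bv_mean, rng.normal(bv_mean, bv_sd))
    f_mean, f_sd = spec.shrinkage_factor_mean_sd
    f = max(1.0, rng.normal(f_mean, f_sd))

    tj = spec.transform_jitter
    angles = np.deg2rad(rng.normal(0.0, tj.rotation_sd_deg, size=3))
    eps = rng.normal(0.0, tj.scale_sd)
    trans = rng.normal(0.0, tj.translation_sd_mm, size=3)
    rot = _rotation_matrix(angles)
    # subject -> reference: un-shrink isotropically, then rigid+scale jitter
    transform = np.eye(4)
    transform[:3, :3] = (1.0 + eps) * rot * f ** (1.0 / 3.0)
    transform[:3, 3] = trans

    s_vol = _lognormal_unit_mean(rng, spec.volume_cv)
    geom: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for name, nucleus in spec.nucleus_geometry.items():
        for hemi in HEMISPHERES:
            s = s_vol
            if sex == "male":
                s *= spec.sex_volume_effect
            if hemi == "left":
                s *= spec.hemisphere_volume_effect
            center = _mirror(nucleus.center, hemi)
            center = center + rng.normal(0.0, spec.position_jitter_sd, size=3)
            axes = np.asarray(nucleus.semi_axes, float) * s ** (1.0 / 3.0)
            geom[(name, hemi)] = (center, axes)

    record = SubjectRecord(
        subject_id=f"sub-{index + 1:02d}", sex=sex, age=age,
        brain_volume=float(brain_volume), shrinkage_factor=float(f),
        transform_to_reference=transform)
    return _SubjectDraw(record, s_vol, float(eps), geom)


def _default_grid(spec: CohortSpec, voxel_size) -> tuple[np.ndarray, np.ndarray]:
    """Fresh-frame bounding box (with margin) covering every structure;
    subject-space coordinates are contracted by shrinkage, so this box also
    bounds the subject grids."""
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for nucleus in spec.nucleus_geometry.values():
        axes = np.asarray(nucleus.semi_axes)
        for hemi in HEMISPHERES:
            c = _mirror(nucleus.center, hemi)
            lo = np.minimum(lo, c - axes)
            hi = np.maximum(hi, c + axes)
    # shrinkage contracts subject coordinates toward the origin: the grid
    # must cover the bbox under every plausible contraction factor
    f_mean, f_sd = spec.shrinkage_factor_mean_sd
    lam = (f_mean + 4.0 * f_sd) ** (-1.0 / 3.0)
    lo, hi = np.minimum(lo, lam * lo), np.maximum(hi, lam * hi)
    tj = spec.transform_jitter
    margin = 4.0 + 3.0 * (spec.position_jitter_sd + tj.translation_sd_mm)
    # allow for the size factor: 3 sd of the lognormal on the largest axis
    margin += 3.0 * spec.volume_cv * max(
        max(n.semi_axes) for n in spec.nucleus_geometry.values())
    return lo - margin, hi + margin


def rasterize_subject(
    draw: _SubjectDraw,
    spec: CohortSpec,
    voxel_size: float | tuple[float, float, float] | None = None,
) -> LabelVolume:
    """Rasterise one subject's structures into its native label grid.

    Membership is evaluated by mapping voxel centres through the (known)
    subject-to-reference transform and testing the axis-aligned ellipsoid
    inequality in the fresh frame — exact under rotation and anisotropic
    grids, no resampling involved.
    """
    vs = np.broadcast_to(
        np.asarray(spec.voxel_size if voxel_size is None else voxel_size,
                   dtype=float), (3,))
    lo, hi = _default_grid(spec, vs)
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / vs[i])) for i in range(3))
    grid = make_grid(tuple(lo + vs / 2), shape, tuple(vs),
                     space_id=draw.record.subject_id)
    labels = grid.labels
    transform = draw.record.transform_to_reference
    inv = np.linalg.inv(transform)

    claimed_by: dict[int, str] = {}
    for name, nucleus in spec.nucleus_geometry.items():
        claimed_by[nucleus.label] = name
    for (name, hemi), (center_fresh, axes_fresh) in draw.fresh_geometry.items():
        nucleus = spec.nucleus_geometry[name]
        # conservative subject-space bounding box via the inverse transform
        center_subj = inv[:3, :3] @ center_fresh + inv[:3, 3]
        r_subj = axes_fresh.max() * np.linalg.norm(inv[:3, :3], 2)
        lo_idx = np.floor(grid.world_to_index(center_subj - r_subj - vs)).astype(int)
        hi_idx = np.ceil(grid.world_to_index(center_subj + r_subj + vs)).astype(int) + 1
        if np.any(lo_idx < -1) or np.any(hi_idx > np.asarray(shape) + 1):
            raise ValueError(
                f"structure {name} ({hemi}) of {draw.record.subject_id} "
                f"exceeds the subject grid bounds")
        lo_idx = np.clip(lo_idx, 0, shape)
        hi_idx = np.clip(hi_idx, 0, shape)
        ii, jj, kk = np.meshgrid(*[np.arange(lo_idx[d], hi_idx[d]) for d in range(3)],
                                 indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        world = grid.index_to_world(idx)
        fresh = world @ transform[:3, :3].T + transform[:3, 3]
        u = (fresh - center_fresh) / axes_fresh
        inside = (u * u).sum(axis=1) <= 1.0
        if not inside.any():
            continue
        sel = idx[inside]
        existing = labels[sel[:, 0], sel[:, 1], sel[:, 2]]
        clash = existing[existing != 0]
        if clash.size:
            other = claimed_by.get(int(clash[0]), str(clash[0]))
            raise ValueError(
                f"structures {other} and {name} overlap after jitter in "
                f"subject {draw.record.subject_id}")
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = nucleus.label
    return grid


def _ground_truth_rows(draw: _SubjectDraw, spec: CohortSpec) -> list[dict]:
    rows = []
    transform = draw.record.transform_to_reference
    inv = np.linalg.inv(transform)
    det = np.linalg.det(transform[:3, :3])
    f = draw.record.shrinkage_factor
    lin_scale = np.cbrt(det)  # isotropic: f^(1/3) * (1+eps)
    for (name, hemi), (center_fresh, axes_fresh) in draw.fresh_geometry.items():
        v_fresh = ellipsoid_volume(*axes_fresh)
        v_raw = v_fresh / det            # volume in shrunken subject space
        v_corr = v_raw * f               # what perfect estimation recovers
        center_subj = inv[:3, :3] @ center_fresh + inv[:3, 3]
        axes_subj = axes_fresh / lin_scale
        rows.append({
            "subject_id": draw.record.subject_id,
            "structure": name, "hemisphere": hemi,
            "semi_a_mm": axes_subj[0], "semi_b_mm": axes_subj[1],
            "semi_c_mm": axes_subj[2],
            "center_x_mm": center_subj[0], "center_y_mm": center_subj[1],
            "center_z_mm": center_subj[2],
            "center_ref_x_mm": center_fresh[0],
            "center_ref_y_mm": center_fresh[1],
            "center_ref_z_mm": center_fresh[2],
            "volume_raw_mm3": v_raw, "volume_corr_mm3": v_corr,
        })
    return rows


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectRecord], list[LabelVolume], GroundTruth]:
    """Generate the synthetic cohort: metadata, label volumes, ground truth.

    Deterministic for a given ``spec.seed``; each subject consumes an
    independent child stream of the master seed, so prefixes of the cohort
    are reproducible regardless of ``n_subjects``.
    """
    draws = draw_cohort(spec)
    records = [d.record for d in draws]
    volumes = [rasterize_subject(d, spec) for d in draws]
    rows: list[dict] = []
    for d in draws:
        rows.extend(_ground_truth_rows(d, spec))
    truth = GroundTruth(pd.DataFrame(rows))
    return records, volumes, truth


def ground_truth_table(draws: list["_SubjectDraw"], spec: CohortSpec) -> pd.DataFrame:
    """Ground-truth rows for already-drawn subjects (no rasterisation)."""
    rows: list[dict] = []
    for d in draws:
        rows.extend(_ground_truth_rows(d, spec))
    return pd.DataFrame(rows)


def draw_cohort(spec: CohortSpec) -> list[_SubjectDraw]:
    """Draw all random per-subject quantities without rasterising."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    return [_draw_subject(spec, i, np.random.default_rng(children[i]))
            for i in range(spec.n_subjects)]


def sample_volume_table(spec: CohortSpec) -> pd.DataFrame:
    """Analytic per subject x structure x hemisphere volume table.

    Draws the same distributions as :func:`generate_cohort` but skips
    rasterisation — a cheap cohort model for statistical calibration
    (e.g. type-I-error studies of the permutation tests).
    """
    draws = draw_cohort(spec)
    rows = []
    for d in draws:
        for gt in _ground_truth_rows(d, spec):
            rows.append({
                "subject_id": d.record.subject_id,
                "sex": d.record.sex,
                "structure": gt["structure"],
                "hemisphere": gt["hemisphere"],
                "V_corr_mm3": gt["volume_corr_mm3"],
                "brain_volume_mm3": d.record.brain_volume,
                "proportion": gt["volume_corr_mm3"] / d.record.brain_volume,
            })
    return pd.DataFrame(rows)


def write_cohort(records, volumes, out_dir) -> list[str]:
    """Write NIfTI label volumes, a metadata CSV and per-subject 4x4
    transform text files (world mm, row-major). Returns written paths."""
    import os

    from .grid import write_label_volume

    os.makedirs(out_dir, exist_ok=True)
    written = []
    meta = []
    for rec, vol in zip(records, volumes):
        nii = os.path.join(out_dir, f"{rec.subject_id}_labels.nii")
        write_label_volume(vol, nii)
        written.append(nii)
        txt = os.path.join(out_dir, f"{rec.subject_id}_to_reference.txt")
        np.savetxt(txt, rec.transform_to_reference, fmt="%.10g")
        written.append(txt)
        meta.append({
            "subject_id": rec.subject_id, "sex": rec.sex, "age": rec.age,
            "brain_volume_mm3": rec.brain_volume,
            "shrinkage_factor": rec.shrinkage_factor,
        })
    meta_path = os.path.join(out_dir, "subjects.csv")
    pd.DataFrame(meta).to_csv(meta_path, index=False)
    written.append(meta_path)
    return written
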