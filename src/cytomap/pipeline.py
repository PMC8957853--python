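"""End-to-end orchestration: simulate -> section -> volumetry -> stats ->
probability maps -> meshes, driven by one YAML config.

Every random stage takes an explicit seed, so a rerun with the same config
produces bit-identical outputs; the manifest records a content hash for
every file. Stages whose outputs already exist under the same stage config
are skipped on rerun (partial resume).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from . import group_stats as gs
from . import meshing as msh
from . import probmaps as pm
from . import sectioning as sec
from . import volumetry as vol
from .grid import make_grid, write_label_volume

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("cytomap.pipeline")

MGB_LABELS = [1, 2, 3]
LGB_LABELS = [4]

DEFAULT_CONFIG: dict = {
    "cohort": {
        "n_subjects": 10,
        "volume_cv": 0.25,
        "position_jitter_sd": 0.3,
        "transform_jitter": {"rotation_sd_deg": 2.0, "scale_sd": 0.02,
                             "translation_sd_mm": 1.0},
        "voxel_size": 0.5,
        "seed": 0,
    },
    # one synthetic elementary section (0.1 mm) stands for five 20 um
    # microtome sections; sampling every 3rd keeps the 0.3 mm lattice
    "sectioning": {
        "thickness_mm": 0.1,
        "interval": 3,
        "offset": "random",
        "fine_voxel_size": [0.25, 0.1, 0.25],
    },
    "volumetry": {"normalization": "proportion"},
    "stats": {"n_iter": 10000, "seed": 7, "sidedness": "two",
              "sex_unit": "hemisphere"},
    "probmap": {
        "voxel_size": 1.0,
        "origin": [-40.0, -44.0, -24.0],
        "shape": [80, 38, 32],
        "threshold": 50,
        "reconstruction": "shape_based",
    },
    "mesh": {"voxel_size": 0.25, "smooth_iters": 10, "smooth_step": 0.1},
    "output_dir": "pipeline_out",
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and \
            isinstance(base.get(k), dict) else v
    return out


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (see DEFAULT_CONFIG for defaults)."""

    raw: dict

    def __post_init__(self):
        self.raw = _merge(DEFAULT_CONFIG, self.raw)
        c = self.raw
        tj = coh.TransformJitter(**c["cohort"]["transform_jitter"])
        kw = {k: v for k, v in c["cohort"].items() if k != "transform_jitter"}
        self.cohort_spec = coh.CohortSpec(transform_jitter=tj, **kw)
        if c["sectioning"]["interval"] < 1:
            raise ValueError("sectioning interval must be >= 1")
        if c["volumetry"]["normalization"] not in ("proportion", "rescaled"):
            raise ValueError("normalization must be 'proportion' or 'rescaled'")
        if c["stats"]["sex_unit"] not in ("hemisphere", "subject_sum"):
            raise ValueError("sex_unit must be 'hemisphere' or 'subject_sum'")
        self.output_dir = c["output_dir"]

    def __getitem__(self, key):
        return self.raw[key]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig(yaml.safe_load(fh) or {})


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_hash(cfg: PipelineConfig, *sections: str) -> str:
    payload = {s: cfg.raw[s] for s in sections}
    payload["cohort"] = cfg.raw["cohort"]
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class _StageState:
    """Remembers which stage ran under which config hash (resume support)."""

    def __init__(self, out_dir: str):
        self.path = os.path.join(out_dir, ".stage_state.json")
        self.state = {}
        if os.path.exists(self.path):
            with open(self.path) as fh:
                self.state = json.load(fh)

    def fresh(self, stage: str, digest: str, files: list[str]) -> bool:
        prev = self.state.get(stage)
        return not (prev and prev.get("hash") == digest
                    and all(os.path.exists(f) for f in prev.get("files", [])))

    def record(self, stage: str, digest: str, files: list[str]) -> None:
        self.state[stage] = {"hash": digest, "files": files}
        with open(self.path, "w") as fh:
            json.dump(self.state, fh, indent=1, sort_keys=True)


def _offsets(cfg: PipelineConfig, n: int) -> list[int]:
    policy = cfg["sectioning"]["offset"]
    k = cfg["sectioning"]["interval"]
    if policy == "random":
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.cohort_spec.seed, 915]))
        return [int(o) for o in rng.integers(0, k, size=n)]
    return [int(policy)] * n


def _structure_labels(spec: coh.CohortSpec) -> dict[str, list[int]]:
    labels = {name: [n.label] for name, n in spec.nucleus_geometry.items()}
    if all(s in labels for s in coh.MGB_SUBDIVISIONS):
        labels["MGB"] = [labels[s][0] for s in coh.MGB_SUBDIVISIONS]
    return labels


def run_pipeline(config: PipelineConfig | dict, output_dir: str | None = None) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(dict(config))
    out = output_dir or config.output_dir
    os.makedirs(out, exist_ok=True)
    state = _StageState(out)
    spec = config.cohort_spec
    t0 = time.time()

    draws = coh.draw_cohort(spec)
    records = [d.record for d in draws]
    sex_by_subject = {r.subject_id: r.sex for r in records}
    labels_of = _structure_labels(spec)
    nuclei = [n for n in ("MGB", "LGB") if n in labels_of]
    manifest_files: list[str] = []
    stage_log: dict[str, dict] = {}

    def _stage_done(stage, digest, files, skipped, t_start):
        manifest_files.extend(files)
        stage_log[stage] = {"skipped": skipped,
                            "elapsed_s": round(time.time() - t_start, 3)}
        if not skipped:
            state.record(stage, digest, files)
        log.info("stage %-10s %s (%.1fs)", stage,
                 "skipped" if skipped else "done", time.time() - t_start)

    # ---- stage: cohort -------------------------------------------------
    ts = time.time()
    digest = _stage_hash(config, "cohort")
    cohort_dir = os.path.join(out, "cohort")
    prev = state.state.get("cohort", {})
    if state.fresh("cohort", digest, prev.get("files", [])):
        try:
            volumes = [coh.rasterize_subject(d, spec) for d in draws]
        except ValueError as err:
            raise RuntimeError(f"stage cohort failed: {err}") from err
        files = coh.write_cohort(records, volumes, cohort_dir)
        gt_path = os.path.join(cohort_dir, "ground_truth.csv")
        coh.ground_truth_table(draws, spec).to_csv(
            gt_path, index=False, float_format="%.8g")
        files.append(gt_path)
        _stage_done("cohort", digest, files, False, ts)
    else:
        _stage_done("cohort", digest, prev["files"], True, ts)

    # shared heavy intermediates for volumetry + probmaps
    sec_cfg = config["sectioning"]
    offsets = _offsets(config, spec.n_subjects)
    vol_digest = _stage_hash(config, "sectioning", "volumetry")
    pmap_digest = _stage_hash(config, "sectioning", "probmap")
    volumes_csv = os.path.join(out, "volumes.csv")
    pmap_dir = os.path.join(out, "probmaps")
    need_vol = state.fresh("volumetry", vol_digest, [volumes_csv])
    need_pmap = state.fresh("probmaps", pmap_digest, [])

    fine_volumes = None
    if need_vol or need_pmap:
        fine_volumes = [
            coh.rasterize_subject(d, spec,
                                  voxel_size=tuple(sec_cfg["fine_voxel_size"]))
            for d in draws]

    # ---- stage: volumetry ----------------------------------------------
    ts = time.time()
    if need_vol:
        estimates: list[vol.VolumeEstimate] = []
        for i, (rec, fv) in enumerate(zip(records, fine_volumes)):
            per_hemi: dict[str, dict[str, vol.VolumeEstimate]] = {}
            for hemi in ("left", "right"):
                per_hemi[hemi] = {}
                for name in spec.nucleus_geometry:
                    try:
                        stack = sec.slice_volume(
                            fv, labels_of[name],
                            thickness=sec_cfg["thickness_mm"],
                            interval=sec_cfg["interval"],
                            offset=offsets[i], hemisphere=hemi, structure=name)
                    except ValueError as err:
                        raise RuntimeError(
                            f"stage volumetry failed for {rec.subject_id}: "
                            f"{err}") from err
                    est = vol.estimate_from_stack(
                        stack, rec.shrinkage_factor, rec.brain_volume)
                    per_hemi[hemi][name] = est
                    estimates.append(est)
                if "MGB" in labels_of:
                    parts = [per_hemi[hemi][s] for s in coh.MGB_SUBDIVISIONS]
                    mgb = vol.sum_structures(parts, structure="MGB")
                    per_hemi[hemi]["MGB"] = mgb
                    estimates.append(mgb)
        frame = vol.estimates_to_frame(estimates, sex_by_subject)
        frame.to_csv(volumes_csv, index=False, float_format="%.8g")
        _stage_done("volumetry", vol_digest, [volumes_csv], False, ts)
    else:
        _stage_done("volumetry", vol_digest, [volumes_csv], True, ts)

    # ---- stage: stats --------------------------------------------------
    ts = time.time()
    st_cfg = config["stats"]
    st_digest = _stage_hash(config, "sectioning", "volumetry", "stats")
    stats_dir = os.path.join(out, "stats")
    prev = state.state.get("stats", {})
    if state.fresh("stats", st_digest, prev.get("files", [])):
        os.makedirs(stats_dir, exist_ok=True)
        frame = pd.read_csv(volumes_csv)
        variable = "proportion"
        values_all = frame.copy()
        if config["volumetry"]["normalization"] == "rescaled":
            mean_bv = np.mean([r.brain_volume for r in records])
            values_all["proportion"] = values_all["proportion"] * mean_bv
        files = []
        for nucleus in nuclei:
            sub = values_all[values_all.structure == nucleus].sort_values(
                ["subject_id", "hemisphere"])
            wide = sub.pivot(index="subject_id", columns="hemisphere",
                             values=variable)
            sexes = sub.drop_duplicates("subject_id").set_index(
                "subject_id").loc[wide.index, "sex"]
            res = {}
            # hemisphere: 2n values grouped left vs right
            res["hemisphere"] = gs.permutation_contrast(
                np.concatenate([wide["left"], wide["right"]]),
                ["left"] * len(wide) + ["right"] * len(wide),
                n_iter=st_cfg["n_iter"], seed=st_cfg["seed"],
                sidedness=st_cfg["sidedness"], contrast_name="hemisphere")
            # sex: per-hemisphere observations (or per-subject sums)
            if st_cfg["sex_unit"] == "hemisphere":
                vals = np.concatenate([wide["left"], wide["right"]])
                labs = list(sexes) * 2
            else:
                vals = (wide["left"] + wide["right"]).to_numpy()
                labs = list(sexes)
            order = np.argsort([0 if l == "male" else 1 for l in labs],
                               kind="stable")
            res["sex"] = gs.permutation_contrast(
                np.asarray(vals)[order], np.asarray(labs)[order],
                n_iter=st_cfg["n_iter"], seed=st_cfg["seed"] + 1,
                sidedness=st_cfg["sidedness"], contrast_name="sex")
            res["interaction"] = gs.interaction_contrast(
                wide["left"].to_numpy(), wide["right"].to_numpy(),
                sexes.to_numpy(), n_iter=st_cfg["n_iter"],
                seed=st_cfg["seed"] + 2, sidedness=st_cfg["sidedness"])
            for contrast, r in res.items():
                path = os.path.join(stats_dir,
                                    f"{nucleus}_{contrast}_permutation.json")
                with open(path, "w") as fh:
                    json.dump({**dataclasses.asdict(r),
                               "nucleus": nucleus}, fh, indent=1,
                              sort_keys=True)
                files.append(path)
                log.info("%s %s: C=%.3g p=%.4f (exceedances %d, null IQR %s)",
                         nucleus, contrast, r.C_obs, r.p_value,
                         r.exceedance_rank, r.null_quantiles)
        if len(nuclei) == 2:
            bilat = values_all[values_all.structure.isin(nuclei)].pivot_table(
                index="subject_id", columns="structure", values="V_corr_mm3",
                aggfunc="sum")
            try:
                tt = dataclasses.asdict(
                    gs.paired_t_test(bilat[nuclei[0]], bilat[nuclei[1]]))
            except ValueError as err:  # zero-variance differences
                tt = {"t": None, "df": len(bilat) - 1, "p_value": None,
                      "sided": "two", "degenerate": str(err)}
            path = os.path.join(stats_dir, "nucleus_comparison_ttest.json")
            with open(path, "w") as fh:
                json.dump({**tt,
                           "comparison": f"{nuclei[0]} vs {nuclei[1]}",
                           "mean_a_mm3": float(bilat[nuclei[0]].mean()),
                           "mean_b_mm3": float(bilat[nuclei[1]].mean())},
                          fh, indent=1, sort_keys=True)
            files.append(path)
        _stage_done("stats", st_digest, files, False, ts)
    else:
        _stage_done("stats", st_digest, prev["files"], True, ts)

    # ---- stage: probability maps ---------------------------------------
    ts = time.time()
    pm_cfg = config["probmap"]
    prev = state.state.get("probmaps", {})
    if state.fresh("probmaps", pmap_digest, prev.get("files", [])):
        os.makedirs(pmap_dir, exist_ok=True)
        ref = make_grid(
            tuple(np.asarray(pm_cfg["origin"]) + pm_cfg["voxel_size"] / 2),
            tuple(pm_cfg["shape"]), pm_cfg["voxel_size"],
            space_id="reference")
        files = []
        com_rows = []
        for nucleus in nuclei:
            masks = []
            for i, (rec, fv) in enumerate(zip(records, fine_volumes)):
                stack = sec.slice_volume(
                    fv, labels_of[nucleus],
                    thickness=sec_cfg["thickness_mm"],
                    interval=sec_cfg["interval"], offset=offsets[i],
                    structure=nucleus)
                recon = pm.stack_to_volume(stack, pm_cfg["reconstruction"])
                masks.append(pm.to_reference(
                    recon, rec.transform_to_reference, ref))
            pmap = pm.compute_probability_map(masks, ref, structure=nucleus)
            nii = os.path.join(pmap_dir, f"{nucleus}_probability.nii")
            pm.write_probability_map(pmap, nii)
            files.append(nii)
            for hemi in ("left", "right"):
                com = pm.center_of_mass(pmap, hemisphere=hemi)
                com_rows.append({"structure": nucleus, "hemisphere": hemi,
                                 "x_mm": com.x, "y_mm": com.y, "z_mm": com.z})
        com_frame = pd.DataFrame(com_rows)
        com_csv = os.path.join(pmap_dir, "centers_of_mass.csv")
        com_frame.to_csv(com_csv, index=False)
        com_json = os.path.join(pmap_dir, "centers_of_mass.json")
        with open(com_json, "w") as fh:
            json.dump(com_rows, fh, indent=1, sort_keys=True)
        files += [com_csv, com_json]
        _stage_done("probmaps", pmap_digest, files, False, ts)
    else:
        _stage_done("probmaps", pmap_digest, prev["files"], True, ts)

    # ---- stage: meshes -------------------------------------------------
    ts = time.time()
    m_cfg = config["mesh"]
    m_digest = _stage_hash(config, "mesh")
    mesh_dir = os.path.join(out, "meshes")
    prev = state.state.get("meshes", {})
    if state.fresh("meshes", m_digest, prev.get("files", [])):
        os.makedirs(mesh_dir, exist_ok=True)
        # high-resolution single-subject reconstruction (first subject)
        hi = coh.rasterize_subject(draws[0], spec,
                                   voxel_size=m_cfg["voxel_size"])
        rec = records[0]
        files = []
        rows = []
        x_world = hi.axis_coordinates(0)
        for name in spec.nucleus_geometry:
            for hemi in ("left", "right"):
                keep = x_world < 0 if hemi == "left" else x_world > 0
                sub = hi.labels * keep[:, None, None]
                half = type(hi)(sub, hi.affine, hi.space_id)
                mesh = msh.extract_mesh(half, labels_of[name],
                                        structure=f"{name}_{hemi}")
                smoothed = msh.smooth_mesh(mesh, m_cfg["smooth_iters"],
                                           m_cfg["smooth_step"])
                path = os.path.join(mesh_dir, f"{name}_{hemi}.obj")
                msh.write_mesh_obj(smoothed, path)
                files.append(path)
                v_raw = msh.mesh_volume(smoothed)
                rows.append({
                    "subject_id": rec.subject_id, "structure": name,
                    "hemisphere": hemi, "method": "mesh",
                    "V_raw_mm3": v_raw,
                    "V_corr_mm3": v_raw * rec.shrinkage_factor,
                })
        mesh_csv = os.path.join(mesh_dir, "mesh_volumes.csv")
        pd.DataFrame(rows).to_csv(mesh_csv, index=False, float_format="%.8g")
        files.append(mesh_csv)
        _stage_done("meshes", m_digest, files, False, ts)
    else:
        _stage_done("meshes", m_digest, prev["files"], True, ts)

    # ---- manifest ------------------------------------------------------
    manifest = {
        "config": config.raw,
        "stages": stage_log,
        "elapsed_s": round(time.time() - t0, 3),
        "files": {os.path.relpath(f, out): _sha256(f)
                  for f in sorted(set(manifest_files))},
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
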