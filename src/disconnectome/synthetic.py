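"""Synthetic cohort generator with known ground truth.

Emulates the data structures the pipeline consumes for a left
anterior-temporal resection cohort:

* a tube-like fibre bundle per subject — smooth streamlines (Catmull-Rom
  curves through jittered control points) descending from a posterior trunk
  to anterior-inferior terminations whose depth varies across streamlines,
  so a cavity of varying posterior extent transects a graded fraction of
  the bundle;
* an ellipsoidal anterior resection cavity whose posterior radius is drawn
  per subject, clipped to the grid (cavities may reach the volume edge, as
  real resections reach the brain surface);
* FA/MD-like scalar maps carrying additive scanner-batch offsets;
* three-timepoint memory z-scores (preoperative, 3 and 12 months) whose
  postoperative change follows a linear mixed model in the true transection
  fraction, age at surgery, resection volume, preoperative score and
  timepoint, with a per-subject random intercept and Gaussian noise.

Every random draw descends from the master seed through per-subject
``numpy.random.SeedSequence(master, spawn_key=(subject_index,))`` streams,
so cohorts are fully reproducible and extendable without rewriting earlier
subjects.  The ground-truth sidecar stores every simulated component
(effects, random intercepts, noise), sufficient to reconstruct each score
exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BinaryMask, TractBundle, VolumeGrid, write_tractogram, write_volume
from .metrics import bundle_probability_map, transection_fraction
from .neuropsych import synthetic_normative_table

__all__ = ["SimulationConfig", "SyntheticCohort", "gen_bundle", "gen_resection_mask", "gen_cohort"]

TASKS = ("encoding", "retrieval")
TASK_MAX = {"encoding": 75.0, "retrieval": 15.0}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort (all lengths in mm)."""

    n_subjects: int = 80
    grid_shape: tuple = (48, 56, 48)
    voxel_size: float = 1.0
    # bundle geometry
    n_streamlines: int = 30
    n_points: int = 40
    tube_radius: float = 1.5
    jitter_sd: float = 0.8  # per-control-point streamline jitter
    subject_jitter_sd: float = 1.0  # inter-subject spatial jitter
    termination_center_range: tuple = (31.0, 45.0)  # per-subject fan centre (y, mm)
    termination_half_span: float = 14.0  # fan spread around the centre (y, mm)
    # cavity geometry
    cavity_center: tuple = (24.0, 52.0, 12.0)
    cavity_rx_range: tuple = (8.0, 16.0)  # cavity width, uniform per subject
    cavity_rz_range: tuple = (7.0, 14.0)  # cavity height, uniform per subject
    posterior_extent_range: tuple = (1.0, 30.0)  # cavity y-radius, uniform
    # outcome model (memory z-score change from baseline)
    beta_transect: float = -0.5  # per unit transection fraction (0-1)
    beta_time_12m: float = 0.25  # 12 m recovery relative to 3 m
    beta_age: float = -0.01  # per year of age at surgery
    beta_resvol: float = -3.0  # per unit normalized resection volume
    beta_pre: float = -0.25  # regression to the mean on baseline z
    intercept: float = 0.2
    subject_sd: float = 0.2  # random-intercept SD
    noise_sd: float = 0.28  # residual SD
    pre_mean: float = -0.5
    pre_sd: float = 0.9
    # scanner batches
    batches: tuple = ("HDx", "MR750")
    fa_batch_offset: float = 0.04
    md_batch_offset: float = 3e-5
    fa_noise_sd: float = 0.02
    md_noise_sd: float = 2e-5
    # seizure outcome
    ilae_intercept: float = -0.3
    ilae_beta: float = 1.0
    # missingness per postoperative timepoint
    missing_rate_3m: float = 0.06
    missing_rate_12m: float = 0.12
    seed: int = 0

    def grid(self) -> VolumeGrid:
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        return VolumeGrid(np.zeros(self.grid_shape), affine)


def _subject_streams(config: SimulationConfig, subject_index: int, n: int = 4):
    ss = np.random.SeedSequence(config.seed, spawn_key=(subject_index,))
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def _catmull_rom(ctrl: np.ndarray, n_points: int) -> np.ndarray:
    """Catmull-Rom curves through control points, vectorized.

    ctrl: (n_streamlines, n_ctrl, 3) -> (n_streamlines, n_points, 3)
    """
    s, k, _ = ctrl.shape
    padded = np.concatenate([ctrl[:, :1], ctrl, ctrl[:, -1:]], axis=1)
    n_seg = k - 1
    t = np.linspace(0.0, n_seg, n_points)
    seg = np.minimum(t.astype(int), n_seg - 1)
    u = t - seg
    p0 = padded[:, seg]
    p1 = padded[:, seg + 1]
    p2 = padded[:, seg + 2]
    p3 = padded[:, seg + 3]
    u = u[None, :, None]
    return 0.5 * (
        2 * p1
        + (-p0 + p2) * u
        + (2 * p0 - 5 * p1 + 4 * p2 - p3) * u**2
        + (-p0 + 3 * p1 - 3 * p2 + p3) * u**3
    )


def gen_bundle(config: SimulationConfig, subject_index: int = 0, rng=None) -> TractBundle:
    """Fibre bundle for one subject: smooth streamlines within the tube."""
    if config.tube_radius <= 0:
        raise ValueError(f"tube radius must be > 0, got {config.tube_radius}")
    if rng is None:
        rng = _subject_streams(config, subject_index)[0]
    s = config.n_streamlines
    # anatomical variability: how far anteriorly the bundle reaches varies
    # across subjects independently of the cavity
    fan_center = rng.uniform(*config.termination_center_range)
    y_end = rng.uniform(
        fan_center - config.termination_half_span,
        fan_center + config.termination_half_span,
        size=s,
    )
    shift = rng.normal(0.0, config.subject_jitter_sd, size=3)  # whole-subject jitter

    # radial tube offset in the x/z plane, constant along each streamline
    theta = rng.uniform(0, 2 * np.pi, size=s)
    rad = config.tube_radius * np.sqrt(rng.uniform(0, 1, size=s))
    off = np.column_stack([rad * np.cos(theta), np.zeros(s), rad * np.sin(theta)])

    cx = config.cavity_center[0]
    ctrl = np.empty((s, 5, 3))
    ctrl[:, 0] = [cx, 6.0, 34.0]
    ctrl[:, 1] = np.column_stack([np.full(s, cx), 0.40 * y_end, np.full(s, 36.0)])
    ctrl[:, 2] = np.column_stack([np.full(s, cx), 0.72 * y_end, np.full(s, 27.0)])
    ctrl[:, 3] = np.column_stack([np.full(s, cx), 0.92 * y_end, np.full(s, 15.0)])
    ctrl[:, 4] = np.column_stack([np.full(s, cx), y_end, np.full(s, 10.0)])
    ctrl += off[:, None, :]
    ctrl += rng.normal(0.0, config.jitter_sd, size=ctrl.shape)
    ctrl += shift[None, None, :]
    pts = _catmull_rom(ctrl, config.n_points)
    return TractBundle(list(pts))


def gen_resection_mask(
    config: SimulationConfig, subject_index: int = 0, rng=None
) -> tuple[BinaryMask, float]:
    """Ellipsoidal anterior cavity; returns (mask, posterior extent in mm).

    The cavity centre must lie inside the grid and the voxelized cavity
    must be non-empty; the ellipsoid itself is clipped at the grid edge.
    """
    if rng is None:
        rng = _subject_streams(config, subject_index)[1]
    grid = config.grid()
    extent = np.array(config.grid_shape) * config.voxel_size
    center = np.clip(
        np.array(config.cavity_center) + rng.normal(0.0, 1.0, size=3),
        1.0,
        extent - 2.0,
    )
    r_post = rng.uniform(*config.posterior_extent_range)
    rx = rng.uniform(*config.cavity_rx_range)
    rz = rng.uniform(*config.cavity_rz_range)
    mask = ellipsoid_mask(grid, center, (rx, r_post, rz))
    if mask.n_voxels == 0:
        raise ValueError(
            f"cavity (centre {center}, radii {(rx, r_post, rz)}) is empty on the grid"
        )
    return mask, float(r_post)


def ellipsoid_mask(grid: VolumeGrid, center_mm, radii_mm) -> BinaryMask:
    """Voxelized ellipsoid (world mm) on a grid, clipped to the grid."""
    radii = np.asarray(radii_mm, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    if np.any(radii <= 0):
        raise ValueError(f"ellipsoid radii must be > 0, got {radii}")
    shape = np.array(grid.shape)
    ctr_vox = np.linalg.inv(grid.affine)[:3] @ np.append(center, 1.0)
    if np.any(ctr_vox < 0) or np.any(ctr_vox >= shape):
        raise ValueError(f"cavity centre {center} mm falls outside the grid")
    idx = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    world = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    inside = np.sum(((world - center) / radii) ** 2, axis=1) <= 1.0
    return BinaryMask(inside.reshape(grid.shape).astype(np.uint8), grid.affine)


def _scalar_maps(config, grid, bundle, batch_idx, rng):
    prob = bundle_probability_map(bundle, grid, method="points").data
    fa = 0.22 + 0.35 * prob + rng.normal(0.0, config.fa_noise_sd, grid.shape)
    md = 8.5e-4 - 2.5e-4 * prob + rng.normal(0.0, config.md_noise_sd, grid.shape)
    if batch_idx == 1:
        fa = fa + config.fa_batch_offset
        md = md + config.md_batch_offset
    return grid.like(np.clip(fa, 0.0, 1.0)), grid.like(np.clip(md, 1e-5, None))


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    manifest: pd.DataFrame
    bundles: list
    masks: list
    fa_maps: list
    md_maps: list
    icv_mask: BinaryMask
    truth: dict

    def long_table(self, task: str = "encoding") -> pd.DataFrame:
        """Long-format analysis table: one row per subject x timepoint."""
        rows = []
        for _, r in self.manifest.iterrows():
            for tp in ("3m", "12m"):
                rows.append(
                    {
                        "subject_id": r["subject_id"],
                        "timepoint": tp,
                        "change_z": r[f"{task}_{tp}_z"] - r[f"{task}_pre_z"],
                        "age_surgery": r["age_surgery"],
                        "age_onset": r["age_onset"],
                        "resection_volume": r["resection_volume"],
                        "pre_z": r[f"{task}_pre_z"],
                        "transection": r["percent_cut_true"] / 100.0,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> Path:
        """Write NIfTI/TCK files, the manifest CSV and the truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        paths = {"bundle": [], "resection": [], "fa": [], "md": []}
        for i, sid in enumerate(manifest["subject_id"]):
            sub = out / sid
            sub.mkdir(exist_ok=True)
            write_tractogram(self.bundles[i], sub / "bundle.tck")
            write_volume(self.masks[i], sub / "resection.nii.gz")
            paths["bundle"].append(str(Path(sid) / "bundle.tck"))
            paths["resection"].append(str(Path(sid) / "resection.nii.gz"))
            if self.fa_maps:
                write_volume(self.fa_maps[i], sub / "fa.nii.gz")
                write_volume(self.md_maps[i], sub / "md.nii.gz")
                paths["fa"].append(str(Path(sid) / "fa.nii.gz"))
                paths["md"].append(str(Path(sid) / "md.nii.gz"))
        for key, vals in paths.items():
            if vals:
                manifest[f"{key}_path"] = vals
        write_volume(self.icv_mask, out / "icv.nii.gz")
        manifest.to_csv(out / "manifest.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)
        return out


def gen_cohort(config: SimulationConfig, include_maps: bool = True) -> SyntheticCohort:
    """Generate the full synthetic cohort in memory.

    ``include_maps=False`` skips FA/MD map synthesis for model-calibration
    studies that only need geometry and scores.
    """
    grid = config.grid()
    norms = synthetic_normative_table()
    icv = ellipsoid_mask(
        grid,
        np.array(config.grid_shape) * config.voxel_size / 2.0,
        np.array(config.grid_shape) * config.voxel_size / 2.0 - 1.0,
    )

    bundles, masks, fa_maps, md_maps, rows = [], [], [], [], []
    truth_subjects = []
    for i in range(config.n_subjects):
        rng_bundle, rng_cavity, rng_maps, rng_scores = _subject_streams(config, i)
        sid = f"sub-{i:03d}"
        bundle = gen_bundle(config, i, rng=rng_bundle)
        mask, r_post = gen_resection_mask(config, i, rng=rng_cavity)
        frac = transection_fraction(bundle, mask, method="points").percent_cut / 100.0
        resvol = mask.volume_mm3 / icv.volume_mm3

        batch_idx = int(rng_scores.integers(0, 2))
        age_onset = float(rng_scores.uniform(10.0, 35.0))
        age_surgery = age_onset + float(rng_scores.uniform(6.0, 25.0))
        u_subject = float(rng_scores.normal(0.0, config.subject_sd))

        row = {
            "subject_id": sid,
            "age_onset": age_onset,
            "age_surgery": age_surgery,
            "batch": config.batches[batch_idx],
            "resection_type": "ATLR" if r_post >= 15.0 else "limited",
            "resection_volume": resvol,
            "percent_cut_true": 100.0 * frac,
            "posterior_extent_mm": r_post,
        }
        subject_truth = {
            "subject_id": sid,
            "random_intercept": u_subject,
            "transection_fraction": frac,
            "noise": {},
            "pre_z": {},
        }
        miss3 = rng_scores.uniform() < config.missing_rate_3m
        miss12 = rng_scores.uniform() < config.missing_rate_12m
        for task in TASKS:
            pre_z = float(rng_scores.normal(config.pre_mean, config.pre_sd))
            subject_truth["pre_z"][task] = pre_z
            mean, sd = norms.lookup(task, age_surgery)
            row[f"{task}_pre_z"] = pre_z
            row[f"{task}_pre_raw"] = float(np.clip(mean + pre_z * sd, 0, TASK_MAX[task]))
            for tp, is12, missing in (("3m", 0, miss3), ("12m", 1, miss12)):
                eps = float(rng_scores.normal(0.0, config.noise_sd))
                subject_truth["noise"][f"{task}_{tp}"] = eps
                change = (
                    config.intercept
                    + config.beta_time_12m * is12
                    + config.beta_age * age_surgery
                    + config.beta_resvol * resvol
                    + config.beta_pre * pre_z
                    + config.beta_transect * frac
                    + u_subject
                    + eps
                )
                post_z = pre_z + change
                if missing:
                    row[f"{task}_{tp}_z"] = np.nan
                    row[f"{task}_{tp}_raw"] = np.nan
                else:
                    row[f"{task}_{tp}_z"] = post_z
                    row[f"{task}_{tp}_raw"] = float(
                        np.clip(mean + post_z * sd, 0, TASK_MAX[task])
                    )
        p_free = 1.0 / (1.0 + np.exp(-(config.ilae_intercept + config.ilae_beta * frac)))
        seizure_free = int(rng_scores.uniform() < p_free)
        row["ilae_12m"] = 1 if seizure_free else int(rng_scores.integers(2, 6))
        subject_truth["p_seizure_free"] = float(p_free)

        if include_maps:
            fa, md = _scalar_maps(config, grid, bundle, batch_idx, rng_maps)
            fa_maps.append(fa)
            md_maps.append(md)
        bundles.append(bundle)
        masks.append(mask)
        rows.append(row)
        truth_subjects.append(subject_truth)

    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "model": {
            "formula": "change = intercept + beta_time_12m*I(12m) + beta_age*age_surgery"
            " + beta_resvol*resection_volume + beta_pre*pre_z"
            " + beta_transect*transection_fraction + u_subject + noise",
        },
        "subjects": truth_subjects,
    }
    return SyntheticCohort(
        config=config,
        manifest=pd.DataFrame(rows),
        bundles=bundles,
        masks=masks,
        fa_maps=fa_maps,
        md_maps=md_maps,
        icv_mask=icv,
        truth=truth,
    )
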