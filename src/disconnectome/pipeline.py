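"""End-to-end orchestration of the disconnectome analysis.

Stages, in order (each writes its intermediate CSV so reruns are auditable
and byte-reproducible):

1. ``metrics``   — per-subject virtual-lesion transection, bundle mask,
                   normalized volume, median FA/MD (embarrassingly
                   parallel across subjects);
2. ``atlas``     — cohort probabilistic atlas from the per-subject bundle
                   masks, plus cohort-level min-max volume rescale;
3. ``disconnect``— atlas-based disconnection probability per subject,
                   binarized at the configured threshold;
4. ``harmonize`` — Welch gate + ComBat on batch-significant metrics;
5. ``rci``       — robust-regression reliable change classification;
6. ``fit``       — LMM change models (confound-only vs confound+tract,
                   LRT), GLMM for RCI ~ disconnection, logistic model for
                   seizure freedom ~ disconnection.

Stage outputs are pure functions of (inputs, config); the report carries a
config hash and the seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as dm
from .harmonization import harmonize_features
from .io import read_mask, read_tractogram, read_volume, write_volume
from .models import (
    binarize_ilae,
    fit_binary_glmm,
    fit_change_lmm,
    likelihood_ratio_test,
)
from .neuropsych import rci_table

log = logging.getLogger("disconnectome")


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and offending subject."""

    def __init__(self, stage: str, subject: str | None, message: str):
        self.stage = stage
        self.subject = subject
        who = f" (subject {subject})" if subject else ""
        super().__init__(f"stage '{stage}'{who}: {message}")


@dataclass
class PipelineConfig:
    manifest: str = "manifest.csv"
    data_dir: str = "."
    output_dir: str = "results"
    atlas_threshold: float = 0.5  # disconnection binarization
    probability_threshold: float = 0.01  # bundle probability-map threshold
    dilation_mm: float = 1.0  # prior-mask dilation
    rci_confidence: float = 0.80
    harmonization_alpha: float = 0.05
    harmonization_eb: bool = True
    tasks: tuple = ("encoding", "retrieval")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.atlas_threshold <= 1:
            raise ValueError("atlas_threshold must be in (0, 1]")
        if not 0 <= self.probability_threshold <= 1:
            raise ValueError("probability_threshold must be in [0, 1]")
        if self.dilation_mm < 0:
            raise ValueError("dilation_mm must be >= 0")
        if not 0 < self.rci_confidence < 1:
            raise ValueError("rci_confidence must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tasks" in raw:
            raw["tasks"] = tuple(raw["tasks"])
        return cls(**raw)

    def content_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded: the same
        analysis written elsewhere is the same analysis)."""
        payload = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self).items()
                if k not in ("manifest", "data_dir", "output_dir")
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "seed": self.seed, "stages": self.stages}, fh, indent=2, default=float)


def _subject_files(cfg: PipelineConfig, row: pd.Series) -> dict:
    base = Path(cfg.data_dir)
    out = {}
    for key in ("bundle_path", "resection_path", "fa_path", "md_path"):
        if key in row and isinstance(row[key], str):
            out[key] = base / row[key]
    return out


def stage_metrics(cfg: PipelineConfig, manifest: pd.DataFrame, out_dir: Path) -> pd.DataFrame:
    """Per-subject geometry metrics; also writes each bundle's binary mask."""
    icv_path = Path(cfg.data_dir) / "icv.nii.gz"
    icv = read_mask(icv_path) if icv_path.exists() else None
    rows = []
    masks_dir = out_dir / "bundle_masks"
    masks_dir.mkdir(parents=True, exist_ok=True)
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        t0 = time.perf_counter()
        files = _subject_files(cfg, row)
        try:
            bundle = read_tractogram(files["bundle_path"])
            resection = read_mask(files["resection_path"])
        except (KeyError, FileNotFoundError, ValueError) as exc:
            raise PipelineError("metrics", sid, str(exc)) from exc
        tr = dm.transection_fraction(bundle, resection)
        prob = dm.bundle_probability_map(bundle, resection)
        bmask = dm.threshold_map(prob, cfg.probability_threshold)
        write_volume(bmask, masks_dir / f"{sid}.nii.gz")
        rec = {
            "subject_id": sid,
            "n_streamlines": tr.n_pre,
            "n_surviving": tr.n_post,
            "percent_cut": tr.percent_cut,
            "bundle_volume_mm3": bmask.volume_mm3,
        }
        if icv is not None:
            rec["normalized_volume"] = dm.tract_volume_metrics(bmask, icv)
        for key, col in (("fa_path", "median_fa"), ("md_path", "median_md")):
            if key in files:
                rec[col] = dm.tract_median_metric(bundle, read_volume(files[key]))
        rows.append(rec)
        log.info("subject=%s stage=metrics percent_cut=%.1f wall=%.2fs", sid, tr.percent_cut, time.perf_counter() - t0)
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "metrics.csv", index=False)
    return df


def stage_atlas(cfg: PipelineConfig, manifest: pd.DataFrame, metrics_df: pd.DataFrame, out_dir: Path):
    masks = [read_mask(out_dir / "bundle_masks" / f"{sid}.nii.gz") for sid in manifest["subject_id"].astype(str)]
    atlas = dm.build_atlas(masks)
    write_volume(atlas.grid, out_dir / "atlas.nii.gz")
    if "normalized_volume" in metrics_df:
        metrics_df = metrics_df.copy()
        metrics_df["rescaled_volume"] = dm.cohort_rescale(metrics_df["normalized_volume"])
        metrics_df.to_csv(out_dir / "metrics.csv", index=False)
    return atlas, metrics_df


def stage_disconnect(cfg: PipelineConfig, manifest: pd.DataFrame, atlas, out_dir: Path) -> pd.DataFrame:
    rows = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        files = _subject_files(cfg, row)
        try:
            resection = read_mask(files["resection_path"])
        except (KeyError, FileNotFoundError) as exc:
            raise PipelineError("disconnect", sid, str(exc)) from exc
        res = dm.disconnection_probability(resection, atlas, threshold=cfg.atlas_threshold)
        rows.append(
            {
                "subject_id": sid,
                "probability": res.probability,
                "disconnected": res.disconnected,
                "threshold": res.threshold,
            }
        )
        log.info("subject=%s stage=disconnect probability=%.2f", sid, res.probability)
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "disconnection.csv", index=False)
    return df


def stage_harmonize(cfg: PipelineConfig, manifest: pd.DataFrame, metrics_df: pd.DataFrame, out_dir: Path) -> pd.DataFrame:
    table = manifest[["subject_id", "batch", "age_surgery", "age_onset"]].merge(metrics_df, on="subject_id")
    feature_cols = [c for c in ("median_fa", "median_md", "percent_cut", "rescaled_volume") if c in table]
    adjusted, tests, adj = harmonize_features(
        table,
        feature_cols,
        batch_col="batch",
        covariate_cols=["age_surgery", "age_onset"],
        alpha=cfg.harmonization_alpha,
        eb=cfg.harmonization_eb,
    )
    welch_df = pd.DataFrame(
        [{"feature": k, "t": v.t, "df": v.df, "p": v.p, "adjusted": v.p < cfg.harmonization_alpha} for k, v in tests.items()]
    )
    welch_df.to_csv(out_dir / "welch_tests.csv", index=False)
    adjusted.to_csv(out_dir / "harmonized_metrics.csv", index=False)
    if adj is not None:
        adj.to_json(out_dir / "combat_parameters.json")
    return adjusted


def stage_rci(cfg: PipelineConfig, manifest: pd.DataFrame, out_dir: Path) -> pd.DataFrame:
    try:
        rci = rci_table(
            manifest,
            tasks=cfg.tasks,
            confidence=cfg.rci_confidence,
        )
    except ValueError as exc:
        raise PipelineError("rci", None, str(exc)) from exc
    rci.to_csv(out_dir / "rci.csv", index=False)
    return rci


def _long_table(manifest: pd.DataFrame, harmonized: pd.DataFrame, task: str) -> pd.DataFrame:
    base = manifest.merge(
        harmonized[[c for c in ("subject_id", "percent_cut", "rescaled_volume") if c in harmonized]],
        on="subject_id",
        how="left",
    )
    rows = []
    for _, r in base.iterrows():
        for tp in ("3m", "12m"):
            post = r.get(f"{task}_{tp}_z", np.nan)
            rows.append(
                {
                    "subject_id": r["subject_id"],
                    "timepoint": tp,
                    "change_z": post - r[f"{task}_pre_z"],
                    "age_surgery": r["age_surgery"],
                    "age_onset": r["age_onset"],
                    "resection_volume": r["resection_volume"],
                    "pre_z": r[f"{task}_pre_z"],
                    "transection": r.get("percent_cut", np.nan) / 100.0,
                    "rescaled_volume": r.get("rescaled_volume", np.nan),
                }
            )
    return pd.DataFrame(rows)


def stage_fit(cfg: PipelineConfig, manifest: pd.DataFrame, harmonized: pd.DataFrame, rci: pd.DataFrame, disconnect: pd.DataFrame, out_dir: Path) -> dict:
    results: dict = {}
    for task in cfg.tasks:
        lt = _long_table(manifest, harmonized, task)
        null = fit_change_lmm(lt)
        full = fit_change_lmm(lt, tract_term="transection")
        lrt = likelihood_ratio_test(null, full)
        results[f"lmm_{task}"] = {
            "null": null.summary_dict(),
            "full": full.summary_dict(),
            "lrt": {"chi_sq": lrt.chi_sq, "df": lrt.df, "p": lrt.p},
        }
    # RCI decline vs atlas-based disconnection (both postoperative timepoints)
    rci_enc = rci[rci["task"] == cfg.tasks[0]].merge(disconnect[["subject_id", "disconnected"]], on="subject_id")
    rci_enc = rci_enc.dropna(subset=["rci"])
    rci_enc["decline"] = (rci_enc["rci"] == -1).astype(int)
    rci_enc = rci_enc.merge(manifest[["subject_id", "resection_volume"]], on="subject_id")
    if rci_enc["decline"].nunique() == 2 and rci_enc["disconnected"].nunique() == 2:
        glmm = fit_binary_glmm(rci_enc, outcome="decline", predictor="disconnected")
        results["glmm_rci"] = glmm.summary_dict()
    # seizure freedom vs disconnection (one row per subject: logistic)
    seiz = manifest[["subject_id", "ilae_12m", "resection_volume"]].copy()
    seiz["seizure_free"] = [binarize_ilae(v) for v in seiz["ilae_12m"]]
    seiz = seiz.merge(disconnect[["subject_id", "disconnected"]], on="subject_id")
    if seiz["seizure_free"].nunique() == 2 and seiz["disconnected"].nunique() == 2:
        logit = fit_binary_glmm(seiz, outcome="seizure_free", predictor="disconnected", random_intercept=False)
        results["seizure_outcome"] = logit.summary_dict()
    with open(out_dir / "model_fits.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return results


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(cfg.data_dir) / cfg.manifest
    if not manifest_path.exists():
        raise PipelineError("setup", None, f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)

    report = PipelineReport(config_hash=cfg.content_hash(), seed=cfg.seed)
    metrics_df = stage_metrics(cfg, manifest, out_dir)
    report.stages["metrics"] = {"n_subjects": len(metrics_df)}
    atlas, metrics_df = stage_atlas(cfg, manifest, metrics_df, out_dir)
    report.stages["atlas"] = {"n_subjects": atlas.n_subjects}
    disconnect = stage_disconnect(cfg, manifest, atlas, out_dir)
    report.stages["disconnect"] = {"n_disconnected": int(disconnect["disconnected"].sum())}
    harmonized = stage_harmonize(cfg, manifest, metrics_df, out_dir)
    report.stages["harmonize"] = {"n_features": int(len(harmonized.columns))}
    rci = stage_rci(cfg, manifest, out_dir)
    report.stages["rci"] = {
        "n_decline": int((rci["rci"] == -1).sum()),
        "n_classified": int(rci["rci"].notna().sum()),
    }
    fits = stage_fit(cfg, manifest, harmonized, rci, disconnect, out_dir)
    report.stages["fit"] = {k: v.get("lrt", {}) for k, v in fits.items() if isinstance(v, dict) and "lrt" in v}
    report.to_json(out_dir / "report.json")
    return report
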