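"""End-to-end orchestration: simulate -> calibrate/extract -> split ->
select -> fit -> map.

``run_pipeline`` drives the whole analysis from one config object (or YAML
file): a synthetic scene is generated, every sample's cube triplet is
white/dark-calibrated and reduced to its mean ROI spectrum, the spectra
are trimmed to the working range (default 420-1000 nm), SPXY partitions
the cohort per organ (75 % calibration), random frog ranks wavelengths
per modelling target (leaf, stem, root, whole-plant), F-PLSR and RF-PLSR
models are fitted and scored for each target, and nitrogen distribution
maps are rendered for a handful of held-out samples with the whole-plant
RF-PLSR model.  A manifest records seeds, per-stage artifacts and content
hashes; identical seeds give identical hashes.

Two profiles exist: ``reduced`` (default; 60 samples, 500-iteration frog
chains, 5 runs) keeps a full run in the minutes range, and ``paper``
restores the full-scale study conditions (280 samples, 10 000 iterations,
50 runs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import chemical_imaging, synthetic_data
from .hypercube_io import SpectraTable, trim_bands
from .partitioning import SplitResult, spxy_split
from .regression import full_vs_selected_report
from .synthetic_data import SceneConfig
from .variable_selection import FrogConfig, random_frog

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

TARGETS = ("leaf", "stem", "root", "whole-plant")
DEFAULT_K = {"leaf": 10, "stem": 9, "root": 7, "whole-plant": 8}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    profile: str = "reduced"            # "reduced" | "paper"
    out_dir: str = "hypernitro_run"
    trim_low_nm: float = 420.0
    trim_high_nm: float = 1000.0
    split_fraction: float = 0.75
    stratify: bool = True
    k_per_target: dict = field(default_factory=lambda: dict(DEFAULT_K))
    max_lvs: int = 20
    n_maps: int = 4
    scene: SceneConfig | None = None
    frog: FrogConfig | None = None

    def resolved(self) -> "PipelineConfig":
        """Fill scene/frog configs from the profile and master seed."""
        cfg = dataclasses.replace(self)
        if cfg.profile not in ("reduced", "paper"):
            raise ValueError(f"unknown profile {cfg.profile!r}")
        if cfg.scene is None:
            if cfg.profile == "paper":
                cfg.scene = SceneConfig(rng_seed=cfg.seed)
            else:
                cfg.scene = SceneConfig(rng_seed=cfg.seed, n_leaf=24,
                                        n_stem=24, n_root=12,
                                        image_shape=(16, 12))
        if cfg.frog is None:
            if cfg.profile == "paper":
                cfg.frog = FrogConfig(rng_seed=cfg.seed + 1)
            else:
                cfg.frog = FrogConfig(T=500, n_runs=5, rng_seed=cfg.seed + 1)
        for t, k in cfg.k_per_target.items():
            if t not in TARGETS:
                raise ValueError(f"unknown model target {t!r}")
            if k < 1:
                raise ValueError(f"k for target {t!r} must be >= 1")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scene = raw.pop("scene", None)
        frog = raw.pop("frog", None)
        cfg = cls(**raw)
        if scene is not None:
            if "image_shape" in scene:
                scene["image_shape"] = tuple(scene["image_shape"])
            if "band_effects" in scene:
                scene["band_effects"] = tuple(
                    tuple(t) for t in scene["band_effects"])
            cfg.scene = SceneConfig(**scene)
        if frog is not None:
            cfg.frog = FrogConfig(**frog)
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _target_rows(table: SpectraTable, target: str) -> np.ndarray:
    if target == "whole-plant":
        return np.arange(table.n_samples)
    return np.where(table.organs == target)[0]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to
    ``<out_dir>/manifest.json``)."""
    cfg = config.resolved()
    out = cfg.out_dir
    try:
        os.makedirs(out, exist_ok=True)
        probe = os.path.join(out, ".write_probe")
        with open(probe, "w") as fh:
            fh.write("ok")
        os.remove(probe)
    except OSError as e:                 # abort before any compute
        raise PipelineError("setup", e)

    manifest: dict = {
        "seed": cfg.seed, "profile": cfg.profile,
        "stages": {}, "files": {}, "metrics": {},
    }
    t0 = time.time()

    def log(stage, **extra):
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 3),
                                     **extra}

    # -- simulate ----------------------------------------------------------
    try:
        samples = synthetic_data.generate_scene(cfg.scene)
        ref_csv = os.path.join(out, "reference_tnc.csv")
        synthetic_data.write_reference_table(samples, ref_csv)
    except Exception as e:
        raise PipelineError("simulate", e)
    log("simulate", n_samples=len(samples), scene_seed=cfg.scene.rng_seed)

    # -- extract -----------------------------------------------------------
    try:
        table = synthetic_data.extract_spectra_table(samples)
        table = trim_bands(table, cfg.trim_low_nm, cfg.trim_high_nm)
        spectra_csv = os.path.join(out, "spectra.csv")
        table.to_csv(spectra_csv)
    except Exception as e:
        raise PipelineError("extract", e)
    log("extract", n_wavelengths=table.n_wavelengths,
        range_nm=[float(table.wavelengths[0]), float(table.wavelengths[-1])])

    # -- split -------------------------------------------------------------
    try:
        split = spxy_split(table, cfg.split_fraction, per_organ=cfg.stratify)
        split_json = os.path.join(out, "split.json")
        split.to_json(split_json)
    except Exception as e:
        raise PipelineError("split", e)
    log("split", n_calibration=split.n_calibration,
        n_prediction=split.n_prediction, counts=split.per_organ_counts)

    # -- select + fit per target -------------------------------------------
    metrics_rows = []
    rf_whole_model = None
    for ti, target in enumerate(TARGETS):
        rows = _target_rows(table, target)
        sub = table.subset(rows)
        in_cal = np.isin(table.sample_ids[rows], split.calibration_ids)
        cal_idx = np.where(in_cal)[0]
        pred_idx = np.where(~in_cal)[0]
        try:
            frog_cfg = dataclasses.replace(cfg.frog,
                                           rng_seed=cfg.frog.rng_seed + 101 * ti)
            frog = random_frog(sub.subset(cal_idx), frog_cfg)
            with open(os.path.join(out, f"frog_{target}.json"), "w") as fh:
                json.dump(frog.to_dict(), fh)
        except Exception as e:
            raise PipelineError(f"select[{target}]", e)
        try:
            k = cfg.k_per_target.get(target, DEFAULT_K[target])
            report = full_vs_selected_report(sub, cal_idx, pred_idx, frog, k,
                                             max_lvs=cfg.max_lvs)
            with open(os.path.join(out, f"model_{target}.json"), "w") as fh:
                json.dump({
                    "target": target,
                    "F-PLSR": report.full_model.to_dict(),
                    "RF-PLSR": report.selected_model.to_dict(),
                    "selected_wavelengths_nm":
                        [float(w) for w in report.selected_wavelengths],
                    "elimination_percent": report.elimination_percent,
                }, fh)
        except Exception as e:
            raise PipelineError(f"fit[{target}]", e)
        for name, m in (("F-PLSR", report.full_metrics),
                        ("RF-PLSR", report.selected_metrics)):
            metrics_rows.append({
                "target": target, "model": name,
                "n_wavelengths": (table.n_wavelengths if name == "F-PLSR"
                                  else k),
                **{kk: round(vv, 6) if isinstance(vv, float) else vv
                   for kk, vv in m.as_dict().items()},
            })
        manifest["metrics"][target] = report.as_dict()
        if target == "whole-plant":
            rf_whole_model = report.selected_model
        log(f"model[{target}]", k=k,
            selected_nm=[float(w) for w in report.selected_wavelengths])

    metrics_csv = os.path.join(out, "metrics.csv")
    pd.DataFrame(metrics_rows).to_csv(metrics_csv, index=False)

    # -- map ---------------------------------------------------------------
    try:
        maps = []
        by_id = {s.sample_id: s for s in samples}
        chosen = [by_id[str(sid)] for sid in split.prediction_ids[:cfg.n_maps]]
        for s in chosen:
            cube = trim_bands(s.calibrated(), cfg.trim_low_nm, cfg.trim_high_nm)
            maps.append(chemical_imaging.predict_map(
                cube, s.roi_mask, rf_whole_model, organ=s.organ,
                sample_id=s.sample_id))
        legend = chemical_imaging.render_maps(
            maps, os.path.join(out, "maps"), per_organ_scales=True)
    except Exception as e:
        raise PipelineError("map", e)
    log("map", n_maps=len(maps), organs=sorted(legend["organs"]))

    # -- manifest ----------------------------------------------------------
    for root, _, names in os.walk(out):
        for name in sorted(names):
            if name.endswith((".csv", ".json", ".txt")) and name != "manifest.json":
                path = os.path.join(root, name)
                rel = os.path.relpath(path, out)
                manifest["files"][rel] = _sha256(path)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
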