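"""Reproducible multi-stage pipeline with structured configuration.

Stages (dependency order): simulate → rasterize-ref → train → predict →
cues → ucm → segment → evaluate.  A single global seed deterministically
derives every stage's seed; outputs are written under one directory with a
manifest (config hash, per-stage outputs) and re-runs with an unchanged
configuration reuse existing outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from .cues import CueConfig, combine_with_fcn, gpb
from .evaluation import MatchConfig, error_map, extract_edgels, match_edgels, pr_curve
from .fcn import FCNBoundaryDetector, BoundaryProbabilityMap
from .grids import MultibandRaster
from .grouping import CombinatorialGrouping
from .io import load_raster, load_vector, write_raster, write_vector, VectorBoundarySet
from .owt import OWTUCM
from .reference import BoundaryMask, prepare_reference
from .synthetic import SceneParams, derive_seed, scene_batch

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("fieldseg")

STAGES = (
    "simulate",
    "rasterize-ref",
    "train",
    "predict",
    "cues",
    "ucm",
    "segment",
    "evaluate",
)

_NETWORK_KEYS = {"in_channels", "encoder_blocks", "tile", "overlap"}
_TRAIN_KEYS = {
    "patch_size",
    "n_patches",
    "batch_size",
    "epochs",
    "learning_rate",
    "beta1",
    "beta2",
    "boundary_class_weight",
}
_GROUPING_KEYS = {
    "max_combine",
    "max_candidates",
    "overlap_tolerance",
    "min_area_frac",
    "n_levels",
}


def _check_keys(section: str, given: dict, allowed: set):
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section '{section}': {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Nested pipeline configuration; unknown keys are errors, and the file
    representation round-trips losslessly."""

    scene: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    cues: dict = field(default_factory=dict)
    match: dict = field(default_factory=dict)
    grouping: dict = field(default_factory=dict)
    n_train_scenes: int = 3
    n_test_scenes: int = 3
    n_thresholds: int = 15
    alpha_fcn: float = 0.5
    seed: int = 0
    out_dir: str = "fieldseg_out"

    def __post_init__(self):
        _check_keys(
            "scene", self.scene, {f.name for f in dataclasses.fields(SceneParams)}
        )
        _check_keys("network", self.network, _NETWORK_KEYS)
        _check_keys("train", self.train, _TRAIN_KEYS)
        _check_keys(
            "cues", self.cues, {f.name for f in dataclasses.fields(CueConfig)}
        )
        _check_keys(
            "match", self.match, {f.name for f in dataclasses.fields(MatchConfig)}
        )
        _check_keys("grouping", self.grouping, _GROUPING_KEYS)

    # -- file representation -------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        _check_keys("<root>", d, allowed)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    # -- derived stage objects -----------------------------------------
    def scene_params(self, seed: int) -> SceneParams:
        return SceneParams(**{**self.scene, "seed": seed})

    def detector(self) -> FCNBoundaryDetector:
        return FCNBoundaryDetector(
            **self.network, **self.train, seed=derive_seed(self.seed, 3)
        )

    def cue_config(self) -> CueConfig:
        return CueConfig(**{**self.cues, "seed": derive_seed(self.seed, 4)})

    def match_config(self) -> MatchConfig:
        return MatchConfig(**self.match)


def _write_truth(out: Path, name: str, truth) -> None:
    write_raster(out / f"{name}.tif", truth.image)
    write_vector(out / f"{name}_lines.geojson", truth.boundary_lines)
    polys = VectorBoundarySet(
        geometries=[g for _, g in truth.field_polygons],
        properties=[{"field_id": fid} for fid, _ in truth.field_polygons],
        crs=truth.boundary_lines.crs,
    )
    write_vector(out / f"{name}_fields.geojson", polys)


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages in dependency order and return the
    manifest.  Stage outputs already present from a run with an identical
    configuration are reused."""
    stages = set(STAGES if stages is None else stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": chash, "stages": {}}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash:
            manifest = old
    manifest["config_hash"] = chash

    def done(stage, outputs):
        manifest["stages"][stage] = {
            "outputs": [str(p) for p in outputs],
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.info("stage %s done (%d outputs)", stage, len(outputs))

    def cached(stage):
        rec = manifest["stages"].get(stage)
        ok = rec is not None and all(Path(p).exists() for p in rec["outputs"])
        if ok:
            log.info("stage %s cached", stage)
        return ok

    def require(stage, path):
        if not Path(path).exists():
            raise FileNotFoundError(
                f"missing input {path}; run stage '{stage}' first"
            )
        return path

    n_tr, n_te = config.n_train_scenes, config.n_test_scenes

    if "simulate" in stages and not cached("simulate"):
        params = config.scene_params(seed=0)
        train_scenes = scene_batch(params, n_tr, seed=derive_seed(config.seed, 1))
        test_scenes = scene_batch(params, n_te, seed=derive_seed(config.seed, 2))
        outputs = []
        for i, t in enumerate(train_scenes):
            _write_truth(out, f"train_{i}", t)
            outputs += [out / f"train_{i}.tif", out / f"train_{i}_lines.geojson"]
        for i, t in enumerate(test_scenes):
            _write_truth(out, f"test_{i}", t)
            outputs += [out / f"test_{i}.tif", out / f"test_{i}_lines.geojson"]
        done("simulate", outputs)

    if "rasterize-ref" in stages and not cached("rasterize-ref"):
        outputs = []
        for name in [f"train_{i}" for i in range(n_tr)] + [
            f"test_{i}" for i in range(n_te)
        ]:
            img = load_raster(require("simulate", out / f"{name}.tif"))
            lines = load_vector(require("simulate", out / f"{name}_lines.geojson"))
            ref = prepare_reference(lines, img.grid)
            write_raster(
                out / f"{name}_ref.tif",
                MultibandRaster(data=ref.mask.astype(np.uint8), grid=img.grid),
            )
            outputs.append(out / f"{name}_ref.tif")
        done("rasterize-ref", outputs)

    if "train" in stages and not cached("train"):
        images, masks = [], []
        for i in range(n_tr):
            img = load_raster(require("simulate", out / f"train_{i}.tif"))
            ref = load_raster(require("rasterize-ref", out / f"train_{i}_ref.tif"))
            images.append(img)
            masks.append(BoundaryMask(grid=img.grid, mask=ref.data[0] > 0))
        det = config.detector()
        det.fit(images, masks)
        det.save(out / "detector.npz")
        np.savetxt(out / "loss_history.txt", det.loss_history_)
        done("train", [out / "detector.npz", out / "loss_history.txt"])

    if "predict" in stages and not cached("predict"):
        det = FCNBoundaryDetector.load(require("train", out / "detector.npz"))
        outputs = []
        for i in range(n_te):
            img = load_raster(require("simulate", out / f"test_{i}.tif"))
            pm = det.predict_proba(img)
            write_raster(
                out / f"test_{i}_prob.tif",
                MultibandRaster(data=pm.prob, grid=img.grid),
            )
            outputs.append(out / f"test_{i}_prob.tif")
        done("predict", outputs)

    if "cues" in stages and not cached("cues"):
        ccfg = config.cue_config()
        outputs = []
        for i in range(n_te):
            img = load_raster(require("simulate", out / f"test_{i}.tif"))
            prob = load_raster(require("predict", out / f"test_{i}_prob.tif"))
            sig = gpb(img, ccfg)
            sig = combine_with_fcn(
                sig,
                BoundaryProbabilityMap(grid=prob.grid, prob=prob.data[0]),
                config.alpha_fcn,
                ccfg.lift_mode,
            )
            write_raster(
                out / f"test_{i}_cues.tif",
                MultibandRaster(data=sig.strength, grid=img.grid),
            )
            outputs.append(out / f"test_{i}_cues.tif")
        done("cues", outputs)

    if "ucm" in stages and not cached("ucm"):
        from .cues import OrientedContourSignal

        owt = OWTUCM()
        outputs = []
        for i in range(n_te):
            cues_r = load_raster(require("cues", out / f"test_{i}_cues.tif"))
            sig = OrientedContourSignal(grid=cues_r.grid, strength=cues_r.data)
            hier = owt.transform(sig)
            write_raster(
                out / f"test_{i}_ucm.tif",
                MultibandRaster(data=hier.ucm_raster(), grid=cues_r.grid),
            )
            _save_hierarchy(out / f"test_{i}_hierarchy.json", hier)
            outputs += [out / f"test_{i}_ucm.tif", out / f"test_{i}_hierarchy.json"]
        done("ucm", outputs)

    if "segment" in stages and not cached("segment"):
        from .cues import OrientedContourSignal

        owt = OWTUCM()
        grouper = CombinatorialGrouping(**config.grouping)
        outputs = []
        for i in range(n_te):
            cues_r = load_raster(require("cues", out / f"test_{i}_cues.tif"))
            sig = OrientedContourSignal(grid=cues_r.grid, strength=cues_r.data)
            hier = owt.transform(sig)
            seg = grouper.transform(hier)
            write_raster(
                out / f"test_{i}_segments.tif",
                MultibandRaster(
                    data=seg.labels.astype(np.int32), grid=cues_r.grid
                ),
            )
            from .grouping import segment_polygons

            polys = segment_polygons(seg, cues_r.grid)
            write_vector(
                out / f"test_{i}_segments.geojson",
                VectorBoundarySet(
                    geometries=[g for _, g in polys],
                    properties=[{"segment_id": sid} for sid, _ in polys],
                    crs=cues_r.grid.crs,
                ),
            )
            outputs += [
                out / f"test_{i}_segments.tif",
                out / f"test_{i}_segments.geojson",
            ]
        done("segment", outputs)

    if "evaluate" in stages and not cached("evaluate"):
        mcfg = config.match_config()
        metrics = {"d_max_px": mcfg.d_max, "tolerance_m": mcfg.tolerance_m, "scenes": []}
        outputs = []
        for i in range(n_te):
            ucm_r = load_raster(require("ucm", out / f"test_{i}_ucm.tif"))
            ref_r = load_raster(require("rasterize-ref", out / f"test_{i}_ref.tif"))
            res = pr_curve(
                ucm_r.data[0], ref_r.data[0] > 0, mcfg, config.n_thresholds,
                apply_nms=False,
            )
            det_e = extract_edgels(ucm_r.data[0] > res["best_threshold"])
            ref_e = extract_edgels(ref_r.data[0] > 0)
            corr = match_edgels(det_e, ref_e, mcfg)
            emap = error_map(corr, ucm_r.grid.shape)
            write_raster(
                out / f"test_{i}_errors.tif",
                MultibandRaster(data=emap, grid=ucm_r.grid),
            )
            best = res["best"]
            metrics["scenes"].append(
                {
                    "scene": i,
                    "best_f": res["best_f"],
                    "best_threshold": res["best_threshold"],
                    "precision": best.precision if best else 0.0,
                    "recall": best.recall if best else 0.0,
                    "curve": res["curve"],
                }
            )
            curve_csv = out / f"test_{i}_pr_curve.csv"
            curve_csv.write_text(
                "threshold,precision,recall,f_measure\n"
                + "\n".join(
                    f"{t:.6f},{p:.6f},{r:.6f},{f:.6f}" for t, p, r, f in res["curve"]
                )
                + "\n"
            )
            outputs += [out / f"test_{i}_errors.tif", curve_csv]
        fs = [s["best_f"] for s in metrics["scenes"]]
        metrics["mean_best_f"] = float(np.mean(fs)) if fs else 0.0
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        outputs.append(out / "metrics.json")
        done("evaluate", outputs)

    return manifest


def _save_hierarchy(path, hier) -> None:
    doc = {
        "n_regions": hier.finest.n_regions,
        "merges": [
            {"a": a, "b": b, "new": new, "strength": float(s)}
            for a, b, new, s in hier.merges
        ],
    }
    Path(path).write_text(json.dumps(doc))
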