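"""End-to-end orchestration: simulate -> detect -> QC -> train -> evaluate.

A single YAML-style config dictionary drives every stage; each stage seed
is derived deterministically from the global seed and the stage name, so a
rerun with the same config reproduces byte-identical artifacts.  Every
artifact is recorded in a run manifest with its SHA-256 content hash.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from . import detector as _detector
from . import evaluation as _evaluation
from . import models as _models
from . import proteomics as _proteomics
from . import synthetic as _synthetic
from .records import EyeRecord, cohort_to_frame

__all__ = ["stage_seed", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {"n_patients": 100},
    "images": {"n_images": 6, "fundus": {}},
    "detector": {},
    "models": {
        "image_nb": {},
        "proteomics_gbm": {},
        "combined_gbm": {},
    },
    "cv": {"k": 10, "repeats": 10},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: stable hash of (global seed, stage name)."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merged(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


class PipelineError(RuntimeError):
    pass


def _simulate_stage(cfg: dict, out: Path, manifest: dict) -> tuple[list[EyeRecord], Path]:
    seed = stage_seed(cfg["seed"], "simulate")
    cohort_spec = _synthetic.SyntheticCohortSpec(**cfg["cohort"], seed=seed)
    records, summary = _synthetic.generate_cohort(cohort_spec)
    cohort_path = out / "cohort.csv"
    cohort_to_frame(records).to_csv(cohort_path, index=False)
    (out / "exclusion_summary.json").write_text(
        json.dumps(summary.as_dict(), indent=2)
    )

    img_cfg = cfg.get("images") or {}
    n_images = int(img_cfg.get("n_images", 0))
    truth_rows = []
    img_dir = out / "images"
    if n_images:
        img_dir.mkdir(exist_ok=True)
        for i in range(n_images):
            fspec = _synthetic.SyntheticFundusSpec(
                **img_cfg.get("fundus", {}), seed=stage_seed(seed, f"image{i}")
            )
            image, truths = _synthetic.generate_fundus(fspec, image_id=f"IMG{i:03d}")
            iio.imwrite(
                img_dir / f"{image.image_id}.png",
                (image.pixels * 255).round().astype(np.uint8),
            )
            for t in truths:
                truth_rows.append(
                    {
                        "image_id": image.image_id,
                        "center_row": t.center_row,
                        "center_col": t.center_col,
                        "diameter_px": t.diameter_px,
                    }
                )
        pd.DataFrame(
            truth_rows,
            columns=["image_id", "center_row", "center_col", "diameter_px"],
        ).to_csv(out / "truth.csv", index=False)
    return records, img_dir if n_images else None


def _detect_stage(cfg: dict, out: Path, img_dir: Path | None) -> None:
    if img_dir is None:
        return
    det_cfg = _detector.DetectorConfig(
        **cfg.get("detector", {}), seed=stage_seed(cfg["seed"], "detect")
    )
    truth = pd.read_csv(out / "truth.csv")
    images = []
    for png in sorted(img_dir.glob("*.png")):
        px = iio.imread(png).astype(float) / 255.0
        images.append(
            _detector.FundusImage(pixels=px, image_id=png.stem)
        )
    half = max(1, len(images) // 2)
    train_cands: list = []
    for image in images[:half]:
        cands = _detector.detect_candidates(image, det_cfg)
        truths = [
            _synthetic.GroundTruthMA(r.center_row, r.center_col, r.diameter_px)
            for r in truth[truth.image_id == image.image_id].itertuples()
        ]
        _detector.match_to_ground_truth(cands, truths, det_cfg.match_tolerance_px)
        train_cands.extend(cands)
    model = _detector.train_candidate_classifier(train_cands, det_cfg)
    _detector.save_model(model, det_cfg, out / "detector_model.joblib")

    rows = []
    for image in images:
        cands = _detector.detect_candidates(image, det_cfg)
        _detector.score_candidates(cands, model)
        for c in cands:
            rows.append(
                {
                    "image_id": c.image_id,
                    "centroid_row": c.centroid[0],
                    "centroid_col": c.centroid[1],
                    "area": c.features.area,
                    "rotational_inertia": c.features.rotational_inertia,
                    "mean_opened": c.features.mean_intensity_opened,
                    "mean_green": c.features.mean_intensity_green,
                    "sd_green": c.features.sd_intensity_green,
                    "score": c.score,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "image_id",
            "centroid_row",
            "centroid_col",
            "area",
            "rotational_inertia",
            "mean_opened",
            "mean_green",
            "sd_green",
            "score",
        ],
    ).to_csv(out / "candidates.csv", index=False)


def _qc_stage(records: list[EyeRecord], out: Path) -> list[EyeRecord]:
    included = [r for r in records if r.included]
    samples = [
        _proteomics.TearSample(
            patient_id=r.patient_id,
            eye=r.eye,
            volume_uL=r.volume_uL,
            time_min=r.time_min,
            concentrations=r.proteins,
        )
        for r in included
        if r.volume_uL is not None and r.proteins is not None
    ]
    retained, report = _proteomics.qc_filter(samples)
    (out / "qc_report.json").write_text(json.dumps(report.as_dict(), indent=2))
    _proteomics.samples_to_frame(retained).to_csv(out / "retained.csv", index=False)
    keep = {(s.patient_id, s.eye) for s in retained}
    return [r for r in included if r.key in keep]


def _train_and_evaluate(cfg: dict, records: list[EyeRecord], out: Path) -> dict:
    reports = {}
    model_cfgs = cfg.get("models") or {}
    if not model_cfgs:
        raise PipelineError("config requests no screening models")
    for kind, overrides in model_cfgs.items():
        if kind in ("proteomics_gbm", "combined_gbm") and any(
            r.proteins is None for r in records
        ):
            raise PipelineError(
                f"{kind} requested but some records lack a protein table"
            )
        if kind in ("image_nb", "combined_gbm") and any(
            r.ma_count is None for r in records
        ):
            raise PipelineError(f"{kind} requested but some records lack an MA count")
        spec = _models.ModelSpec(
            model_kind=kind,
            seed=stage_seed(cfg["seed"], f"train:{kind}"),
            **overrides,
        )
        model = _models.train(records, spec)
        _models.save_model(model, out / f"model_{kind}.joblib")
        cv = _evaluation.CVConfig(
            **cfg.get("cv", {}), seed=stage_seed(cfg["seed"], f"cv:{kind}")
        )
        report = _evaluation.run_cv(records, spec, cv)
        path = out / f"metrics_{kind}.json"
        path.write_text(json.dumps(report.as_dict(), indent=2))
        reports[kind] = report.as_dict()["aggregate"]
    return reports


def run_pipeline(config: dict | None, out_dir) -> dict:
    """Execute all stages in dependency order and write ``manifest.json``.

    Returns the manifest: per-stage log entries with elapsed times, a table
    of artifact SHA-256 hashes, the derived seeds, and aggregate metrics of
    the three screening models.  Rerunning with an identical config
    reproduces identical artifact hashes.
    """
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "seeds": {
            s: stage_seed(cfg["seed"], s)
            for s in ("simulate", "detect", "qc", "train", "evaluate")
        },
        "stages": [],
        "artifacts": {},
    }

    def log_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            manifest["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        manifest["stages"].append(
            {"stage": name, "status": "ok", "elapsed_s": time.perf_counter() - t0}
        )
        return result

    records, img_dir = log_stage("simulate", _simulate_stage, cfg, out, manifest)
    log_stage("detect", _detect_stage, cfg, out, img_dir)
    modelling_records = log_stage("proteomics_qc", _qc_stage, records, out)
    manifest["metrics"] = log_stage(
        "train_evaluate", _train_and_evaluate, cfg, modelling_records, out
    )

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
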