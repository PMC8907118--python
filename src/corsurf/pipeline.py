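"""End-to-end reconstruction workflow and batch evaluation.

The reconstruction pipeline runs four stages per hemisphere: intensity
normalization, hemispheric white-matter segmentation, level-set regression,
and topology correction + surface extraction (with optional smoothing).
Hemispheres are independent tasks and may run concurrently with results
identical to sequential execution; every stage writes its output to a file
another stage (or the user) can consume standalone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import read_volume, write_surface
from .levelset import DEFAULT_TRUNCATION, write_levelset
from .topology import DigitalTopologyConfig, extract_surface, smooth_surface
from .unet import (
    TrainedModel,
    load_model,
    normalize_intensity,
    predict_sliding,
    segment_hemispheres,
    target_to_levelset,
)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "run_evaluation_suite"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and hemisphere."""

    def __init__(self, stage: str, hemisphere: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed for hemisphere {hemisphere}: {cause}")
        self.stage = stage
        self.hemisphere = hemisphere
        self.cause = cause


@dataclass
class PipelineConfig:
    segmentation_model: str | Path | TrainedModel
    regression_model: str | Path | TrainedModel
    output_dir: str | Path = "."
    hemispheres: str = "both"  # left | right | both
    topology: DigitalTopologyConfig = field(default_factory=DigitalTopologyConfig)
    truncation: float = DEFAULT_TRUNCATION
    smoothing_iters: int = 0
    parallel: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.hemispheres not in ("left", "right", "both"):
            raise ValueError("hemispheres must be left, right or both")


def _resolve_model(ref) -> TrainedModel:
    if isinstance(ref, TrainedModel):
        return ref
    path = Path(ref)
    if not path.is_dir():
        raise FileNotFoundError(f"model directory not found: {path}")
    return load_model(path)


def _config_digest(cfg: PipelineConfig) -> str:
    payload = {
        "hemispheres": cfg.hemispheres,
        "connectivity": [
            cfg.topology.foreground_connectivity,
            cfg.topology.background_connectivity,
        ],
        "truncation": cfg.truncation,
        "smoothing_iters": cfg.smoothing_iters,
        "seed": cfg.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(image_path, cfg: PipelineConfig) -> dict:
    """Reconstruct white surfaces from a T1-like volume.

    Returns a manifest dict (also written to ``manifest.json`` in the output
    directory) recording per-stage wall times, output paths, and per-
    hemisphere status.  A failing stage aborts its hemisphere only; the
    result records the stage-named error and the other hemisphere completes.
    Raises :class:`StageError` if every selected hemisphere failed.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest: dict = {
        "image": str(image_path),
        "config_digest": _config_digest(cfg),
        "seed": cfg.seed,
        "stages": {},
        "hemispheres": {},
    }

    t0 = time.time()
    image = read_volume(image_path)
    seg_model = _resolve_model(cfg.segmentation_model)
    reg_model = _resolve_model(cfg.regression_model)
    normalized = normalize_intensity(image)
    manifest["stages"]["normalize"] = time.time() - t0

    t0 = time.time()
    mask_left, mask_right = segment_hemispheres(seg_model, normalized)
    manifest["stages"]["segment"] = time.time() - t0

    wanted = ["left", "right"] if cfg.hemispheres == "both" else [cfg.hemispheres]
    masks = {"left": mask_left, "right": mask_right}

    def reconstruct_hemi(side: str) -> dict:
        record: dict = {"status": "ok", "stages": {}}
        mask = masks[side]
        try:
            if mask.data.sum() == 0:
                raise ValueError("empty mask")
        except ValueError as exc:
            raise StageError("segment", side, exc) from exc
        try:
            t = time.time()
            pred = predict_sliding(reg_model, normalized, mask)
            ls = target_to_levelset(pred, truncation=cfg.truncation)
            ls_path = out_dir / f"{side}.levelset.nii.gz"
            write_levelset(ls, ls_path)
            record["levelset"] = str(ls_path)
            record["stages"]["regress"] = time.time() - t
        except Exception as exc:
            raise StageError("regress", side, exc) from exc
        try:
            t = time.time()
            mesh = extract_surface(ls, cfg.topology, correct=True)
            if cfg.smoothing_iters:
                mesh = smooth_surface(mesh, cfg.smoothing_iters)
            surf_path = out_dir / f"{side}.white.surf"
            write_surface(mesh, surf_path, format="freesurfer")
            record["surface"] = str(surf_path)
            record["n_vertices"] = mesh.n_vertices
            record["euler_characteristic"] = mesh.euler_characteristic()
            record["stages"]["extract"] = time.time() - t
        except Exception as exc:
            raise StageError("extract", side, exc) from exc
        return record

    def safe(side):
        try:
            return side, reconstruct_hemi(side)
        except StageError as exc:
            logger.error("%s", exc)
            return side, {"status": "failed", "stage": exc.stage, "error": str(exc)}

    if cfg.parallel and len(wanted) > 1:
        with ThreadPoolExecutor(max_workers=len(wanted)) as pool:
            results = list(pool.map(safe, wanted))
    else:
        results = [safe(side) for side in wanted]
    for side, record in results:
        manifest["hemispheres"][side] = record

    manifest["wall_time"] = time.time() - t_start
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if all(r["status"] == "failed" for _, r in results):
        failed = manifest["hemispheres"][wanted[0]]
        raise StageError(failed["stage"], wanted[0], RuntimeError(failed["error"]))
    return manifest


def run_evaluation_suite(pred_dir, truth_dir, out_dir=None) -> dict:
    """Evaluate every reconstructed case against its ground-truth twin.

    Cases pair up by file name: ``<case>.white.surf`` (and optionally
    ``<case>.pial.surf``, ``<case>.labels.txt`` + ``<case>.names.tsv``) must
    exist under both directories.  Unpaired cases are listed and skipped.
    Writes one JSON report per case plus ``aggregate.json`` with across-case
    mean and sd of each summary metric.
    """
    from .io_formats import read_labelmap, read_surface
    from .metrics import (
        cortical_thickness,
        dice_per_region,
        surface_displacement,
        triangle_quality,
    )

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    out_dir = Path(out_dir) if out_dir else pred_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    pred_cases = {p.name[: -len(".white.surf")] for p in pred_dir.glob("*.white.surf")}
    truth_cases = {p.name[: -len(".white.surf")] for p in truth_dir.glob("*.white.surf")}
    unpaired = sorted(pred_cases ^ truth_cases)
    for case in unpaired:
        logger.warning("unpaired case skipped: %s", case)

    reports = {}
    for case in sorted(pred_cases & truth_cases):
        pred_white = read_surface(pred_dir / f"{case}.white.surf")
        truth_white = read_surface(truth_dir / f"{case}.white.surf")
        _, q_mean = triangle_quality(pred_white)
        disp = surface_displacement(pred_white, truth_white)
        report = {
            "q_mean": q_mean,
            "displacement_mean": float(disp.mean()),
            "displacement_max": float(disp.max()),
        }
        pred_pial = pred_dir / f"{case}.pial.surf"
        if pred_pial.exists():
            thickness = cortical_thickness(pred_white, read_surface(pred_pial))
            report["thickness_mean"] = float(thickness.mean())
        labels_p = pred_dir / f"{case}.labels.txt"
        labels_t = truth_dir / f"{case}.labels.txt"
        if labels_p.exists() and labels_t.exists():
            lp = read_labelmap(labels_p, pred_dir / f"{case}.names.tsv")
            lt = read_labelmap(labels_t, truth_dir / f"{case}.names.tsv")
            dice = dice_per_region(lp, lt)
            present = [v for v in dice.values() if v is not None]
            report["dice_mean"] = float(np.mean(present)) if present else None
        with open(out_dir / f"{case}.report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        reports[case] = report

    keys = sorted({k for r in reports.values() for k in r if r[k] is not None})
    aggregate = {
        "n_cases": len(reports),
        "unpaired": unpaired,
        "metrics": {
            k: {
                "mean": float(np.mean([r[k] for r in reports.values() if k in r])),
                "sd": float(np.std([r[k] for r in reports.values() if k in r], ddof=1))
                if sum(k in r for r in reports.values()) > 1
                else 0.0,
            }
            for k in keys
        },
    }
    with open(out_dir / "aggregate.json", "w") as fh:
        json.dump(aggregate, fh, indent=2, sort_keys=True)
    return {"cases": reports, "aggregate": aggregate}
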