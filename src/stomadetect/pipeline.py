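"""End-to-end orchestration: simulate → patchify → train → detect →
evaluate → density, fully reproducible from (config, seed)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .calibration import view_field_area_mm2
from .classify import PatchCNNClassifier
from .detection import DEFAULT_TAU_GRID, detect_stomata
from .evaluation import (count_accuracy, fit_counts_regression,
                         match_detections, pr_curve, precision_recall_f)
from .io import (RunConfig, RunLog, save_weights, write_annotations,
                 write_detections)
from .patches import build_training_set
from .synthetic import SynthConfig, generate_dataset

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(log: RunLog, name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.append(name, status="error", error=str(exc))
                raise PipelineError(name, exc) from exc
            return False
    return _Ctx()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the whole synthetic-data pipeline and write all artifacts.

    Returns the evaluation report (also written as JSON to the run
    directory): match counts, the PR curve over the 19-point τ grid,
    per-image count accuracy, the counts regression and densities.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out / "run_log.jsonl")
    log.append("run", config_hash=cfg.config_hash(), seed=cfg.seed,
               config=cfg.to_dict())

    with _stage(log, "simulate"):
        synth = SynthConfig(n_stomata=cfg.n_stomata, seed=cfg.seed,
                            stoma_major_axis_px=cfg.stoma_major_axis_px,
                            image_id="train")
        train_scenes = generate_dataset(cfg.n_train_images, synth,
                                        out_dir=out / "train_images")
        eval_scenes = generate_dataset(
            cfg.n_eval_images,
            dataclasses.replace(synth, seed=cfg.seed + 1, image_id="eval"),
            out_dir=out / "eval_images")
        log.append("simulate", n_train=len(train_scenes),
                   n_eval=len(eval_scenes))

    with _stage(log, "patchify"):
        ds = build_training_set([s.pair for s in train_scenes], cfg.patch,
                                neg_pos_ratio=cfg.neg_pos_ratio, seed=cfg.seed)
        log.append("patchify", **ds.class_counts)

    with _stage(log, "train"):
        clf = PatchCNNClassifier(
            architecture=cfg.architecture, epochs=cfg.epochs,
            batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
            random_state=cfg.seed)
        clf.fit(ds.X, ds.y)
        save_weights(out / "weights.npz", clf)
        (out / "history.json").write_text(json.dumps(clf.history_))
        log.append("train", final_loss=clf.history_["loss"][-1],
                   final_accuracy=clf.history_["accuracy"][-1])

    with _stage(log, "detect"):
        det_sets = [detect_stomata(clf, s.micrograph, cfg.patch, cfg.detection)
                    for s in eval_scenes]
        write_detections(out / "detections.csv", det_sets)
        write_annotations(out / "truth.csv",
                          [a for s in eval_scenes for a in s.annotations])
        log.append("detect", n_detections=sum(map(len, det_sets)))

    with _stage(log, "evaluate"):
        total = None
        for ds_i, scene in zip(det_sets, eval_scenes):
            mr = match_detections(ds_i, scene.annotations, cfg.match_radius_px)
            total = mr if total is None else total + mr
        p, r, f, _ = precision_recall_f(total.tp, total.fp, total.fn)
        curve = pr_curve(clf, eval_scenes, cfg.patch, cfg.detection,
                         DEFAULT_TAU_GRID, cfg.match_radius_px)
        acc = count_accuracy([(len(d), len(s.annotations))
                              for d, s in zip(det_sets, eval_scenes)])
        counts = [(len(d), len(s.annotations))
                  for d, s in zip(det_sets, eval_scenes)]
        try:
            reg = dataclasses.asdict(fit_counts_regression(counts))
        except ValueError:
            reg = None
        log.append("evaluate", tp=total.tp, fp=total.fp, fn=total.fn,
                   f_score=f)

    with _stage(log, "density"):
        area = view_field_area_mm2(cfg.calibration)
        densities = [{
            "image_id": d.image_id,
            "count": len(d),
            "area_mm2": area,
            "density_per_mm2": len(d) / area,
        } for d in det_sets]
        log.append("density", n_images=len(densities))

    report = {
        "config_hash": cfg.config_hash(),
        "match": {"tp": total.tp, "fp": total.fp, "fn": total.fn},
        "precision": p,
        "recall": r,
        "f_score": f,
        "pr_curve": [dataclasses.asdict(pt) for pt in curve],
        "count_accuracy": {"per_image": acc.per_image,
                           "mean_accuracy_pct": acc.mean_accuracy_pct},
        "counts_regression": reg,
        "densities": densities,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
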