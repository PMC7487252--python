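"""Reference experiments validating the pipeline on synthetic scenes.

Three self-contained, seeded experiments:

* :func:`mean_shift_reference_deviation` — compares the package's
  vectorized flat-kernel mean shift against a deliberately naive
  fixed-point reimplementation (plain Python loops) on random instances;
* :func:`oracle_detection_experiment` — runs the full threshold/cluster
  pipeline with a geometric window oracle in place of a trained network,
  where exact recovery of every stoma is provable;
* :func:`end_to_end_experiment` — the desk-scale learning study: train
  the shallow CNN on labeled patches from easy-regime scenes and measure
  detection precision/recall/F on held-out scenes across the 19-point
  threshold grid.

These power both the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .classify import PatchCNNClassifier
from .cluster import mean_shift
from .detection import DetectionConfig, WindowOracle, detect_stomata
from .evaluation import match_detections, pr_curve
from .patches import PatchConfig, build_training_set
from .synthetic import SynthConfig, generate_dataset

__all__ = [
    "naive_mean_shift_modes",
    "mean_shift_reference_deviation",
    "oracle_detection_experiment",
    "end_to_end_experiment",
]


def naive_mean_shift_modes(points, bandwidth, tol=1e-3, max_iter=300):
    """Straightforward fixed-point flat-kernel mean shift, plain loops.

    Kept intentionally naive and separate from :mod:`.cluster` so it can
    serve as an independent reference for the vectorized implementation.
    """
    pts = [(float(x), float(y)) for x, y in points]
    converged = []
    for px, py in pts:
        for _ in range(max_iter):
            sx = sy = cnt = 0
            for qx, qy in pts:
                if (qx - px) ** 2 + (qy - py) ** 2 <= bandwidth ** 2:
                    sx += qx
                    sy += qy
                    cnt += 1
            nx, ny = sx / cnt, sy / cnt
            done = ((nx - px) ** 2 + (ny - py) ** 2) ** 0.5 < tol
            px, py = nx, ny
            if done:
                break
        converged.append((px, py))
    modes: list[tuple[float, float]] = []
    for p in converged:
        if not any((p[0] - m[0]) ** 2 + (p[1] - m[1]) ** 2 < (bandwidth / 2) ** 2
                   for m in modes):
            modes.append(p)
    return modes


def mean_shift_reference_deviation(n_instances: int = 200, seed: int = 0,
                                   bandwidths=(30.0, 60.0, 120.0),
                                   max_points: int = 12) -> dict:
    """Largest mode discrepancy (px) between the vectorized mean shift and
    the naive reference over random instances; also checks mode counts."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    count_mismatches = 0
    for k in range(n_instances):
        bw = float(bandwidths[k % len(bandwidths)])
        n = int(rng.integers(1, max_points + 1))
        pts = rng.uniform(0, 500, size=(n, 2))
        modes, _ = mean_shift(pts, bw)
        ref = naive_mean_shift_modes(pts, bw)
        if len(modes) != len(ref):
            count_mismatches += 1
            continue
        got = sorted(map(tuple, modes))
        exp = sorted(ref)
        for g, e in zip(got, exp):
            worst = max(worst, abs(g[0] - e[0]), abs(g[1] - e[1]))
    return {
        "n_instances": n_instances,
        "mode_count_mismatches": count_mismatches,
        "max_deviation_px": worst,
    }


def oracle_detection_experiment(n_scenes: int = 10, seed: int = 0,
                                stride_px: int = 30) -> dict:
    """Detection with a perfect geometric window scorer on easy scenes.

    In the easy regime (major axis ≤ patch − stride, border margin one
    patch) every stoma owns at least one fully containing window and the
    positive windows of distinct stomata form well-separated clusters, so
    the pipeline must recover exactly one detection per stoma, each within
    half a stride (per axis) of the true center.
    """
    scenes = generate_dataset(n_scenes, SynthConfig.easy(seed=seed,
                                                         image_id="oracle"))
    patch_cfg = PatchConfig(stride_px=stride_px)
    n_truth = n_det = 0
    max_err = 0.0
    tp = fp = fn = 0
    for sc in scenes:
        ds = detect_stomata(WindowOracle(sc.annotations), sc.micrograph,
                            patch_cfg, DetectionConfig())
        mr = match_detections(ds, sc.annotations, radius_px=30.0)
        n_truth += len(sc.annotations)
        n_det += len(ds)
        tp += mr.tp
        fp += mr.fp
        fn += mr.fn
        if mr.pairs:
            max_err = max(max_err, max(p[2] for p in mr.pairs))
    return {
        "n_scenes": n_scenes,
        "n_truth": n_truth,
        "n_detections": n_det,
        "tp": tp, "fp": fp, "fn": fn,
        "max_localization_error_px": max_err,
    }


def end_to_end_experiment(seed: int = 1, n_train_scenes: int = 5,
                          n_eval_scenes: int = 6, epochs: int = 30,
                          verbose: int = 0) -> dict:
    """Desk-scale learning study on easy synthetic scenes.

    Five training scenes of 25 stomata yield roughly 2,000 labeled patches
    at the default 6:1 negative:positive ratio; the shallow architecture
    is trained for ``epochs`` epochs with its published Adam settings and
    evaluated on held-out scenes via the detection pipeline across the
    19-point threshold grid (micro-averaged, 60 px match radius).
    """
    base = SynthConfig.easy(seed=seed, image_id="train")
    train_scenes = generate_dataset(n_train_scenes, base)
    eval_scenes = generate_dataset(
        n_eval_scenes, replace(base, seed=seed + 1, image_id="eval"))
    patch_cfg = PatchConfig()
    ds = build_training_set([s.pair for s in train_scenes], patch_cfg,
                            seed=seed)
    clf = PatchCNNClassifier(architecture="basic_shallow", epochs=epochs,
                             random_state=seed, verbose=verbose)
    clf.fit(ds.X, ds.y)
    curve = pr_curve(clf, eval_scenes, patch_cfg, DetectionConfig())
    at_07 = next(pt for pt in curve if abs(pt.threshold - 0.7) < 1e-9)
    recalls = [pt.recall for pt in curve]
    return {
        "n_patches": len(ds),
        "class_counts": ds.class_counts,
        "final_train_accuracy": clf.history_["accuracy"][-1],
        "curve": curve,
        "precision_at_tau07": at_07.precision,
        "recall_at_tau07": at_07.recall,
        "f_score_at_tau07": at_07.f_score,
        "recall_monotone_violations": sum(
            1 for a, b in zip(recalls, recalls[1:]) if b > a + 1e-12),
    }
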