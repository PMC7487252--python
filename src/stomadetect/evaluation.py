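"""Information-retrieval evaluation of stoma detections.

Detections are matched one-to-one to ground-truth annotations within a
spatial radius (greedy nearest-pair by default, optimal assignment behind
a flag); the resulting TP/FP/FN feed precision = TP/(TP+FP), recall =
TP/(TP+FN) and their harmonic mean, the F-score.  Threshold sweeps over
the canonical 19-point τ grid produce precision–recall curves with
F iso-lines; stomatal count agreement is summarized per image as
100·(1 − |computed − manual| / manual) and by an OLS regression of
computed on manual counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .calibration import StomaAnnotation
from .detection import (DEFAULT_TAU_GRID, DetectionConfig, DetectionSet,
                        detections_from_scores, score_image)
from .patches import PatchConfig

__all__ = [
    "MatchResult",
    "PRPoint",
    "CountAccuracy",
    "RegressionSummary",
    "match_detections",
    "precision_recall_f",
    "pr_curve",
    "f_iso_levels",
    "count_accuracy",
    "fit_counts_regression",
]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn)


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float
    f_score: float
    degenerate: bool = False


@dataclass
class CountAccuracy:
    per_image: list[tuple[int, int, float]]   # (computed, manual, accuracy %)
    mean_accuracy_pct: float


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    n: int
    p_value: float = float("nan")


def match_detections(dets: DetectionSet | np.ndarray,
                     truth: Sequence[StomaAnnotation] | np.ndarray,
                     radius_px: float = 60.0,
                     method: str = "greedy") -> MatchResult:
    """One-to-one detection/ground-truth matching within ``radius_px``.

    ``method="greedy"`` pairs by ascending distance (transparent, default);
    ``method="hungarian"`` minimizes total distance over all one-to-one
    assignments within the radius.  Unmatched detections are false
    positives, unmatched truths false negatives.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be non-negative")
    d_xy = (dets.coordinates() if isinstance(dets, DetectionSet)
            else np.asarray(dets, dtype=float).reshape(-1, 2))
    if isinstance(truth, np.ndarray):
        t_xy = np.asarray(truth, dtype=float).reshape(-1, 2)
    else:
        truth = list(truth)
        t_xy = (np.array([(a.x_px, a.y_px) for a in truth]).reshape(-1, 2)
                if truth and isinstance(truth[0], StomaAnnotation)
                else np.asarray(truth, dtype=float).reshape(-1, 2))
    nd, nt = len(d_xy), len(t_xy)
    if nd == 0 or nt == 0:
        return MatchResult(0, nd, nt, [])
    dist = np.sqrt(((d_xy[:, None, :] - t_xy[None, :, :]) ** 2).sum(axis=2))

    pairs: list[tuple[int, int, float]] = []
    if method == "greedy":
        cand = [(dist[i, j], i, j) for i in range(nd) for j in range(nt)
                if dist[i, j] <= radius_px]
        cand.sort()
        used_d: set[int] = set()
        used_t: set[int] = set()
        for d, i, j in cand:
            if i not in used_d and j not in used_t:
                pairs.append((i, j, float(d)))
                used_d.add(i)
                used_t.add(j)
    elif method == "hungarian":
        big = radius_px * max(nd, nt) * 10 + 1
        cost = np.where(dist <= radius_px, dist, big)
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if dist[i, j] <= radius_px:
                pairs.append((int(i), int(j), float(dist[i, j])))
    else:
        raise ValueError(f"unknown matching method {method!r}")
    tp = len(pairs)
    return MatchResult(tp, nd - tp, nt - tp, pairs)


def precision_recall_f(tp: int, fp: int, fn: int
                       ) -> tuple[float, float, float, bool]:
    """(precision, recall, F, degenerate) from a confusion count.

    Zero denominators (no detections, no truths, or P + R = 0) yield 0
    for the affected quantity with ``degenerate=True``.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    if tp + fp > 0:
        p = tp / (tp + fp)
    else:
        p, degenerate = 0.0, True
    if tp + fn > 0:
        r = tp / (tp + fn)
    else:
        r, degenerate = 0.0, True
    if p + r > 0:
        f = 2 * p * r / (p + r)
    else:
        f, degenerate = 0.0, True
    return p, r, f, degenerate


def f_iso_levels() -> tuple[float, ...]:
    """Reference F values for iso-curves on a precision–recall plot."""
    return tuple(np.round(np.arange(1, 10) * 0.1, 1))


def pr_curve(clf, scenes, patch_cfg: PatchConfig = PatchConfig(),
             det_cfg: DetectionConfig = DetectionConfig(),
             tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
             radius_px: float = 60.0,
             average: str = "micro") -> list[PRPoint]:
    """Precision/recall/F per decision threshold over annotated scenes.

    One score map is computed per scene and re-thresholded across the
    grid.  ``average="micro"`` pools TP/FP/FN over all scenes (default);
    ``"macro"`` averages per-scene P/R/F.
    """
    scenes = [s.pair if hasattr(s, "pair") else s for s in scenes]
    if not scenes:
        raise ValueError("at least one annotated scene is required")
    smaps = [(score_image(clf, m, patch_cfg), anns) for m, anns in scenes]
    out = []
    for tau in tau_grid:
        cfg = DetectionConfig(threshold=tau, bandwidth_px=det_cfg.bandwidth_px,
                              min_cluster_size=det_cfg.min_cluster_size)
        if average == "micro":
            total = MatchResult(0, 0, 0)
            for smap, anns in smaps:
                total = total + match_detections(
                    detections_from_scores(smap, cfg), anns, radius_px)
            p, r, f, deg = precision_recall_f(total.tp, total.fp, total.fn)
        elif average == "macro":
            prf = [precision_recall_f(*(lambda mr: (mr.tp, mr.fp, mr.fn))(
                match_detections(detections_from_scores(smap, cfg), anns,
                                 radius_px)))
                   for smap, anns in smaps]
            p = float(np.mean([x[0] for x in prf]))
            r = float(np.mean([x[1] for x in prf]))
            f = float(np.mean([x[2] for x in prf]))
            deg = any(x[3] for x in prf)
        else:
            raise ValueError(f"unknown averaging mode {average!r}")
        out.append(PRPoint(float(tau), p, r, f, deg))
    return out


def count_accuracy(pairs: Sequence[tuple[int, int]]) -> CountAccuracy:
    """Per-image count agreement, 100·(1 − |computed − manual| / manual).

    A 36% deviation of the computed from the manual count — over- or
    under-counting alike — gives 64% accuracy.  Negative values are
    floored at 0; images with a zero manual count are skipped with a
    warning.
    """
    rows = []
    for computed, manual in pairs:
        if manual <= 0:
            warnings.warn("skipping image with zero manual count",
                          stacklevel=2)
            continue
        acc = max(0.0, 100.0 * (1.0 - abs(computed - manual) / manual))
        rows.append((int(computed), int(manual), acc))
    mean = float(np.mean([a for _, _, a in rows])) if rows else float("nan")
    return CountAccuracy(rows, mean)


def fit_counts_regression(pairs: Sequence[tuple[float, float]]
                          ) -> RegressionSummary:
    """OLS of computed counts on manual counts, with R² = 1 − SSres/SStot."""
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if len(arr) < 3:
        raise ValueError("at least 3 images are required for the regression")
    manual = arr[:, 1]
    computed = arr[:, 0]
    if np.allclose(manual, manual[0]):
        raise ValueError("manual counts have zero variance")
    res = stats.linregress(manual, computed)
    # constant computed counts: no variance explained, R^2 = 0 by definition
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0
    return RegressionSummary(float(res.slope), float(res.intercept),
                             r2, len(arr), float(res.pvalue))
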