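"""From trained patch classifier to stoma coordinates.

The pipeline scores every sliding window of a micrograph, keeps the
window centers whose presence confidence reaches the decision threshold
τ (default 0.7, the published precision/recall trade-off), clusters the
surviving centers by mean shift, and reports one detection per mode:
the mode coordinate, the maximum member confidence, and the cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import Micrograph, StomaAnnotation
from .cluster import mean_shift
from .patches import PatchConfig, label_window, window_grid

__all__ = [
    "ScoreMap",
    "DetectionConfig",
    "Detection",
    "DetectionSet",
    "WindowOracle",
    "StomataDetector",
    "score_image",
    "detect_stomata",
    "detection_counts_vs_threshold",
    "DEFAULT_TAU_GRID",
]

#: the canonical 19-point decision-threshold grid, 0.05 … 0.95 in steps of 0.05
DEFAULT_TAU_GRID = tuple(np.round(np.arange(1, 20) * 0.05, 2))


@dataclass(frozen=True)
class DetectionConfig:
    """Decision threshold and clustering geometry."""

    threshold: float = 0.7
    bandwidth_px: float = 60.0
    min_cluster_size: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.bandwidth_px <= 0:
            raise ValueError("bandwidth_px must be strictly positive")


@dataclass
class ScoreMap:
    """Presence confidence of every sliding window of one image."""

    image_id: str
    x_centers: np.ndarray          # (n_windows,)
    y_centers: np.ndarray
    confidences: np.ndarray        # in [0, 1]
    patch_config: PatchConfig

    def __post_init__(self) -> None:
        c = np.asarray(self.confidences, dtype=float)
        if c.size and (c.min() < 0 or c.max() > 1):
            raise ValueError("confidences must lie in [0, 1]")
        self.confidences = c

    def __len__(self) -> int:
        return len(self.confidences)


@dataclass(frozen=True)
class Detection:
    x_px: float
    y_px: float
    confidence: float
    cluster_size: int


@dataclass
class DetectionSet:
    image_id: str
    detections: list[Detection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)

    def coordinates(self) -> np.ndarray:
        return np.array([(d.x_px, d.y_px) for d in self.detections]
                        ).reshape(-1, 2)

    @property
    def count(self) -> int:
        return len(self.detections)


class WindowOracle:
    """Geometry-based reference scorer: 1.0 iff a window fully contains a
    stoma of the given ground truth, else 0.0.

    Used to validate the thresholding/clustering stages independently of
    any trained network.
    """

    def __init__(self, annotations: Sequence[StomaAnnotation]):
        self._by_image: dict[str, list[StomaAnnotation]] = {}
        for a in annotations:
            self._by_image.setdefault(a.image_id, []).append(a)

    def score_window(self, image_id: str, x0: float, y0: float,
                     size: float) -> float:
        anns = self._by_image.get(image_id, [])
        return 1.0 if label_window(x0, y0, size, anns) == "positive" else 0.0


def score_image(clf, m: Micrograph,
                patch_cfg: PatchConfig = PatchConfig()) -> ScoreMap:
    """Score every sliding window; deterministic given the weights.

    ``clf`` is either a fitted patch classifier (``predict_proba`` over
    pixel patches) or any object exposing a geometric
    ``score_window(image_id, x0, y0, size)`` method such as
    :class:`WindowOracle`.
    """
    xs, ys = window_grid(m.width, m.height, patch_cfg)
    P = patch_cfg.patch_size_px
    gx, gy = np.meshgrid(xs, ys)            # row-major: y outer, x inner
    x0s, y0s = gx.ravel(), gy.ravel()

    if hasattr(clf, "score_window"):
        conf = np.array([clf.score_window(m.image_id, x0, y0, P)
                         for x0, y0 in zip(x0s, y0s)])
    else:
        gray = m.gray()
        conf = np.empty(len(x0s))
        batch = 256
        for s in range(0, len(x0s), batch):
            block = np.stack([gray[y0:y0 + P, x0:x0 + P]
                              for x0, y0 in zip(x0s[s:s + batch],
                                                y0s[s:s + batch])])
            conf[s:s + batch] = clf.predict_proba(block)[:, 1]
    half = (P - 1) / 2.0
    return ScoreMap(m.image_id, x0s + half, y0s + half, conf, patch_cfg)


def detections_from_scores(smap: ScoreMap,
                           det_cfg: DetectionConfig) -> DetectionSet:
    """Threshold, cluster, and reduce a score map to detections."""
    keep = smap.confidences >= det_cfg.threshold
    if not keep.any():
        return DetectionSet(smap.image_id, [])
    pts = np.column_stack([smap.x_centers[keep], smap.y_centers[keep]])
    confs = smap.confidences[keep]
    modes, labels = mean_shift(pts, det_cfg.bandwidth_px)
    dets = []
    for j, mode in enumerate(modes):
        member = labels == j
        size = int(member.sum())
        if size < det_cfg.min_cluster_size:
            continue
        dets.append(Detection(float(mode[0]), float(mode[1]),
                              float(confs[member].max()), size))
    return DetectionSet(smap.image_id, dets)


def detect_stomata(clf, m: Micrograph,
                   patch_cfg: PatchConfig = PatchConfig(),
                   det_cfg: DetectionConfig = DetectionConfig()) -> DetectionSet:
    """Full detection pass: score, threshold at τ, mean-shift, reduce."""
    return detections_from_scores(score_image(clf, m, patch_cfg), det_cfg)


def detection_counts_vs_threshold(clf, m: Micrograph,
                                  patch_cfg: PatchConfig = PatchConfig(),
                                  tau_list: Sequence[float] = DEFAULT_TAU_GRID,
                                  det_cfg: DetectionConfig = DetectionConfig(),
                                  ) -> list[tuple[float, int]]:
    """Detection count per threshold, reusing one score map."""
    taus = list(tau_list)
    if any(b < a for a, b in zip(taus, taus[1:])):
        raise ValueError("tau_list must be ascending")
    smap = score_image(clf, m, patch_cfg)
    out = []
    for tau in taus:
        cfg = DetectionConfig(threshold=tau, bandwidth_px=det_cfg.bandwidth_px,
                              min_cluster_size=det_cfg.min_cluster_size)
        out.append((tau, len(detections_from_scores(smap, cfg))))
    return out


class StomataDetector:
    """Convenience bundle of a fitted patch classifier and the detection
    configuration; ``predict`` maps a micrograph to a DetectionSet."""

    def __init__(self, classifier,
                 patch_config: PatchConfig = PatchConfig(),
                 detection_config: DetectionConfig = DetectionConfig()):
        self.classifier = classifier
        self.patch_config = patch_config
        self.detection_config = detection_config

    def score(self, m: Micrograph) -> ScoreMap:
        return score_image(self.classifier, m, self.patch_config)

    def predict(self, m: Micrograph) -> DetectionSet:
        return detect_stomata(self.classifier, m,
                              self.patch_config, self.detection_config)

    def count(self, m: Micrograph) -> int:
        return len(self.predict(m))
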