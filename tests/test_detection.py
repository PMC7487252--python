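import numpy as np
import pytest

from stomadetect.detection import (DEFAULT_TAU_GRID, DetectionConfig,
                                   StomataDetector, WindowOracle,
                                   detect_stomata,
                                   detection_counts_vs_threshold,
                                   detections_from_scores, score_image)
from stomadetect.evaluation import match_detections
from stomadetect.patches import PatchConfig, extract_patches


class _ConstantClassifier:
    def __init__(self, value):
        self.value = value

    def predict_proba(self, X):
        n = len(X)
        return np.column_stack([np.full(n, 1 - self.value),
                                np.full(n, self.value)])


class TestScoreImage:
    def test_constant_propagation(self, small_scene):
        smap = score_image(_ConstantClassifier(0.5), small_scene.micrograph,
                           PatchConfig(120, 60))
        assert np.allclose(smap.confidences, 0.5)

    def test_entry_count_matches_extract(self, small_scene):
        cfg = PatchConfig(120, 40)
        smap = score_image(_ConstantClassifier(0.2), small_scene.micrograph, cfg)
        assert len(smap) == len(extract_patches(small_scene.micrograph, cfg))

    def test_full_frame_window_count(self, full_scene):
        smap = score_image(WindowOracle(full_scene.annotations),
                           full_scene.micrograph, PatchConfig(120, 40))
        assert len(smap) == 1064  # 38 x 28 windows on 1600x1200

    def test_oracle_scores_are_binary(self, small_scene):
        smap = score_image(WindowOracle(small_scene.annotations),
                           small_scene.micrograph, PatchConfig(120, 30))
        assert set(np.unique(smap.confidences)) <= {0.0, 1.0}
        assert smap.confidences.max() == 1.0


class TestDetect:
    def test_no_window_above_threshold(self, small_scene):
        ds = detect_stomata(_ConstantClassifier(0.1), small_scene.micrograph,
                            PatchConfig(120, 60), DetectionConfig(0.7))
        assert len(ds) == 0

    def test_single_hot_window(self):
        from stomadetect.detection import ScoreMap
        n = 25
        conf = np.full(n, 0.1)
        conf[12] = 0.9
        xs = np.tile(np.arange(5) * 100.0 + 60, 5)
        ys = np.repeat(np.arange(5) * 100.0 + 60, 5)
        smap = ScoreMap("img", xs, ys, conf, PatchConfig(120, 100))
        ds = detections_from_scores(smap, DetectionConfig(0.7))
        assert len(ds) == 1
        d = ds.detections[0]
        assert (d.x_px, d.y_px) == (xs[12], ys[12])
        assert d.confidence == pytest.approx(0.9)
        assert d.cluster_size == 1

    def test_oracle_recovers_every_stoma(self, small_scene):
        ds = detect_stomata(WindowOracle(small_scene.annotations),
                            small_scene.micrograph, PatchConfig(120, 30))
        mr = match_detections(ds, small_scene.annotations, radius_px=30)
        assert mr.fp == 0 and mr.fn == 0
        assert len(ds) == len(small_scene.annotations)

    def test_deterministic(self, small_scene):
        a = detect_stomata(WindowOracle(small_scene.annotations),
                           small_scene.micrograph, PatchConfig(120, 30))
        b = detect_stomata(WindowOracle(small_scene.annotations),
                           small_scene.micrograph, PatchConfig(120, 30))
        assert a.coordinates().tolist() == b.coordinates().tolist()

    def test_detector_wrapper(self, small_scene):
        det = StomataDetector(WindowOracle(small_scene.annotations))
        assert det.count(small_scene.micrograph) == len(small_scene.annotations)


class TestThresholdSweep:
    def test_19_point_grid(self):
        assert len(DEFAULT_TAU_GRID) == 19
        assert DEFAULT_TAU_GRID[0] == 0.05 and DEFAULT_TAU_GRID[-1] == 0.95

    def test_counts_non_increasing(self, small_scene):
        rows = detection_counts_vs_threshold(
            WindowOracle(small_scene.annotations), small_scene.micrograph,
            PatchConfig(120, 30), DEFAULT_TAU_GRID)
        assert len(rows) == 19
        counts = [n for _, n in rows]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_descending_grid_rejected(self, small_scene):
        with pytest.raises(ValueError, match="ascending"):
            detection_counts_vs_threshold(
                WindowOracle(small_scene.annotations), small_scene.micrograph,
                PatchConfig(120, 30), [0.9, 0.5])

    def test_surviving_set_shrinks_with_threshold(self, small_scene):
        smap = score_image(WindowOracle(small_scene.annotations),
                           small_scene.micrograph, PatchConfig(120, 30))
        lo = set(np.flatnonzero(smap.confidences >= 0.05))
        hi = set(np.flatnonzero(smap.confidences >= 0.95))
        assert hi <= lo
        n_lo = len(detections_from_scores(smap, DetectionConfig(0.05)))
        n_hi = len(detections_from_scores(smap, DetectionConfig(0.95)))
        assert n_hi <= n_lo


class TestDetectionConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            DetectionConfig(threshold=0.0)
        with pytest.raises(ValueError):
            DetectionConfig(bandwidth_px=-1.0)
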