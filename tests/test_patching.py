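import numpy as np
import pytest

from stomadetect.calibration import Micrograph, StomaAnnotation
from stomadetect.patches import (NEGATIVE, POSITIVE, Patch, PatchConfig,
                                 augment, build_training_set,
                                 dihedral_transform, extract_patches,
                                 label_patch, label_window, window_grid)


def _blank(w, h, image_id="img"):
    return Micrograph(image_id, np.zeros((h, w), dtype=np.uint8))


class TestExtractPatches:
    def test_grid_count_full_frame(self):
        m = _blank(1600, 1200)
        patches = extract_patches(m, PatchConfig(120, 40))
        assert len(patches) == 38 * 28  # (floor(1480/40)+1) x (floor(1080/40)+1)

    def test_single_window(self):
        m = _blank(120, 120)
        patches = extract_patches(m, PatchConfig(120, 30))
        assert len(patches) == 1 and (patches[0].x0, patches[0].y0) == (0, 0)

    def test_too_small_image_errors(self):
        with pytest.raises(ValueError, match="smaller than patch"):
            extract_patches(_blank(119, 119), PatchConfig(120, 30))

    def test_row_major_order_and_bounds(self):
        m = _blank(200, 160)
        patches = extract_patches(m, PatchConfig(120, 40))
        corners = [(p.x0, p.y0) for p in patches]
        assert corners == [(0, 0), (40, 0), (80, 0), (0, 40), (40, 40), (80, 40)]
        assert all(p.x0 + p.size <= 200 and p.y0 + p.size <= 160
                   for p in patches)

    def test_flush_window_covers_every_pixel(self):
        cfg = PatchConfig(120, 50, flush=True)
        xs, ys = window_grid(1600, 1200, cfg)
        assert xs[-1] == 1600 - 120 and ys[-1] == 1200 - 120
        covered_x = np.zeros(1600, bool)
        for x0 in xs:
            covered_x[x0:x0 + 120] = True
        assert covered_x.all()

    def test_invalid_stride(self):
        with pytest.raises(ValueError):
            PatchConfig(120, 0)
        with pytest.raises(ValueError):
            PatchConfig(120, 121)


class TestLabelPatch:
    def _patch(self, x0=0, y0=0, size=120):
        return Patch("img", x0, y0, size, np.zeros((size, size), np.float32))

    def test_fully_contained_is_positive(self):
        ann = StomaAnnotation("img", 60.0, 60.0, 80.0)
        assert label_patch(self._patch(), [ann]) == POSITIVE

    def test_clipped_is_negative(self):
        ann = StomaAnnotation("img", 10.0, 60.0, 80.0)  # crosses left edge
        assert label_patch(self._patch(), [ann]) == NEGATIVE

    def test_no_annotations_negative(self):
        assert label_patch(self._patch(), []) == NEGATIVE

    def test_boundary_touching_counts_as_contained(self):
        ann = StomaAnnotation("img", 60.0, 60.0, 120.0)  # exactly fills patch
        assert label_patch(self._patch(), [ann]) == POSITIVE

    def test_tiling_positive_count_matches_geometry(self, small_scene):
        """At stride == patch size (disjoint tiling), the number of positive
        tiles equals a brute-force count of stomata falling entirely inside
        exactly one tile."""
        m, anns = small_scene.pair
        cfg = PatchConfig(120, 120)
        patches = extract_patches(m, cfg)
        n_pos = sum(label_patch(p, anns) == POSITIVE for p in patches)
        # brute force: each stoma is inside at most one disjoint tile
        count = 0
        xs, ys = window_grid(m.width, m.height, cfg)
        for a in anns:
            h = a.length_px / 2
            hits = [(x0, y0) for x0 in xs for y0 in ys
                    if a.x_px - h >= x0 and a.x_px + h <= x0 + 120
                    and a.y_px - h >= y0 and a.y_px + h <= y0 + 120]
            assert len(hits) <= 1
            count += len(hits)
        # tiles with >= 2 stomata cannot occur at min_separation 140
        assert n_pos <= count
        assert n_pos == len({(p.x0, p.y0) for p in patches
                             if label_patch(p, anns) == POSITIVE})


class TestBuildTrainingSet:
    def test_ratio_and_cap(self, small_scene):
        ds = build_training_set([small_scene.pair], PatchConfig(120, 30),
                                neg_pos_ratio=2.0, seed=0)
        c = ds.class_counts
        assert c[POSITIVE] > 0
        assert c[NEGATIVE] == 2 * c[POSITIVE]
        huge = build_training_set([small_scene.pair], PatchConfig(120, 30),
                                  neg_pos_ratio=1e6, seed=0)
        assert huge.class_counts[NEGATIVE] < 1e6 * huge.class_counts[POSITIVE]

    def test_zero_positives_errors(self):
        m = _blank(240, 240)
        with pytest.raises(ValueError, match="positive"):
            build_training_set([(m, [])], PatchConfig(120, 60))

    def test_deterministic_subsample(self, small_scene):
        a = build_training_set([small_scene.pair], PatchConfig(120, 30), seed=9)
        b = build_training_set([small_scene.pair], PatchConfig(120, 30), seed=9)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)


class TestAugment:
    def _patch(self, pixels):
        s = pixels.shape[0]
        return Patch("img", 0, 0, s, pixels)

    def test_identity_element(self, marker_patch):
        out = dihedral_transform(marker_patch, 0, False, False)
        assert np.array_equal(out, marker_patch)

    def test_hflip_involution(self, marker_patch):
        once = dihedral_transform(marker_patch, 0, True, False)
        twice = dihedral_transform(once, 0, True, False)
        assert np.array_equal(twice, marker_patch)

    def test_dihedral_orbit_distinct(self, marker_patch):
        """All 8 square symmetries of an asymmetric marker are distinct."""
        outs = set()
        for k in range(4):
            for fh in (False, True):
                outs.add(dihedral_transform(marker_patch, k, fh, False).tobytes())
        assert len(outs) == 8

    def test_preserves_histogram_and_size(self, marker_patch):
        p = self._patch(marker_patch)
        out = augment(p, seed=3)
        assert out.pixels.shape == p.pixels.shape
        assert sorted(out.pixels.ravel()) == sorted(p.pixels.ravel())

    def test_nonsquare_rejected(self):
        bad = Patch.__new__(Patch)  # bypass size check to get a non-square
        object.__setattr__(bad, "image_id", "x")
        object.__setattr__(bad, "x0", 0)
        object.__setattr__(bad, "y0", 0)
        object.__setattr__(bad, "size", 4)
        object.__setattr__(bad, "pixels", np.zeros((4, 6), np.float32))
        with pytest.raises(ValueError, match="square"):
            augment(bad, seed=0)
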