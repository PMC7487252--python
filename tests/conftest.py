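"""Shared fixtures: small synthetic scenes and patch sets.

Everything is generated programmatically with fixed seeds; no image data
is stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from stomadetect.patches import PatchConfig, build_training_set
from stomadetect.synthetic import SynthConfig, generate_micrograph


@pytest.fixture(scope="session")
def small_scene():
    """One 620x460 easy-regime scene with 4 stomata (fast to render)."""
    cfg = SynthConfig.easy(width_px=620, height_px=460, n_stomata=4,
                           artifact_rate=1.0, seed=11, image_id="small")
    return generate_micrograph(cfg)


@pytest.fixture(scope="session")
def full_scene():
    """One full-size 1600x1200 scene at the default study conditions."""
    return generate_micrograph(SynthConfig(seed=7, image_id="full"))


@pytest.fixture(scope="session")
def tiny_patchset():
    """~200 labeled 120-px patches from three small easy scenes."""
    scenes = [
        generate_micrograph(
            SynthConfig.easy(width_px=620, height_px=460, n_stomata=4,
                             artifact_rate=1.0, seed=100 + i,
                             image_id=f"tiny_{i}"))
        for i in range(3)
    ]
    ds = build_training_set([s.pair for s in scenes],
                            PatchConfig(stride_px=50), neg_pos_ratio=6.0,
                            seed=5)
    return ds


@pytest.fixture(scope="session")
def marker_patch():
    """A 3x3 asymmetric marker, distinct under all 8 square symmetries."""
    return np.arange(9, dtype=np.float32).reshape(3, 3) / 10.0
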