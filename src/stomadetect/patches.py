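"""Sliding-window patch extraction, labeling and training-set assembly.

Detection is cast as binary classification of fixed-size windows: a
micrograph is divided into overlapping 120 x 120 px patches by a sliding
window, and each patch is labeled *positive* only when a stoma is fully
visible inside it — a stoma clipped by the window border counts as
negative.  Because annotations carry no orientation, containment is judged
on the axis-aligned square of side ``length_px`` centered on the annotated
stoma center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .calibration import Micrograph, StomaAnnotation

__all__ = [
    "PatchConfig",
    "Patch",
    "LabeledPatch",
    "PatchDataset",
    "window_grid",
    "extract_patches",
    "label_patch",
    "label_window",
    "build_training_set",
    "augment",
    "dihedral_transform",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class PatchConfig:
    """Sliding-window geometry.

    ``stride_px`` defaults to a quarter patch (30 px), which keeps window
    centers dense enough that every fully visible stoma of 60–120 px is
    covered by several windows.  ``flush`` adds a final window pressed
    against the right/bottom border when the image size minus the patch
    size is not a multiple of the stride, so that every pixel is covered.
    """

    patch_size_px: int = 120
    stride_px: int = 30
    flush: bool = False

    def __post_init__(self) -> None:
        if self.patch_size_px < 1:
            raise ValueError("patch_size_px must be >= 1")
        if not (1 <= self.stride_px <= self.patch_size_px):
            raise ValueError("stride_px must satisfy 1 <= stride <= patch size")


@dataclass(frozen=True)
class Patch:
    image_id: str
    x0: int
    y0: int
    size: int
    pixels: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != (self.size, self.size):
            raise ValueError("pixel block does not match declared size")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x0 + (self.size - 1) / 2.0, self.y0 + (self.size - 1) / 2.0)


@dataclass(frozen=True)
class LabeledPatch:
    patch: Patch
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown label {self.label!r}")


def _axis_offsets(dim: int, size: int, stride: int, flush: bool) -> list[int]:
    if dim < size:
        raise ValueError(f"image dimension {dim} smaller than patch size {size}")
    offs = list(range(0, dim - size + 1, stride))
    if flush and offs[-1] != dim - size:
        offs.append(dim - size)
    return offs


def window_grid(width: int, height: int, cfg: PatchConfig) -> tuple[np.ndarray, np.ndarray]:
    """Top-left corners of all sliding windows, as (xs, ys) offset vectors."""
    xs = np.array(_axis_offsets(width, cfg.patch_size_px, cfg.stride_px, cfg.flush))
    ys = np.array(_axis_offsets(height, cfg.patch_size_px, cfg.stride_px, cfg.flush))
    return xs, ys


def extract_patches(m: Micrograph, cfg: PatchConfig = PatchConfig()) -> list[Patch]:
    """Cut the image into overlapping square windows, row-major order."""
    xs, ys = window_grid(m.width, m.height, cfg)
    P = cfg.patch_size_px
    out = []
    for y0 in ys:
        for x0 in xs:
            out.append(Patch(m.image_id, int(x0), int(y0), P,
                             m.pixels[y0:y0 + P, x0:x0 + P]))
    return out


def label_window(x0: float, y0: float, size: float,
                 anns: Iterable[StomaAnnotation]) -> str:
    """Label a window by pure geometry, without touching pixels.

    Positive iff at least one stoma is fully contained: the axis-aligned
    square of side ``length_px`` centered at the annotation lies inside
    the window.
    """
    for a in anns:
        h = a.length_px / 2.0
        if (a.x_px - h >= x0 and a.x_px + h <= x0 + size
                and a.y_px - h >= y0 and a.y_px + h <= y0 + size):
            return POSITIVE
    return NEGATIVE


def label_patch(p: Patch, anns: Iterable[StomaAnnotation]) -> str:
    """Positive iff some annotated stoma is fully visible inside the patch."""
    return label_window(p.x0, p.y0, p.size, anns)


@dataclass
class PatchDataset:
    """Labeled patches ready for classifier training.

    ``X`` stacks the grayscale pixel blocks as ``(n, P, P)`` float32 in
    [0, 1]; ``y`` is 1 for positive, 0 for negative.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: dict

    @property
    def class_counts(self) -> dict[str, int]:
        n_pos = int(self.y.sum())
        return {POSITIVE: n_pos, NEGATIVE: int(len(self.y) - n_pos)}

    @property
    def neg_pos_ratio(self) -> float:
        c = self.class_counts
        return c[NEGATIVE] / c[POSITIVE] if c[POSITIVE] else float("inf")

    def __len__(self) -> int:
        return len(self.y)


def build_training_set(
    scenes: Sequence[tuple[Micrograph, Sequence[StomaAnnotation]]],
    cfg: PatchConfig = PatchConfig(),
    neg_pos_ratio: float = 6.0,
    seed: int = 0,
) -> PatchDataset:
    """Assemble a labeled patch set from annotated micrographs.

    All positive windows are kept; negatives are subsampled uniformly
    (seeded) down to ``neg_pos_ratio`` times the positive count, mirroring
    the roughly 6:1 negative:positive imbalance used when training on
    expert-labeled herbarium patches (more negatives are retained because
    background, artifacts and clipped stomata are the more variable class).
    """
    scenes = list(scenes)
    pos: list[tuple[int, int, int]] = []  # (scene idx, x0, y0)
    neg: list[tuple[int, int, int]] = []
    for si, (m, anns) in enumerate(scenes):
        xs, ys = window_grid(m.width, m.height, cfg)
        for y0 in ys:
            for x0 in xs:
                lab = label_window(x0, y0, cfg.patch_size_px, anns)
                (pos if lab == POSITIVE else neg).append((si, int(x0), int(y0)))
    if not pos:
        raise ValueError(
            "no positive patches found; annotate more stomata "
            "(several hundred stomata are recommended for training)"
        )
    rng = np.random.default_rng(seed)
    n_neg = min(len(neg), int(round(neg_pos_ratio * len(pos))))
    keep = rng.choice(len(neg), size=n_neg, replace=False)
    chosen = pos + [neg[i] for i in sorted(keep)]

    P = cfg.patch_size_px
    X = np.empty((len(chosen), P, P), dtype=np.float32)
    grays = [m.gray() for m, _ in scenes]
    for i, (si, x0, y0) in enumerate(chosen):
        X[i] = grays[si][y0:y0 + P, x0:x0 + P]
    y = np.zeros(len(chosen), dtype=np.int64)
    y[: len(pos)] = 1
    return PatchDataset(
        X, y,
        provenance={
            "image_ids": [m.image_id for m, _ in scenes],
            "patch_size_px": P,
            "stride_px": cfg.stride_px,
            "neg_pos_ratio_requested": neg_pos_ratio,
            "seed": seed,
        },
    )


def dihedral_transform(pixels: np.ndarray, k_rot: int,
                       flip_h: bool, flip_v: bool) -> np.ndarray:
    """Apply one of the 8 square symmetries: k 90° rotations then flips."""
    out = np.rot90(pixels, k_rot % 4, axes=(0, 1))
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment(p: Patch, seed: int) -> Patch:
    """Seeded random 90°-multiple rotation plus independent h/v flips.

    Restricted to the dihedral group of the square so that no interpolation
    touches the intensities; label-preserving by construction.
    """
    if p.pixels.shape[0] != p.pixels.shape[1]:
        raise ValueError("augment requires a square patch")
    rng = np.random.default_rng(seed)
    k = int(rng.integers(4))
    fh, fv = bool(rng.integers(2)), bool(rng.integers(2))
    return Patch(p.image_id, p.x0, p.y0, p.size,
                 dihedral_transform(p.pixels, k, fh, fv))
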