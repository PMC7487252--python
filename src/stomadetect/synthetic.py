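"""Seeded generator of synthetic leaf-impression micrographs.

Real inputs to the detection pipeline are focus-stacked brightfield images
of nail-polish epidermal casts: a pale, mottled epidermis with darker
elliptical stomata (a dark pore slit flanked by a lighter guard-cell rim)
at random orientations, contaminated by artifacts such as hairs, air
bubbles and smudges.  This module emulates those images with exact,
by-construction ground truth, so every downstream stage — patch labeling,
training, clustering, evaluation — is testable offline without any
microscope data.

The appearance model is deliberately simple (smooth intensity profiles on
an oriented ellipse); it captures the geometry and contrast cues a patch
classifier exploits, not the histology of a particular species.  All
randomness flows from ``numpy.random.default_rng`` (PCG64), so a fixed
seed reproduces every image and annotation byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .calibration import Calibration, Micrograph, StomaAnnotation

__all__ = ["SynthConfig", "SynthScene", "PackingError",
           "generate_micrograph", "generate_dataset"]

#: µm per pixel implied by a 344 x 258 µm field at 1,600 x 1,200 px
_DEFAULT_UM_PER_PX = 0.215


class PackingError(RuntimeError):
    """Requested stomata cannot be placed at the required separation."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic micrograph.

    Defaults mirror the acquisition geometry of the real data (1,600 x
    1,200 px, stomata with major axes of 60–120 px so each fits a 120-px
    patch) and a separation of 140 px, which guarantees that any 120-px
    window contains at most one complete stoma.  Intensity contrasts are
    exposed so harder (low-contrast, noisy) regimes can be generated.
    """

    width_px: int = 1600
    height_px: int = 1200
    n_stomata: int | tuple[int, int] = 25
    stoma_major_axis_px: tuple[float, float] = (60.0, 120.0)
    aspect_ratio: tuple[float, float] = (0.4, 0.8)
    min_separation_px: float = 140.0
    artifact_rate: float = 3.0
    noise_level: float = 0.03
    blur_sigma_px: float = 1.0
    pore_depth: float = 0.38
    rim_height: float = 0.14
    background_level: float = 0.62
    border_margin_px: float | None = None
    seed: int = 0
    image_id: str = "synthetic"
    um_per_px: float = _DEFAULT_UM_PER_PX

    def __post_init__(self) -> None:
        lo, hi = self.stoma_major_axis_px
        if not (0 < lo <= hi < min(self.width_px, self.height_px)):
            raise ValueError("stoma_major_axis_px must lie within (0, min(W, H))")
        if self.min_separation_px < hi:
            raise ValueError(
                "min_separation_px below the maximum major axis allows "
                "overlapping stomata")

    @classmethod
    def easy(cls, **overrides) -> "SynthConfig":
        """The *easy* regime used for pipeline validation.

        Restricts major axes to 60–90 px: with a 120-px patch and a 30-px
        stride, a stoma of length L is guaranteed at least one fully
        containing window only when L ≤ patch − stride = 90, since the
        window origins that fully contain it span an interval of length
        120 − L.  A border margin of one patch size keeps that interval
        clear of the truncated window grid at the image edges.  Within
        this regime an ideal window scorer recovers every stoma exactly;
        the default 60–120 px range matches the band a trained detector
        handles best but leaves the largest stomata without any fully
        containing window at this stride.
        """
        overrides.setdefault("stoma_major_axis_px", (60.0, 90.0))
        overrides.setdefault("border_margin_px", 120.0)
        return cls(**overrides)

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.width_px, self.height_px,
                           self.width_px * self.um_per_px,
                           self.height_px * self.um_per_px)


@dataclass
class SynthScene:
    """A rendered micrograph with its exact ground truth."""

    micrograph: Micrograph
    annotations: list[StomaAnnotation]
    artifact_locations: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def pair(self) -> tuple[Micrograph, list[StomaAnnotation]]:
        return self.micrograph, self.annotations


def _place_centers(cfg: SynthConfig, rng: np.random.Generator,
                   n: int, margins: np.ndarray) -> np.ndarray:
    """Rejection-sample centers with per-stoma border margin and mutual
    separation; raises :class:`PackingError` naming the achievable count."""
    centers: list[tuple[float, float]] = []
    max_tries = 200 * max(n, 1)
    tries = 0
    for i in range(n):
        placed = False
        m = margins[i]
        if (cfg.width_px - 1 - m < m) or (cfg.height_px - 1 - m < m):
            raise PackingError(
                f"border margin {m:.0f} px exceeds half the image; cannot "
                f"place stomata in a {cfg.width_px}x{cfg.height_px} image")
        while tries < max_tries:
            tries += 1
            x = rng.uniform(m, cfg.width_px - 1 - m)
            y = rng.uniform(m, cfg.height_px - 1 - m)
            ok = all((x - cx) ** 2 + (y - cy) ** 2 >= cfg.min_separation_px ** 2
                     for cx, cy in centers)
            if ok:
                centers.append((x, y))
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could only place {len(centers)} of {n} stomata at "
                f"min_separation {cfg.min_separation_px} px in a "
                f"{cfg.width_px}x{cfg.height_px} image")
    return np.array(centers).reshape(-1, 2)


def _mottle(shape: tuple[int, int], rng: np.random.Generator,
            sigma: float, amplitude: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    low = ndimage.gaussian_filter(noise, sigma)
    s = low.std()
    return (amplitude / s) * low if s > 0 else low


def _draw_stoma(img: np.ndarray, x: float, y: float, major: float,
                minor: float, theta: float, cfg: SynthConfig) -> None:
    """Oriented ellipse: lighter guard-cell rim around a dark pore slit."""
    a, b = major / 2.0, minor / 2.0
    r = int(np.ceil(a)) + 2
    y0, y1 = max(0, int(y) - r), min(img.shape[0], int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(img.shape[1], int(x) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - x, yy - y
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st          # along major axis
    v = -dx * st + dy * ct
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # guard-cell rim: bright annulus peaking at rho ~ 0.75
    rim = cfg.rim_height * np.exp(-((rho - 0.75) / 0.22) ** 2)
    rim[rho > 1.15] = 0.0
    # pore: dark slit elongated along the major axis
    slit = np.sqrt((u / (0.55 * a)) ** 2 + (v / (0.28 * b)) ** 2)
    pore = -cfg.pore_depth * np.exp(-slit ** 2)
    # faint dark outline at the ellipse boundary
    outline = -0.25 * cfg.rim_height * np.exp(-((rho - 1.0) / 0.08) ** 2)
    img[y0:y1, x0:x1] += rim + pore + outline


def _draw_artifact(img: np.ndarray, kind: str, x: float, y: float,
                   rng: np.random.Generator) -> None:
    h, w = img.shape
    if kind == "hair":
        # dark curved streak across a local neighborhood
        length = rng.uniform(150, 500)
        theta = rng.uniform(0, np.pi)
        curve = rng.uniform(-0.002, 0.002)
        t = np.linspace(-length / 2, length / 2, int(length * 2))
        xs = x + t * np.cos(theta) - curve * t ** 2 * np.sin(theta)
        ys = y + t * np.sin(theta) + curve * t ** 2 * np.cos(theta)
        width = rng.uniform(1.5, 3.5)
        depth = rng.uniform(0.2, 0.4)
        for off in np.linspace(-width / 2, width / 2, max(2, int(width * 2))):
            xi = np.round(xs + off * np.sin(theta)).astype(int)
            yi = np.round(ys - off * np.cos(theta)).astype(int)
            m = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            img[yi[m], xi[m]] -= depth
    elif kind == "bubble":
        rad = rng.uniform(15, 50)
        r = int(rad) + 3
        y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.sqrt((xx - x) ** 2 + (yy - y) ** 2) / rad
        img[y0:y1, x0:x1] += 0.18 * np.exp(-(d / 0.7) ** 2)        # bright lens
        img[y0:y1, x0:x1] -= 0.30 * np.exp(-((d - 1.0) / 0.08) ** 2)  # dark ring
    else:  # smudge
        rad = rng.uniform(25, 80)
        r = int(rad) + 3
        y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.sqrt((xx - x) ** 2 + (yy - y) ** 2) / rad
        img[y0:y1, x0:x1] -= rng.uniform(0.08, 0.2) * np.exp(-d ** 2)


def generate_micrograph(cfg: SynthConfig) -> SynthScene:
    """Render one synthetic micrograph with exact annotations.

    The annotation list contains exactly one entry per drawn stoma, at the
    ellipse center, with ``length_px`` equal to the drawn major axis; all
    centers keep at least ``min_separation_px`` from each other and half a
    major axis from the border (only fully visible stomata exist).
    """
    rng = np.random.default_rng(cfg.seed)
    n = (int(cfg.n_stomata) if np.isscalar(cfg.n_stomata)
         else int(rng.integers(cfg.n_stomata[0], cfg.n_stomata[1] + 1)))

    majors = rng.uniform(*cfg.stoma_major_axis_px, size=n)
    aspects = rng.uniform(*cfg.aspect_ratio, size=n)
    thetas = rng.uniform(0, np.pi, size=n)
    margins = majors / 2.0
    if cfg.border_margin_px is not None:
        margins = np.maximum(margins, cfg.border_margin_px)
    centers = _place_centers(cfg, rng, n, margins=margins)

    img = np.full((cfg.height_px, cfg.width_px), cfg.background_level)
    img += _mottle(img.shape, rng, sigma=60.0, amplitude=0.05)   # illumination
    img += _mottle(img.shape, rng, sigma=7.0, amplitude=0.035)   # cell texture

    for (x, y), L, asp, th in zip(centers, majors, aspects, thetas):
        _draw_stoma(img, x, y, L, L * asp, th, cfg)

    artifacts: list[tuple[float, float, str]] = []
    n_art = int(rng.poisson(cfg.artifact_rate))
    kinds = rng.choice(["hair", "bubble", "smudge"], size=n_art)
    for kind in kinds:
        # keep artifacts clear of stomata so synthetic labels stay unambiguous
        for _ in range(50):
            ax = rng.uniform(0, cfg.width_px - 1)
            ay = rng.uniform(0, cfg.height_px - 1)
            if n == 0 or (((centers[:, 0] - ax) ** 2 +
                           (centers[:, 1] - ay) ** 2).min()
                          >= (cfg.min_separation_px * 0.9) ** 2):
                _draw_artifact(img, str(kind), ax, ay, rng)
                artifacts.append((ax, ay, str(kind)))
                break

    if cfg.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, cfg.blur_sigma_px)
    if cfg.noise_level > 0:
        img = img + rng.standard_normal(img.shape) * cfg.noise_level
    # quantize to 8 bit, like the camera would
    img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)

    micro = Micrograph(cfg.image_id, img8, cfg.calibration)
    anns = [StomaAnnotation(cfg.image_id, float(x), float(y), float(L))
            for (x, y), L in zip(centers, majors)]
    return SynthScene(micro, anns, artifacts)


def generate_dataset(n_images: int, cfg: SynthConfig,
                     out_dir: str | Path | None = None) -> list[SynthScene]:
    """Generate ``n_images`` scenes; optionally write PNGs plus one CSV.

    Per-image seeds are derived deterministically from ``cfg.seed`` via a
    ``SeedSequence``, so the same call reproduces identical files.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(n_images)
    scenes = []
    for i in range(n_images):
        sub = replace(cfg, seed=int(child_seeds[i]) & 0x7FFFFFFF,
                      image_id=f"{cfg.image_id}_{i:03d}")
        scenes.append(generate_micrograph(sub))
    if out_dir is not None:
        from .io import write_annotations, write_png
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sc in scenes:
            write_png(out / f"{sc.micrograph.image_id}.png", sc.micrograph)
        write_annotations(out / "annotations.csv",
                          [a for sc in scenes for a in sc.annotations])
    return scenes
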