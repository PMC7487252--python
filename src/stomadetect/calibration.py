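"""Shared domain types and pixel/micrometer/density arithmetic.

The micrographs this package targets are focus-stacked light-microscope
images of epidermal leaf impressions, acquired at a fixed magnification so
that a known view field (in µm) maps onto a known pixel grid.  Everything
downstream — patch windows, detection coordinates, stomatal densities —
hangs off the conversions defined here.

Conventions: coordinates are 0-based with ``x`` the column and ``y`` the
row, origin at the top-left, pixel centers at integer coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Calibration",
    "Micrograph",
    "StomaAnnotation",
    "DensityResult",
    "CalibrationError",
    "view_field_area_mm2",
    "density_per_mm2",
    "um_per_px",
]

#: Default calibration: 1,600 x 1,200 px covering a 344 x 258 µm view field
#: (0.0888 mm², about 0.215 µm per pixel) — a x1,000 digital microscope setup.
DEFAULT_FIELD = (1600, 1200, 344.0, 258.0)


class CalibrationError(ValueError):
    """Raised for non-positive or inconsistent calibration values."""


@dataclass(frozen=True)
class Calibration:
    """Mapping between the pixel grid and the physical view field.

    Parameters
    ----------
    image_width_px, image_height_px : int
        Size of the pixel grid.
    field_width_um, field_height_um : float
        Physical extent of the imaged field, in micrometers.

    The µm-per-px ratio is expected to be square; a warning is emitted when
    the two axes disagree by more than 2%.
    """

    image_width_px: int
    image_height_px: int
    field_width_um: float
    field_height_um: float

    def __post_init__(self) -> None:
        for name in ("image_width_px", "image_height_px",
                     "field_width_um", "field_height_um"):
            if getattr(self, name) <= 0:
                raise CalibrationError(f"{name} must be strictly positive")
        rx = self.field_width_um / self.image_width_px
        ry = self.field_height_um / self.image_height_px
        if abs(rx - ry) > 0.02 * max(rx, ry):
            warnings.warn(
                f"anisotropic calibration: {rx:.4g} µm/px (x) vs "
                f"{ry:.4g} µm/px (y) differ by more than 2%",
                stacklevel=3,
            )

    @classmethod
    def default(cls) -> "Calibration":
        return cls(*DEFAULT_FIELD)


def view_field_area_mm2(cal: Calibration) -> float:
    """Area of the calibrated view field in mm², unrounded.

    E.g. a 344 x 258 µm field gives 0.088752 mm² (0.09 mm² at 2 dp).
    """
    return cal.field_width_um * cal.field_height_um / 1e6


def density_per_mm2(count: int, area_mm2: float) -> float:
    """Stomatal density, stomata per mm² of leaf surface."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be strictly positive")
    return count / area_mm2


def um_per_px(cal: Calibration) -> float:
    """Pixel pitch in µm/px, averaged over the two axes."""
    return 0.5 * (cal.field_width_um / cal.image_width_px
                  + cal.field_height_um / cal.image_height_px)


@dataclass
class Micrograph:
    """A single (possibly focus-stacked) micrograph.

    ``pixels`` is held as float in [0, 1]; 8-bit integer input is rescaled
    on construction.  Grayscale arrays are 2-D ``(H, W)``; RGB arrays are
    ``(H, W, 3)``.
    """

    image_id: str
    pixels: np.ndarray
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError("pixels must be (H, W) or (H, W, 3)")
        if np.issubdtype(px.dtype, np.integer):
            if px.min() < 0 or px.max() > 255:
                raise ValueError("integer pixel intensities must lie in [0, 255]")
            px = px.astype(np.float32) / 255.0
        else:
            px = px.astype(np.float32, copy=False)
            if px.size and (px.min() < -1e-6 or px.max() > 1.0 + 1e-6):
                raise ValueError("float pixel intensities must lie in [0, 1]")
        self.pixels = px
        if self.calibration is not None:
            ch, cw = self.calibration.image_height_px, self.calibration.image_width_px
            if (self.height, self.width) != (ch, cw):
                raise ValueError(
                    f"image is {self.width}x{self.height} px but calibration "
                    f"declares {cw}x{ch} px"
                )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def gray(self) -> np.ndarray:
        """Grayscale view, (H, W) float32 in [0, 1]."""
        if self.pixels.ndim == 2:
            return self.pixels
        # ITU-R 601 luma weights
        return (self.pixels @ np.array([0.299, 0.587, 0.114], dtype=np.float32))

    def density(self, count: int) -> "DensityResult":
        """Convert a stomata count on this image to stomata/mm²."""
        if self.calibration is None:
            raise CalibrationError(
                f"micrograph {self.image_id!r} has no calibration; "
                "density requires one"
            )
        area = view_field_area_mm2(self.calibration)
        return DensityResult(self.image_id, count, area,
                             density_per_mm2(count, area))


@dataclass(frozen=True)
class StomaAnnotation:
    """Ground-truth stoma: center coordinates plus approximate length.

    ``length_px`` is the major-axis extent of the stoma (guard cells
    included); it defaults to the patch size used throughout, 120 px.
    Only stomata lying entirely within the view field are annotated.
    """

    image_id: str
    x_px: float
    y_px: float
    length_px: float = 120.0

    def __post_init__(self) -> None:
        if self.length_px <= 0:
            raise ValueError("length_px must be strictly positive")
        if self.x_px < 0 or self.y_px < 0:
            raise ValueError("annotation coordinates must be non-negative")

    def validate_against(self, m: Micrograph) -> None:
        if not (0 <= self.x_px < m.width and 0 <= self.y_px < m.height):
            raise ValueError(
                f"annotation ({self.x_px}, {self.y_px}) outside image "
                f"{m.image_id!r} of size {m.width}x{m.height}"
            )


@dataclass(frozen=True)
class DensityResult:
    image_id: str
    count: int
    area_mm2: float
    density_per_mm2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.density_per_mm2 is None:
            object.__setattr__(self, "density_per_mm2",
                               density_per_mm2(self.count, self.area_mm2))
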