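"""Image loading and physical calibration.

Scans of seedling roots arrive as PNG/TIFF/JPEG files, grayscale or RGB.
Everything downstream works on a plain 2D uint8-range intensity grid with an
optional pixels-per-cm calibration attached.  The coordinate convention used
throughout the package is 0-based (row y, column x): y increases downward
(depth), x increases rightward.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "RasterImage",
    "CalibrationScale",
    "ImageInputError",
    "ValidationError",
    "load_image",
    "to_length",
    "to_grayscale",
]


class ImageInputError(ValueError):
    """Raised when an input file cannot be read as an image."""


class ValidationError(ValueError):
    """Raised when a value violates a domain precondition."""


@dataclass(frozen=True)
class CalibrationScale:
    """Physical calibration: how many pixels span one centimeter.

    Scanners report DPI, but flatbed root scans are commonly shared without
    reliable metadata, so calibration is an explicit user input and all
    traits fall back to pixel units when it is absent.
    """

    pixels_per_cm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixels_per_cm) or self.pixels_per_cm <= 0:
            raise ValidationError(
                f"pixels_per_cm must be a positive finite number, got {self.pixels_per_cm!r}"
            )


@dataclass
class RasterImage:
    """A 2D grayscale intensity grid in [0, 255] with optional calibration."""

    pixels: np.ndarray
    pixels_per_cm: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError(
                f"image must be a non-empty 2D grid, got shape {px.shape}"
            )
        if px.min() < 0 or px.max() > 255:
            raise ValidationError("intensities must lie within [0, 255]")
        self.pixels = px
        if self.pixels_per_cm is not None and self.pixels_per_cm <= 0:
            raise ValidationError("pixels_per_cm must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def scale(self) -> Optional[CalibrationScale]:
        if self.pixels_per_cm is None:
            return None
        return CalibrationScale(self.pixels_per_cm)


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, C) array to (H, W) by the unweighted channel mean.

    Root scans are near-monochrome, so plain channel averaging is used
    instead of luminance weighting; an already-2D array passes through
    unchanged (idempotence).
    """
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 2:
        return a
    if a.ndim == 3:
        return a.mean(axis=2)
    raise ValidationError(f"cannot interpret array of shape {a.shape} as an image")


def load_image(
    path: Union[str, Path], pixels_per_cm: Optional[float] = None
) -> RasterImage:
    """Load a PNG/TIFF/JPEG scan as a grayscale :class:`RasterImage`.

    RGB(A) inputs are converted by unweighted channel mean over the color
    channels (alpha is dropped).  Calibration is never inferred from file
    metadata; pass ``pixels_per_cm`` explicitly to attach one.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ImageInputError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"image {path} is zero-sized")
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha before averaging
        arr = arr[:, :, :3]
    gray = to_grayscale(arr)
    # 16-bit TIFFs and similar are rescaled onto the canonical 0-255 range.
    if gray.max() > 255:
        gray = gray * (255.0 / float(np.iinfo(np.asarray(arr).dtype).max))
    return RasterImage(gray, pixels_per_cm=pixels_per_cm)


def to_length(pixel_count: float, scale: CalibrationScale) -> float:
    """Convert a length measured in pixels to centimeters.

    Linear by construction: ``to_length(a + b) == to_length(a) + to_length(b)``.
    """
    if pixel_count < 0:
        raise ValidationError("pixel_count must be nonnegative")
    return float(pixel_count) / scale.pixels_per_cm
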