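"""Background normalization, Otsu thresholding and root-object isolation.

The segmentation stage turns a grayscale scan into per-root binary masks:

1. estimate the background intensity mode and subtract it (roots end up
   bright on a near-zero background);
2. threshold with Otsu's method on the 256-bin histogram;
3. label connected components (8-connectivity, so thin diagonal root
   segments stay in one piece) and keep the large ones;
4. group components into up to ``max_roots`` left-to-right bounding boxes,
   merging components whose horizontal extents overlap (fragments of one
   root).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .image_io import RasterImage, ValidationError

__all__ = [
    "BoundingBox",
    "RootMask",
    "NoRootError",
    "DegenerateImageError",
    "normalize_background",
    "otsu_threshold",
    "binarize",
    "largest_component",
    "detect_root_regions",
    "crop_mask",
]

# 8-connectivity structuring element shared by all labeling calls.
_STRUCT8 = np.ones((3, 3), dtype=bool)

#: Minimum component size in pixels at full scan resolution (~4400x6200);
#: scaled down proportionally to the image area for smaller images.
MIN_COMPONENT_SIZE = 100
REFERENCE_AREA = 4400 * 6200

#: Padding (pixels) added around each detected root box before cropping.
BBOX_PAD = 10

#: Fraction of each image dimension treated as the border frame when
#: estimating the background mode.
BORDER_FRACTION = 0.05


class NoRootError(ValueError):
    """Raised when no foreground object qualifies as a root."""


class DegenerateImageError(ValueError):
    """Raised when an image is constant and cannot be thresholded."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, half-open on bottom and right."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise ValidationError(f"degenerate bounding box {self}")

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    def padded(self, pad: int, shape: tuple) -> "BoundingBox":
        """Expand by ``pad`` pixels, clipped to an image of the given shape."""
        return BoundingBox(
            max(0, self.top - pad),
            max(0, self.left - pad),
            min(shape[0], self.bottom + pad),
            min(shape[1], self.right + pad),
        )


@dataclass
class RootMask:
    """Binary foreground grid for a single connected root object."""

    bits: np.ndarray
    bbox: BoundingBox

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if not self.bits.any():
            raise NoRootError("root mask has no foreground pixels")
        ys, xs = np.nonzero(self.bits)
        if (
            ys.min() < self.bbox.top
            or ys.max() >= self.bbox.bottom
            or xs.min() < self.bbox.left
            or xs.max() >= self.bbox.right
        ):
            raise ValidationError("foreground pixels fall outside the bounding box")


def _tight_bbox(bits: np.ndarray) -> BoundingBox:
    ys, xs = np.nonzero(bits)
    return BoundingBox(int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1)


def normalize_background(img: RasterImage) -> RasterImage:
    """Subtract the modal background intensity, clamped at zero.

    The mode is estimated from the histogram of the image's border frame
    (outer 5% on each side), where root tissue is assumed absent; an
    already-black background makes this a no-op.
    """
    px = img.pixels
    b = max(1, int(round(BORDER_FRACTION * min(px.shape))))
    frame = np.concatenate(
        [
            px[:b, :].ravel(),
            px[-b:, :].ravel(),
            px[b:-b, :b].ravel(),
            px[b:-b, -b:].ravel(),
        ]
    )
    if frame.size == 0:  # image smaller than the frame: use everything
        frame = px.ravel()
    hist, _ = np.histogram(frame, bins=256, range=(0, 256))
    mode = int(np.argmax(hist))
    out = np.clip(px - mode, 0.0, 255.0)
    return RasterImage(out, pixels_per_cm=img.pixels_per_cm)


def otsu_threshold(img: RasterImage) -> int:
    """Otsu's threshold on the 256-bin histogram.

    Returns the integer intensity ``t`` maximizing the between-class
    variance of the {pixels <= t} / {pixels > t} split, with ties broken by
    the smallest such ``t``.  Foreground is defined downstream as
    intensity > t.
    """
    px = img.pixels
    hist, _ = np.histogram(px, bins=256, range=(0, 256))
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image cannot be thresholded")
    hist = hist.astype(np.float64)
    total = hist.sum()
    omega = np.cumsum(hist) / total            # P(class0) for t = 0..255
    mu = np.cumsum(hist * np.arange(256)) / total
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def binarize(img: RasterImage, t: float, invert: bool = False) -> np.ndarray:
    """Foreground = intensity strictly above the threshold.

    ``invert`` handles dark-roots-on-light scans (foreground below t).
    """
    if invert:
        return img.pixels < t
    return img.pixels > t


def largest_component(bits: np.ndarray) -> RootMask:
    """Keep only the largest 8-connected foreground component.

    Everything else is treated as noise.  Equal-size ties are broken by the
    component containing the smallest (top, left) pixel, for determinism.
    """
    bits = np.asarray(bits, dtype=bool)
    if not bits.any():
        raise NoRootError("no foreground pixels")
    labels, n = ndimage.label(bits, structure=_STRUCT8)
    sizes = ndimage.sum_labels(bits, labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    candidates = np.nonzero(sizes == best_size)[0] + 1
    if len(candidates) == 1:
        best = candidates[0]
    else:
        # tie-break: component whose first pixel in raster order comes first
        order = {}
        flat = labels.ravel()
        for lab in candidates:
            order[lab] = np.argmax(flat == lab)
        best = min(candidates, key=lambda lab: order[lab])
    keep = labels == best
    return RootMask(keep, _tight_bbox(keep))


#: Absolute floor on the noise-component size: area scaling from the full
#: scan resolution would otherwise let single speckle pixels qualify as
#: roots in small images.
MIN_COMPONENT_FLOOR = 16


def _min_size_for(shape: tuple, override: Optional[int] = None) -> float:
    if override is not None:
        return override
    area = shape[0] * shape[1]
    return max(MIN_COMPONENT_FLOOR, MIN_COMPONENT_SIZE * area / REFERENCE_AREA)


def detect_root_regions(
    bits: np.ndarray,
    max_roots: int = 3,
    min_component_size: Optional[int] = None,
    pad: int = BBOX_PAD,
) -> List[BoundingBox]:
    """Find up to ``max_roots`` per-root bounding boxes, left to right.

    Components above the size floor are grouped by overlapping horizontal
    extent (fragments of a single root share an x-interval); the largest
    ``max_roots`` groups survive.  Returned boxes are padded by ``pad``
    pixels, clipped to the image, and sorted by left edge.
    """
    if max_roots < 1:
        raise ValidationError("max_roots must be >= 1")
    bits = np.asarray(bits, dtype=bool)
    min_size = _min_size_for(bits.shape, min_component_size)
    labels, n = ndimage.label(bits, structure=_STRUCT8)
    if n == 0:
        raise NoRootError("no foreground component")
    sizes = ndimage.sum_labels(bits, labels, index=np.arange(1, n + 1))
    objs = ndimage.find_objects(labels)
    regions = []  # (left, right, top, bottom, size) per surviving component
    for lab in range(1, n + 1):
        if sizes[lab - 1] < min_size:
            continue
        sl = objs[lab - 1]
        regions.append(
            [sl[1].start, sl[1].stop, sl[0].start, sl[0].stop, float(sizes[lab - 1])]
        )
    if not regions:
        raise NoRootError("no component above the minimum size")

    # merge regions whose x-intervals overlap, until a fixed point
    regions.sort(key=lambda r: r[0])
    merged: List[list] = []
    for r in regions:
        if merged and r[0] < merged[-1][1]:  # x-overlap with previous group
            m = merged[-1]
            m[1] = max(m[1], r[1])
            m[2] = min(m[2], r[2])
            m[3] = max(m[3], r[3])
            m[4] += r[4]
        else:
            merged.append(list(r))

    merged.sort(key=lambda r: -r[4])
    merged = merged[:max_roots]
    merged.sort(key=lambda r: r[0])
    return [
        BoundingBox(r[2], r[0], r[3], r[1]).padded(pad, bits.shape) for r in merged
    ]


def crop_mask(bits: np.ndarray, box: BoundingBox) -> RootMask:
    """Crop a region and keep its largest component as the root mask."""
    sub = np.asarray(bits, dtype=bool)[box.top : box.bottom, box.left : box.right]
    return largest_component(sub)
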