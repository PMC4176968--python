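"""Synthetic root-scan generator with exact polyline ground truth.

Emulates flatbed scans of seedling roots: bright, thin, branching
structures on a dark noisy background, with a roughly vertical primary
axis and lateral branches.  Curves are generated as unit-step heading
random walks, rasterized with hard (non-antialiased) strokes so that
thresholding is unambiguous, and the generating polylines are returned as
ground truth — their arc lengths are exact and independent of
rasterization, which is what makes pipeline length estimates testable.

The random model (heading jitter, uniform branch depths/lengths/angles)
is chosen to span the trait space — bushiness, length distribution,
width/depth ratio — not to mimic the biology of any particular species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import line as _draw_line
from skimage.morphology import disk

from .image_io import RasterImage, ValidationError

__all__ = ["SyntheticRootSpec", "GroundTruth", "generate_root", "generate_scan"]

#: Foreground stroke intensity (background noise stays far below Otsu's cut).
FOREGROUND_INTENSITY = 220.0


@dataclass(frozen=True)
class SyntheticRootSpec:
    """Parameters of one synthetic root.

    Angles are measured from vertical (0 = straight down); ``curvature``
    is the per-step heading jitter standard deviation in degrees.
    """

    primary_length_px: float = 300.0
    n_branches: int = 5
    branch_length_range: Tuple[float, float] = (30.0, 90.0)
    branch_angle_range: Tuple[float, float] = (30.0, 70.0)
    curvature: float = 1.0
    stroke_width_px: int = 3
    noise_sd: float = 6.0
    seed: int = 0
    canvas_shape: Optional[Tuple[int, int]] = None  # (H, W); derived if None

    def __post_init__(self) -> None:
        if self.primary_length_px <= 0:
            raise ValidationError("primary_length_px must be positive")
        if self.n_branches < 0:
            raise ValidationError("n_branches must be nonnegative")
        lo, hi = self.branch_length_range
        if lo <= 0 or hi < lo:
            raise ValidationError("branch_length_range must be positive and ordered")
        if self.stroke_width_px < 1 or self.stroke_width_px % 2 == 0:
            raise ValidationError("stroke_width_px must be an odd positive integer")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.hypot(*(np.diff(points, axis=0).T))))


@dataclass
class GroundTruth:
    """Exact generative geometry of one synthetic root."""

    primary_polyline: np.ndarray  # (N, 2) float (y, x) points
    primary_length_px: float
    branch_polylines: List[np.ndarray] = field(default_factory=list)
    branch_lengths: List[float] = field(default_factory=list)
    band_length_fractions: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    bbox: Tuple[int, int, int, int] = (0, 0, 0, 0)  # top, left, bottom, right
    #: True when a rasterized lateral touches another lateral, or re-touches
    #: the primary away from its own attachment; branch-count recovery is
    #: only guaranteed for non-overlapping placements
    overlapping: bool = False

    @property
    def total_length_px(self) -> float:
        return self.primary_length_px + float(sum(self.branch_lengths))

    @property
    def n_branches(self) -> int:
        return len(self.branch_polylines)

    def shifted(self, dy: int, dx: int) -> "GroundTruth":
        off = np.array([dy, dx], dtype=float)
        t, l, b, r = self.bbox
        return GroundTruth(
            primary_polyline=self.primary_polyline + off,
            primary_length_px=self.primary_length_px,
            branch_polylines=[p + off for p in self.branch_polylines],
            branch_lengths=list(self.branch_lengths),
            band_length_fractions=self.band_length_fractions,
            bbox=(t + dy, l + dx, b + dy, r + dx),
            overlapping=self.overlapping,
        )


#: Per-step pull of the heading back toward the growth direction; models
#: gravitropism and keeps a jittered axis from drifting into a random walk.
HEADING_REVERSION = 0.95


def _walk(
    start: np.ndarray,
    heading_deg: float,
    length: float,
    jitter_sd: float,
    rng: np.random.Generator,
    step: float = 1.0,
) -> np.ndarray:
    """Mean-reverting heading walk; heading 0 points straight down (+y)."""
    n = int(math.ceil(length / step))
    pts = np.empty((n + 1, 2))
    pts[0] = start
    h0 = math.radians(heading_deg)
    h = h0
    for i in range(n):
        if jitter_sd > 0:
            h = h0 + HEADING_REVERSION * (h - h0) + math.radians(
                rng.normal(0.0, jitter_sd)
            )
        pts[i + 1] = pts[i] + step * np.array([math.cos(h), math.sin(h)])
    # trim the last step so the arc length is exactly `length`
    if n * step > length:
        excess = n * step - length
        d = pts[-1] - pts[-2]
        pts[-1] = pts[-1] - d * (excess / step)
    return pts


def _band_fractions(
    polylines: Sequence[np.ndarray], top: float, bottom: float
) -> Tuple[float, float, float]:
    """Split total polyline length into depth-thirds by segment midpoint."""
    b1 = top + (bottom - top) / 3.0
    b2 = top + 2.0 * (bottom - top) / 3.0
    bands = [0.0, 0.0, 0.0]
    for poly in polylines:
        mids = (poly[:-1, 0] + poly[1:, 0]) / 2.0
        seglens = np.hypot(*(np.diff(poly, axis=0).T))
        bands[0] += float(seglens[mids < b1].sum())
        bands[1] += float(seglens[(mids >= b1) & (mids < b2)].sum())
        bands[2] += float(seglens[mids >= b2].sum())
    total = sum(bands)
    if total == 0:
        return (0.0, 0.0, 0.0)
    return tuple(b / total for b in bands)  # type: ignore[return-value]


def _rasterize(
    polylines: Sequence[np.ndarray], shape: Tuple[int, int], width: int
) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    for poly in polylines:
        pts = np.rint(poly).astype(int)
        for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
            rr, cc = _draw_line(y0, x0, y1, x1)
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            canvas[rr[ok], cc[ok]] = True
    if width > 1:
        canvas = binary_dilation(canvas, structure=disk((width - 1) // 2))
    return canvas


def generate_root(spec: SyntheticRootSpec) -> Tuple[RasterImage, GroundTruth]:
    """Draw one synthetic root and return the image plus exact ground truth.

    The primary curve grows downward from the top with heading jitter;
    laterals attach at well-separated arc positions (between 15% and 85%
    of the primary length) and grow outward-downward on alternating sides.
    Output is deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    margin = 4 * spec.stroke_width_px + 8
    lo, hi = spec.branch_length_range
    if spec.canvas_shape is None:
        # leave room for lateral reach plus residual drift of the axis
        drift = int(0.25 * spec.primary_length_px)
        h = int(spec.primary_length_px + 2 * margin)
        w = 2 * (int(hi) + drift + 2 * margin) if spec.n_branches else int(
            4 * margin + 2 * drift
        )
        shape = (h, w)
    else:
        shape = spec.canvas_shape
    if shape[0] < spec.primary_length_px / 2 or shape[1] < 2 * margin:
        raise ValidationError(f"canvas {shape} too small for spec")

    start = np.array([float(margin), shape[1] / 2.0])
    primary = _walk(start, 0.0, spec.primary_length_px, spec.curvature, rng)

    # lateral attachment arc-positions: evenly spaced slots with jitter so
    # branches stay separated and never collide with the root's ends
    branches: List[np.ndarray] = []
    if spec.n_branches > 0:
        seg = np.hypot(*(np.diff(primary, axis=0).T))
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        slots = np.linspace(0.2, 0.8, spec.n_branches + 1)
        pos = slots[:-1] + rng.uniform(0.1, 0.9, spec.n_branches) * np.diff(slots)
        for k, frac in enumerate(pos):
            arc = frac * cum[-1]
            idx = int(np.searchsorted(cum, arc))
            idx = min(max(idx, 1), len(primary) - 1)
            attach = primary[idx]
            side = 1 if k % 2 == 0 else -1  # alternate left/right
            angle = side * rng.uniform(*spec.branch_angle_range)
            # seedlings analyzed here have one dominant primary axis: a
            # lateral must stay shorter than the primary length remaining
            # on either side of its attachment, or the longest
            # free-end-to-free-end path would run through the lateral
            # instead of down the primary
            cap = 0.7 * min(frac, 1.0 - frac) * cum[-1]
            length = min(rng.uniform(lo, hi), cap)
            branch = _walk(attach, angle, length, spec.curvature, rng)
            branches.append(branch)
            if branch[:, 1].max() >= shape[1] or branch[:, 1].min() < 0:
                raise ValidationError("branch leaves the canvas; widen canvas_shape")

    # overlap audit on the rasterized strokes: a lateral may touch the
    # primary only near its own attachment, and never another lateral
    primary_fg = _rasterize([primary], shape, spec.stroke_width_px)
    branch_fgs = [_rasterize([b], shape, spec.stroke_width_px) for b in branches]
    overlapping = False
    touch_radius = 3.0 * spec.stroke_width_px
    for k, bfg in enumerate(branch_fgs):
        inter = bfg & primary_fg
        if inter.any():
            yy, xx = np.nonzero(inter)
            d = np.hypot(yy - branches[k][0, 0], xx - branches[k][0, 1])
            if d.max() > touch_radius:
                overlapping = True
        for other in branch_fgs[k + 1 :]:
            if (bfg & other).any():
                overlapping = True

    fg = _rasterize([primary, *branches], shape, spec.stroke_width_px)
    img = np.zeros(shape, dtype=float)
    if spec.noise_sd > 0:
        img += np.abs(rng.normal(0.0, spec.noise_sd, shape))
    img[fg] = FOREGROUND_INTENSITY
    img = np.clip(img, 0.0, 255.0)

    ys, xs = np.nonzero(fg)
    bbox = (int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1)
    all_polys = [primary, *branches]
    top = min(float(p[:, 0].min()) for p in all_polys)
    bottom = max(float(p[:, 0].max()) for p in all_polys)
    truth = GroundTruth(
        primary_polyline=primary,
        primary_length_px=_polyline_length(primary),
        branch_polylines=branches,
        branch_lengths=[_polyline_length(b) for b in branches],
        band_length_fractions=_band_fractions(all_polys, top, bottom),
        bbox=bbox,
        overlapping=overlapping,
    )
    return RasterImage(img), truth


def generate_scan(
    specs: Sequence[SyntheticRootSpec], spacing_px: int = 60
) -> Tuple[RasterImage, List[GroundTruth]]:
    """Composite 1–3 roots side by side on one canvas, like a real scan.

    Ground truths carry each root's horizontal offset.  Roots are placed
    left to right in spec order.
    """
    if not 1 <= len(specs) <= 3:
        raise ValidationError("a scan holds between 1 and 3 roots")
    parts = [generate_root(s) for s in specs]
    heights = [img.height for img, _ in parts]
    widths = [img.width for img, _ in parts]
    H = max(heights)
    W = sum(widths) + spacing_px * (len(parts) - 1)
    canvas = np.zeros((H, W))
    truths: List[GroundTruth] = []
    x0 = 0
    for (img, truth), w in zip(parts, widths):
        canvas[: img.height, x0 : x0 + w] = np.maximum(
            canvas[: img.height, x0 : x0 + w], img.pixels
        )
        truths.append(truth.shifted(0, x0))
        x0 += w + spacing_px
    return RasterImage(canvas), truths
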