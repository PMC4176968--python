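"""The 27 root-system-architecture traits.

Traits are computed from three representations of one root: the binary
mask (areas, extents, centroids), the skeleton and its pixel graph
(lengths, per-row counts, tip counts), and the primary/secondary partition
(primary length, lateral lengths, primary-tube geometry).

Groups:

* lengths — TRL (total root length), PRL (primary root length), SEL
  (cumulative secondary length); TRL = PRL + SEL holds as an identity.
* extents — DEP (depth), WID (width), WDR = WID/DEP.
* areas — PER (perimeter pixels), CVA (convex-hull area), NWA (skeleton
  pixel count, "network area"), SOL = NWA/CVA (solidity).
* counts — per-row skeleton-pixel counts give MNR (84th percentile,
  nearest rank) and MED (median); TNR is the number of skeleton tips;
  BSH = MNR/MED (bushiness).
* vertical distribution — LED (fraction of total length in the top third
  of the root's depth extent), COM/COP and their per-band variants
  CMT/CMM/CMB, CPT/CPM/CPB, all normalized vertical positions in [0, 1].
* primary-tube geometry — local radius along the primary path from the
  Euclidean distance transform gives DIA (mean diameter), VOL and SUA
  (solid-of-revolution volume and lateral surface), SRL = TRL/VOL
  (specific root length).

Calibrated output divides lengths by pixels-per-cm s (areas by s^2,
volumes by s^3); otherwise values stay in pixel units and the vector is
flagged uncalibrated.  A trait whose preconditions fail is reported as NaN
and listed in ``missing`` — never silently zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

from .image_io import CalibrationScale
from .root_topology import RootPartition
from .segmentation import RootMask
from .skeleton_graph import endpoints, total_weight

__all__ = [
    "TRAIT_NAMES",
    "TraitVector",
    "length_traits",
    "extent_traits",
    "area_traits",
    "count_traits",
    "distribution_traits",
    "primary_geometry",
    "compute_all",
]

logger = logging.getLogger(__name__)

#: Canonical trait order used in every exported table.
TRAIT_NAMES: Tuple[str, ...] = (
    "TRL", "PRL", "SEL",
    "COM", "COP", "CMT", "CMM", "CMB", "CPT", "CPM", "CPB",
    "MNR", "PER", "DEP", "WID", "WDR", "MED", "TNR",
    "CVA", "NWA", "SOL", "BSH", "LED",
    "DIA", "VOL", "SUA", "SRL",
)


@dataclass
class TraitVector:
    """All 27 named trait values for one root, plus the unit flag."""

    values: Dict[str, float]
    units_flag: str = "px"  # "cm" when a calibration was applied
    missing: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if set(self.values) != set(TRAIT_NAMES):
            extra = set(self.values) - set(TRAIT_NAMES)
            absent = set(TRAIT_NAMES) - set(self.values)
            raise ValueError(f"trait set mismatch: extra={extra}, absent={absent}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_row(self) -> Dict[str, float]:
        return {name: self.values[name] for name in TRAIT_NAMES}


# ---------------------------------------------------------------------------
# lengths

def length_traits(p: RootPartition) -> Tuple[float, float, float]:
    """(TRL, PRL, SEL) in pixels.  TRL = PRL + SEL by construction."""
    prl = p.primary_length
    sel = p.secondary_total
    return prl + sel, prl, sel


# ---------------------------------------------------------------------------
# extents

def extent_traits(mask: RootMask) -> Tuple[float, float, float]:
    """(DEP, WID, WDR): vertical/horizontal extents of the foreground."""
    ys, xs = np.nonzero(mask.bits)
    dep = float(ys.max() - ys.min() + 1)
    wid = float(xs.max() - xs.min() + 1)
    return dep, wid, wid / dep


# ---------------------------------------------------------------------------
# areas

def _convex_area(points: np.ndarray) -> float:
    """Number of pixel centers inside or on the convex hull of ``points``.

    Degenerate (collinear) point sets have a zero-area hull that contains
    exactly the points themselves.
    """
    uniq = np.unique(points, axis=0)
    if len(uniq) < 3:
        return float(len(uniq))
    try:
        tri = Delaunay(uniq)
    except QhullError:  # collinear foreground
        return float(len(uniq))
    ymin, xmin = uniq.min(axis=0)
    ymax, xmax = uniq.max(axis=0)
    gy, gx = np.mgrid[ymin : ymax + 1, xmin : xmax + 1]
    grid = np.column_stack([gy.ravel(), gx.ravel()]).astype(float)
    inside = tri.find_simplex(grid, tol=1e-9) >= 0
    return float(np.count_nonzero(inside))


def area_traits(mask: RootMask, skel: np.ndarray) -> Tuple[float, float, float, float]:
    """(PER, CVA, NWA, SOL).

    PER counts foreground pixels with at least one background 8-neighbor
    (the image border counts as background); CVA counts pixel centers in
    the convex hull of the foreground; NWA is the skeleton pixel count;
    SOL = NWA / CVA.
    """
    bits = mask.bits
    interior = ndimage.binary_erosion(bits, structure=np.ones((3, 3)), border_value=0)
    per = float(np.count_nonzero(bits) - np.count_nonzero(interior))
    cva = _convex_area(np.column_stack(np.nonzero(bits)))
    nwa = float(np.count_nonzero(skel))
    return per, cva, nwa, nwa / cva


# ---------------------------------------------------------------------------
# counts

def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic."""
    n = len(sorted_vals)
    k = max(1, math.ceil(q * n))
    return float(sorted_vals[k - 1])


def count_traits(skel: np.ndarray, graph: nx.Graph) -> Tuple[float, float, float, float]:
    """(MNR, MED, TNR, BSH) from per-row skeleton-pixel counts.

    A row's count is the number of skeleton pixels it contains — the
    number of distinct roots crossing that scan line.  MNR is the 84th
    percentile (nearest rank, about +1 sd for a normal spread), MED the
    median, TNR the number of degree-1 skeleton tips, BSH = MNR/MED.
    """
    rows = np.count_nonzero(skel, axis=1)
    rows = rows[rows > 0]  # rows intersecting the root
    rows.sort()
    mnr = _nearest_rank(rows, 0.84)
    med = float(np.median(rows))
    tnr = float(len(endpoints(graph)))
    return mnr, med, tnr, mnr / med


# ---------------------------------------------------------------------------
# vertical distribution

def _band_edges(top: int, dep: float) -> Tuple[float, float]:
    return top + dep / 3.0, top + 2.0 * dep / 3.0


def distribution_traits(
    mask: RootMask, graph: nx.Graph, p: RootPartition
) -> Dict[str, float]:
    """LED and the COM/COP family of normalized vertical positions.

    The root's bounding rows are split into three equal-depth bands.  LED
    is the fraction of skeleton path length (edge weights, assigned by
    edge-midpoint row) falling in the top band.  COM is the foreground
    y-centroid normalized by depth; COP is the bounding-box y-midpoint
    normalized likewise (0.5 by construction).  CMT/CMM/CMB and
    CPT/CPM/CPB repeat the pair inside each band, normalized to the band's
    own height.  Pixel centers sit at y + 0.5, so a uniform vertical bar
    scores exactly 0.5.  Bands degenerate below 3 rows of depth: band
    traits become NaN.
    """
    ys, _ = np.nonzero(mask.bits)
    top, bottom = int(ys.min()), int(ys.max()) + 1
    dep = float(bottom - top)
    out: Dict[str, float] = {}

    # LED: top-band share of total skeleton length
    b1, _ = _band_edges(top, dep)
    trl = total_weight(graph)
    if trl > 0:
        top_len = sum(
            w
            for (u, v, w) in graph.edges(data="weight")
            if (u[0] + v[0]) / 2.0 + 0.5 < b1
        )
        out["LED"] = top_len / trl
    else:
        out["LED"] = 1.0 if ys.mean() + 0.5 < b1 else 0.0  # single-pixel skeleton

    out["COM"] = float((ys.mean() + 0.5 - top) / dep)
    out["COP"] = 0.5  # bbox midpoint normalized by depth

    if dep < 3:
        for name in ("CMT", "CMM", "CMB", "CPT", "CPM", "CPB"):
            out[name] = float("nan")
        return out

    edges = [top, *_band_edges(top, dep), bottom]
    for i, (lo, hi), in enumerate(zip(edges[:-1], edges[1:])):
        suffix = "TMB"[i]
        centers = ys + 0.5
        in_band = (centers >= lo) & (centers < hi) if i < 2 else (centers >= lo)
        band_h = hi - lo
        if not in_band.any():
            out[f"CM{suffix}"] = float("nan")
            out[f"CP{suffix}"] = float("nan")
            continue
        band_ys = ys[in_band]
        out[f"CM{suffix}"] = float((band_ys.mean() + 0.5 - lo) / band_h)
        mid = (band_ys.min() + band_ys.max() + 1) / 2.0
        out[f"CP{suffix}"] = float((mid - lo) / band_h)
    return out


# ---------------------------------------------------------------------------
# primary-tube geometry

def primary_geometry(
    mask: RootMask, p: RootPartition
) -> Tuple[float, float, float, float]:
    """(DIA, VOL, SUA, SRL) in pixel units.

    The mask's Euclidean distance transform gives a local radius at each
    primary-path vertex (r = EDT − 0.5 px, the distance from the pixel
    center to the mask boundary, clamped at 0.5 for one-pixel-wide
    spans).  The primary root is modeled as a solid of revolution along
    its path: VOL = sum(pi r^2 ds) and SUA = sum(2 pi r ds) per segment,
    with r averaged over the segment's two vertices and ds the edge
    weight.  DIA = 2 mean(r); SRL = TRL / VOL.
    """
    edt = ndimage.distance_transform_edt(mask.bits)
    radii = []
    for v in p.primary_path:
        r = edt[v] - 0.5
        if r < 0.5:
            if edt[v] <= 0:
                logger.warning("primary path vertex %s off the mask; radius clamped", v)
            r = 0.5
        radii.append(float(r))
    radii_arr = np.asarray(radii)
    dia = 2.0 * float(radii_arr.mean())
    vol = 0.0
    sua = 0.0
    for (u, v), (ru, rv) in zip(
        zip(p.primary_path[:-1], p.primary_path[1:]), zip(radii[:-1], radii[1:])
    ):
        ds = 1.0 if u[0] == v[0] or u[1] == v[1] else math.sqrt(2.0)
        r = 0.5 * (ru + rv)
        vol += math.pi * r * r * ds
        sua += 2.0 * math.pi * r * ds
    trl = p.primary_length + p.secondary_total
    srl = trl / vol if vol > 0 else float("nan")
    return dia, vol, sua, srl


# ---------------------------------------------------------------------------
# assembly

def compute_all(
    mask: RootMask,
    skel: np.ndarray,
    graph: nx.Graph,
    partition: RootPartition,
    scale: Optional[CalibrationScale] = None,
) -> TraitVector:
    """Populate the full 27-trait vector for one root.

    With a calibration, length traits are divided by s = pixels_per_cm,
    SUA by s^2, VOL by s^3 and SRL recomputed, so SRL * VOL = TRL remains
    an identity in either unit system; PER, CVA and NWA stay pixel counts
    and the normalized distribution traits are unitless.
    """
    vals: Dict[str, float] = {}
    trl, prl, sel = length_traits(partition)
    vals.update(TRL=trl, PRL=prl, SEL=sel)
    dep, wid, wdr = extent_traits(mask)
    vals.update(DEP=dep, WID=wid, WDR=wdr)
    per, cva, nwa, sol = area_traits(mask, skel)
    vals.update(PER=per, CVA=cva, NWA=nwa, SOL=sol)
    mnr, med, tnr, bsh = count_traits(skel, graph)
    vals.update(MNR=mnr, MED=med, TNR=tnr, BSH=bsh)
    vals.update(distribution_traits(mask, graph, partition))
    dia, vol, sua, srl = primary_geometry(mask, partition)
    vals.update(DIA=dia, VOL=vol, SUA=sua, SRL=srl)

    units = "px"
    if scale is not None:
        s = scale.pixels_per_cm
        for name in ("TRL", "PRL", "SEL", "DEP", "WID", "DIA"):
            vals[name] /= s
        vals["SUA"] /= s**2
        vals["VOL"] /= s**3
        vals["SRL"] = vals["TRL"] / vals["VOL"] if vals["VOL"] > 0 else float("nan")
        units = "cm"

    missing = {name for name, v in vals.items() if not np.isfinite(v)}
    return TraitVector(values=vals, units_flag=units, missing=missing)
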