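"""Skeletonization and the weighted pixel graph.

The root mask is thinned to a one-pixel-wide skeleton, and each skeleton
pixel becomes a graph vertex.  Vertices at 8-adjacent pixels are joined by
an edge weighted 1 (orthogonal step) or sqrt(2) (diagonal step), so that
shortest-path lengths in the graph approximate Euclidean arc length along
the root.  Degree-1 vertices are root tips (free ends); degree >= 3
vertices are branch points.

Vertices are coordinate tuples and nothing in this module assumes two
dimensions beyond the thinning step itself, so the graph machinery extends
to volumetric skeletons unchanged.
"""

from __future__ import annotations

import logging
import math
from typing import List, Tuple

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

from .segmentation import NoRootError, RootMask

__all__ = [
    "skeletonize",
    "build_graph",
    "detect_cycles",
    "break_cycles",
    "endpoints",
    "branch_points",
    "total_weight",
]

logger = logging.getLogger(__name__)

Vertex = Tuple[int, ...]

SQRT2 = math.sqrt(2.0)


def skeletonize(mask: RootMask) -> np.ndarray:
    """Thin the mask to a one-pixel-wide, topology-preserving skeleton.

    The output is a subset of the input foreground and keeps its
    connectivity (medial-axis thinning).
    """
    if not mask.bits.any():
        raise NoRootError("cannot skeletonize an empty mask")
    return _skimage_skeletonize(mask.bits)


def build_graph(skel: np.ndarray) -> nx.Graph:
    """Build the weighted pixel graph of a skeleton.

    One vertex per skeleton pixel; nearest-neighbor pixels are joined by
    an edge weighted 1 for orthogonal and sqrt(2) for diagonal adjacency.
    A diagonal edge is omitted when the two pixels already share an
    orthogonal skeleton neighbor: that diagonal duplicates the orthogonal
    two-step path and would otherwise mint a spurious triangle at every
    corner and junction (wrong degrees at branch points, phantom cycles).
    """
    skel = np.asarray(skel, dtype=bool)
    if not skel.any():
        raise NoRootError("empty skeleton")
    g = nx.Graph()
    ys, xs = np.nonzero(skel)
    coords = list(zip(ys.tolist(), xs.tolist()))
    pixel_set = set(coords)
    g.add_nodes_from(coords)
    for (y, x) in coords:
        # scan only the forward half of the 8-neighborhood; the reverse
        # half is covered when the neighbor itself is visited
        for dy, dx in ((0, 1), (1, -1), (1, 0), (1, 1)):
            nb = (y + dy, x + dx)
            if nb not in pixel_set:
                continue
            if dy != 0 and dx != 0:
                # shared orthogonal neighbors of the diagonal pair
                if (y, x + dx) in pixel_set or (y + dy, x) in pixel_set:
                    continue
                g.add_edge((y, x), nb, weight=SQRT2)
            else:
                g.add_edge((y, x), nb, weight=1.0)
    return g


def endpoints(g: nx.Graph) -> List[Vertex]:
    """Degree-1 vertices (root tips / free ends), in sorted order."""
    return sorted(v for v, d in g.degree() if d == 1)


def branch_points(g: nx.Graph) -> List[Vertex]:
    """Degree >= 3 vertices, in sorted order."""
    return sorted(v for v, d in g.degree() if d >= 3)


def total_weight(g: nx.Graph) -> float:
    """Sum of all edge weights — the skeleton's total path length."""
    return float(sum(w for _, _, w in g.edges(data="weight")))


def detect_cycles(g: nx.Graph) -> List[List[Tuple[Vertex, Vertex]]]:
    """Independent cycles of the graph as lists of edges; [] for trees.

    The number of cycles equals edges - vertices + components (circuit
    rank).  Loops arise when a lateral root curls back onto the primary.
    """
    cycles = []
    for cyc in nx.cycle_basis(g):
        edges = [(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))]
        cycles.append(edges)
    return cycles


def break_cycles(g: nx.Graph, start: Vertex | None = None) -> nx.Graph:
    """Return a copy of ``g`` with every cycle opened.

    From each cycle the edge whose midpoint is farthest (by graph distance)
    from ``start`` is deleted: a loop formed by a lateral re-touching the
    primary is opened at its far side, leaving the lateral attached where
    it emerges.  ``start`` defaults to the smallest (topmost, then
    leftmost) vertex, the kernel side of a downward-hanging root.  A
    warning is logged per removed edge.
    """
    h = g.copy()
    if h.number_of_nodes() == 0:
        return h
    if start is None:
        start = min(h.nodes)
    while True:
        basis = nx.cycle_basis(h)
        if not basis:
            return h
        dist = nx.single_source_dijkstra_path_length(h, start, weight="weight")
        cyc = basis[0]
        edges = [(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))]

        def midpoint_dist(e):
            u, v = e
            w = h[u][v]["weight"]
            return (dist.get(u, math.inf) + dist.get(v, math.inf) + w) / 2.0

        far = max(edges, key=midpoint_dist)
        h.remove_edge(*far)
        logger.warning("broke skeleton cycle by removing edge %s-%s", far[0], far[1])
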