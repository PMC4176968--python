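"""Primary/secondary root identification on the skeleton graph.

The primary root is the longest of the shortest paths between free ends:
Dijkstra distances are computed from each degree-1 vertex to every other,
and the maximizing endpoint pair defines the primary axis, oriented from
its topmost endpoint (the kernel side — seedling roots hang downward in a
scan).  Removing the primary vertices splits the remainder into connected
components, each a secondary (lateral) root.

Cycle-free input is assumed (see :func:`rhizograph.skeleton_graph.break_cycles`);
on a tree every secondary component attaches to the primary through exactly
one edge, which is credited to that component's length so that edge weights
partition exactly:  total weight = primary length + sum of secondary lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx

from .image_io import ValidationError
from .skeleton_graph import Vertex, endpoints

__all__ = [
    "RootPartition",
    "shortest_paths_from",
    "find_primary_root",
    "extract_secondary_roots",
    "partition_root",
]


@dataclass
class RootPartition:
    """The skeleton split into the primary axis and lateral components."""

    primary_path: List[Vertex]
    primary_length: float
    secondary_components: List[Set[Vertex]] = field(default_factory=list)
    secondary_lengths: List[float] = field(default_factory=list)
    #: per-component vertex on the primary path where the lateral attaches
    attachments: List[Vertex] = field(default_factory=list)
    #: junction debris: remainder components too short to be lateral roots
    #: (thinning residue inside a junction's thickness); their edge weight
    #: still counts toward the secondary total so lengths partition exactly
    debris_components: List[Set[Vertex]] = field(default_factory=list)
    debris_length: float = 0.0

    @property
    def secondary_total(self) -> float:
        return float(sum(self.secondary_lengths)) + self.debris_length


def shortest_paths_from(
    g: nx.Graph, source: Vertex
) -> Tuple[Dict[Vertex, float], Dict[Vertex, Vertex]]:
    """Single-source Dijkstra distances and predecessor map.

    Edge weights are the 1 / sqrt(2) pixel-step lengths, all nonnegative,
    so the distances are exact shortest-path lengths.
    """
    if source not in g:
        raise ValidationError(f"source vertex {source} not in graph")
    pred, dist = nx.dijkstra_predecessor_and_distance(g, source, weight="weight")
    predecessor = {v: ps[0] for v, ps in pred.items() if ps}
    return dist, predecessor


def _reconstruct(predecessor: Dict[Vertex, Vertex], source: Vertex, target: Vertex):
    path = [target]
    while path[-1] != source:
        path.append(predecessor[path[-1]])
    path.reverse()
    return path


def find_primary_root(
    g: nx.Graph, start: Optional[Vertex] = None
) -> Tuple[List[Vertex], float]:
    """The longest shortest path between free ends, and its length.

    Over all pairs of degree-1 endpoints the pair with maximal shortest-path
    distance is selected; ties are broken by the lexicographically smallest
    (y, x) of the pair's upper endpoint, then of the lower.  The returned
    path runs from the topmost of the two endpoints (kernel to tip).  A
    user-supplied ``start`` vertex pins one end instead: the path then runs
    from the endpoint nearest ``start`` to the farthest free end.
    """
    if g.number_of_nodes() == 1:
        v = next(iter(g.nodes))
        return [v], 0.0
    ends = endpoints(g)
    if start is not None:
        if start not in g:
            raise ValidationError(f"start vertex {start} not in graph")
        # pin the kernel end at the free end nearest the given coordinate
        kernel = min(ends, key=lambda e: (sum((a - b) ** 2 for a, b in zip(e, start)), e))
        dist, pred = shortest_paths_from(g, kernel)
        tip = max(
            (e for e in ends if e != kernel and e in dist),
            key=lambda e: (dist[e], tuple(-c for c in e)),
        )
        return _reconstruct(pred, kernel, tip), dist[tip]

    if len(ends) < 2:
        raise ValidationError("graph has fewer than two free ends")
    best: Tuple[float, Tuple[Vertex, Vertex]] | None = None
    paths: Dict[Vertex, Dict[Vertex, Vertex]] = {}
    for u in ends:
        dist, pred = shortest_paths_from(g, u)
        paths[u] = pred
        for v in ends:
            if v <= u or v not in dist:
                continue
            key = (dist[v], (u, v))  # u < v: u is the pair's upper endpoint
            if best is None or key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
                best = key
    if best is None:
        raise ValidationError("no endpoint pair is connected")
    length, (u, v) = best
    path = _reconstruct(paths[u], u, v)
    # orient kernel-first: topmost endpoint (smallest y, then x) leads
    if path[-1] < path[0]:
        path.reverse()
    return path, float(length)


#: Remainder components with total length at or below this many pixels are
#: junction debris, not lateral roots: one-pixel thinning leftovers inside
#: a junction's own thickness (a 2-vertex leftover is at most 1 + sqrt(2)
#: ~ 2.41 px long, well below any resolvable lateral).
JUNCTION_DEBRIS_PX = 2.5


def extract_secondary_roots(
    g: nx.Graph, primary: List[Vertex], debris_px: float = JUNCTION_DEBRIS_PX
) -> Tuple[List[Set[Vertex]], List[float], List[Vertex], List[Set[Vertex]], float]:
    """Connected components left after removing the primary path.

    Each component's length sums its internal edge weights plus the
    weight(s) of its attachment edge(s) back to the primary path, so on a
    tree the graph's total edge weight splits exactly between the primary
    and the secondaries.  Components no longer than ``debris_px`` are
    separated out as junction debris (skeletonization residue at branch
    junctions); their weight is returned so it still counts toward the
    secondary total.  Components are sorted by their smallest vertex for
    determinism, along with each component's attachment vertex on the
    primary.
    """
    primary_set = set(primary)
    rest = g.subgraph(v for v in g.nodes if v not in primary_set)
    components: List[Set[Vertex]] = []
    lengths: List[float] = []
    attach: List[Vertex] = []
    debris: List[Set[Vertex]] = []
    debris_length = 0.0
    for comp in sorted(nx.connected_components(rest), key=min):
        internal = sum(w for _, _, w in rest.subgraph(comp).edges(data="weight"))
        attach_edges = [
            (u, v, d["weight"])
            for u in comp
            for v, d in g[u].items()
            if v in primary_set
        ]
        length = float(internal + sum(w for _, _, w in attach_edges))
        if length <= debris_px:
            debris.append(set(comp))
            debris_length += length
            continue
        components.append(set(comp))
        lengths.append(length)
        attach.append(min((v for _, v, _ in attach_edges), default=min(comp)))
    return components, lengths, attach, debris, debris_length


def partition_root(g: nx.Graph, start: Optional[Vertex] = None) -> RootPartition:
    """Full primary/secondary decomposition of a (cycle-free) skeleton graph."""
    path, length = find_primary_root(g, start=start)
    comps, lengths, attach, debris, debris_len = extract_secondary_roots(g, path)
    return RootPartition(
        primary_path=path,
        primary_length=length,
        secondary_components=comps,
        secondary_lengths=lengths,
        attachments=attach,
        debris_components=debris,
        debris_length=debris_len,
    )
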