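import logging

import networkx as nx
import numpy as np
import pytest

from rhizograph.image_io import RasterImage
from rhizograph.segmentation import RootMask, BoundingBox

# cycle-break warnings are expected noise in bulk runs
logging.getLogger("rhizograph").setLevel(logging.ERROR)


def make_image(arr) -> RasterImage:
    return RasterImage(np.asarray(arr, dtype=float))


def mask_from_bits(bits) -> RootMask:
    bits = np.asarray(bits, dtype=bool)
    ys, xs = np.nonzero(bits)
    box = BoundingBox(int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1)
    return RootMask(bits, box)


def vertical_line_mask(n: int, height: int | None = None, x: int = 2) -> RootMask:
    h = height or (n + 4)
    bits = np.zeros((h, x + 3), dtype=bool)
    bits[2 : 2 + n, x] = True
    return mask_from_bits(bits)


@pytest.fixture
def y_graph() -> nx.Graph:
    """Unit-weight Y: stem of 5 edges, arms of 4 and 3 edges.

    Stem runs from (0,0) down to (5,0); arms fan out from the junction.
    """
    g = nx.Graph()
    stem = [(i, 0) for i in range(6)]
    arm_a = [(5 + i, -i) for i in range(1, 5)]   # 4 edges
    arm_b = [(5 + i, i) for i in range(1, 4)]    # 3 edges
    nx.add_path(g, stem, weight=1.0)
    nx.add_path(g, [stem[-1], *arm_a], weight=1.0)
    nx.add_path(g, [stem[-1], *arm_b], weight=1.0)
    return g


def brute_force_otsu(pixels: np.ndarray) -> int:
    """Exhaustive 256-candidate argmax of between-class variance."""
    hist, _ = np.histogram(pixels, bins=256, range=(0, 256))
    total = hist.sum()
    best_t, best_var = 0, -1.0
    levels = np.arange(256)
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def random_tree(rng: np.random.Generator, n: int) -> nx.Graph:
    """Random tree on distinct integer coordinates with 1/sqrt(2) weights."""
    import math

    coords = [(0, 0)]
    g = nx.Graph()
    g.add_node((0, 0))
    while len(coords) < n:
        parent = coords[rng.integers(len(coords))]
        c = (int(rng.integers(-20, 20)), int(rng.integers(-20, 20)))
        if c in g:
            continue
        w = 1.0 if rng.random() < 0.5 else math.sqrt(2)
        g.add_edge(parent, c, weight=w)
        coords.append(c)
    return g


def brute_force_shortest(g: nx.Graph, u, v) -> float:
    """Shortest path by enumerating every simple path (tiny graphs only)."""
    best = np.inf
    for path in nx.all_simple_paths(g, u, v):
        w = sum(g[a][b]["weight"] for a, b in zip(path[:-1], path[1:]))
        best = min(best, w)
    return best
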