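# Methods

## Pipeline model

A root scan is modeled as bright, thin, branching tissue on a dark
background. The analysis assumes (a) roots do not touch or cross each
other within a scan, (b) each root has one dominant primary axis that is
longer than any kernel-to-lateral-tip route, and (c) the scan's vertical
axis is the growth axis (roots hang downward, kernel at top). All
coordinates are 0-based (row y down, column x right); "depth" is the y
extent.

### Segmentation

The background intensity mode is estimated from the histogram of the
image's border frame (outer 5% of each dimension), where root tissue is
assumed absent, and subtracted with clamping at zero. Otsu's threshold is
computed on the 256-bin histogram of the normalized image as the integer
level maximizing between-class variance, smallest level winning ties;
foreground is strictly above the threshold. An `--invert` mode covers
dark-on-light scans (no normalization; foreground below the threshold).

Connected components use 8-connectivity throughout — thin diagonal root
segments fragment under 4-connectivity. The minimum component size is 100
pixels at a reference resolution of 4400×6200, scaled proportionally to
the image area but floored at 16 pixels (pure area scaling drops below
one pixel for small images, which would admit single noise speckles).
Components whose horizontal bounding intervals overlap are treated as
fragments of the same root and merged; the largest `max_roots` groups
survive, padded by 10 pixels and ordered left to right.

### Skeleton graph

The per-root mask is thinned to a one-pixel, topology-preserving
skeleton (Zhang–Suen, via scikit-image). Each skeleton pixel is a vertex;
orthogonal neighbors are joined with weight 1 and diagonal neighbors with
weight √2, so graph distance approximates Euclidean arc length. A
diagonal edge is omitted when its two pixels share an orthogonal skeleton
neighbor: such a diagonal duplicates the orthogonal two-step path, and
keeping it would create a spurious triangle at every corner and junction
(wrong tip degrees, phantom cycles). Vertices are plain coordinate
tuples and the graph machinery is dimension-agnostic; only thinning and
the raster-facing trait code are 2D.

The √2 weighting is a deliberate choice over unit weights: it changes
absolute lengths of diagonal runs by up to ~8% and is the variant that
matches Euclidean arc length. The residual bias of the 1/√2 chain metric
(it overstates strokes at intermediate angles by up to ~8%, ~2% in
practice for near-vertical roots) is visible in the length-recovery
numbers.

Cycles (a lateral curling back onto the axis) are opened before path
analysis: from each independent cycle the edge whose midpoint is farthest
by graph distance from the kernel-side vertex is deleted, with a logged
warning, until the graph is a tree. Breaking at the far side leaves the
lateral attached where it emerges.

### Primary / secondary partition

Dijkstra shortest paths are computed from every free end (degree-1
vertex) to every other; the pair with maximal distance defines the
primary root. Ties are broken lexicographically on the pair's upper then
lower endpoint; the path is oriented from its topmost endpoint, the
kernel side. A user-supplied `--start Y,X` pins the kernel end to the
free end nearest that coordinate instead.

Removing the primary path's vertices splits the remainder into connected
components — the lateral roots. Because the graph is a tree at this
point, each component attaches to the primary through exactly one edge;
that attachment edge is credited to the component's length, so edge
weights partition exactly and TRL = PRL + SEL is an identity rather than
an approximation. Components no longer than 2.5 px (the maximum length of
a two-vertex leftover, 1 + √2) are junction debris — thinning residue
inside a junction's own thickness — and are excluded from the lateral
list, though their weight still counts toward SEL so the identity
survives. This is bookkeeping of thinning residue, not skeleton spur
pruning; the skeleton itself is never edited.

### Traits

- Per-row counts treat the number of skeleton pixels in an image row as
  the number of roots crossing that scan line. MNR is the 84th percentile
  of these counts by the nearest-rank rule (the ceil(0.84·n)-th order
  statistic), MED their median, BSH = MNR/MED ≥ 1.
- TNR is the number of degree-1 skeleton tips — the only graph quantity
  that counts roots without further assumptions; users comparing against
  branch-count definitions should note TNR ≈ laterals + 2.
- The convex area CVA counts pixel centers inside or on the convex hull
  of the foreground pixel centers (Delaunay point-location); collinear
  degenerate foregrounds fall back to the pixel count, so a single line
  has SOL = 1.
- The perimeter PER counts foreground pixels with at least one background
  8-neighbor, the image border counting as background.
- Vertical-distribution traits split the root's bounding rows into three
  equal-depth bands. LED assigns each skeleton edge to a band by its
  midpoint row and reports the top band's share of total length. COM and
  the per-band CMT/CMM/CMB are foreground y-centroids normalized to the
  relevant extent, using pixel centers at y + 0.5 so a uniform bar scores
  exactly 0.5; COP/CPT/CPM/CPB use bounding-midpoints likewise. Bands
  need at least 3 rows of depth; below that the six band traits are NaN
  and flagged missing (the policy everywhere: missing values are NaN plus
  an entry in `TraitVector.missing`, never silent zeros).
- Primary-tube geometry reads a local radius at each primary-path vertex
  from the Euclidean distance transform of the mask, r = EDT − 0.5
  (pixel center to boundary), clamped at 0.5 px so a one-pixel line has
  diameter 1. The primary is treated as a solid of revolution: per
  segment of arc ds, volume π r² ds and lateral surface 2π r ds with r
  averaged over the segment's endpoints; DIA = 2·mean(r); SRL = TRL/VOL.

With calibration s px/cm, length traits divide by s, SUA by s², VOL by
s³, and SRL is recomputed, so SRL·VOL = TRL holds in either unit system.
Counts (PER, NWA, CVA, TNR, MNR, MED) and normalized ratios are reported
unchanged.

## Synthetic-data generator

The generator emulates the features the pipeline keys on: a bright
(intensity 220) branching structure on a dark background with one-sided
Gaussian noise (sd 6 by default), a roughly vertical primary axis of
known arc length (default 300 px), and laterals attached at separated
arc positions. Curves are mean-reverting heading walks (per-step jitter
sd = `curvature`, reversion 0.95 toward the growth direction — a crude
gravitropism that keeps the axis from drifting into a random walk),
rasterized with hard Bresenham strokes (default width 3 px, anti-aliasing
deliberately off so thresholding is unambiguous). Default laterals: 5 per
root, lengths 30–90 px, 25–75° from vertical, alternating sides,
attachment slots spread over 20–80% of the primary arc.

Two generator rules encode the dominant-primary assumption rather than
any species' biology: a lateral's length is capped at
0.7·min(frac, 1−frac)·L (frac = attachment position, L = primary length)
so the longest free-end-to-free-end path always runs down the primary;
and a rasterized-overlap audit flags roots where a lateral touches
another lateral or re-touches the primary away from its own attachment
(`GroundTruth.overlapping`) — lateral-count recovery is only guaranteed
for non-overlapping placements.

Ground truth is the generating polylines themselves; their arc lengths
are exact and independent of rasterization. What passing tests therefore
show is that the pipeline recovers the geometry of clean, separated,
known-width strokes; they do not exercise root hairs, touching or
crossing roots, uneven illumination, scanner vignetting, or tissue whose
width varies along the axis — all present in real scans to some degree.

## Numerical choices

- Otsu ties → smallest threshold; foreground is strictly greater than t.
- Equal-size component ties → the component first reached in raster
  order.
- Primary-pair ties → lexicographically smallest endpoint pair.
- Zero EDT radius on the path (off-mask vertex, only possible on
  malformed input) → clamped to 0.5 px with a warning.
- VOL = 0 (single-vertex path) → SRL is NaN and flagged missing.
- Batch CSV is written with fixed column order, `%.6f` floats and `\n`
  line endings, so identical inputs give byte-identical files.

## Problem sizes

The test and acceptance suites run the full pipeline on synthetic roots
of 180–380 px primary length (images roughly 350×300 px), 200 roots for
the identity/bounds sweep, 50 for length recovery, and 100 random
instances for each exhaustive-oracle comparison; one root takes ~75 ms
end to end, the whole acceptance script ~40 s.

## Known limitations

- Touching or crossing roots are explicitly out of scope; the x-interval
  merge rule for fragmented roots is a heuristic and can merge genuinely
  separate roots that overlap horizontally.
- TRL/PRL carry the chain-metric bias (~+2% on near-vertical roots).
- The 84th-percentile/row-count definition of MNR counts skeleton pixels,
  so a nearly horizontal root segment inflates its row's count.
- DIA/VOL/SUA assume a circular cross-section (solid of revolution).
- Root hairs are not resolved and multiple equal-order primaries (e.g.
  rice) are not supported; the partition always elects a single primary.
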