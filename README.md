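# rhizograph

Seedling root-system-architecture (RSA) phenotyping from flatbed scans.

Breeders and root biologists who phenotype seedling roots at scale — up to
three roots laid side by side per scan, hundreds of scans per experiment —
need root lengths, branching counts and shape descriptors extracted
automatically, without manual cropping or tracing. `rhizograph` turns each
scan into a weighted pixel graph and reads 27 architectural traits per
root straight off that graph, writing one spreadsheet row per root.

## Method

For each image:

1. **Threshold.** The background intensity mode (estimated over the image
   border) is subtracted, and Otsu's method on the 256-bin histogram picks
   the threshold `t` maximizing between-class variance; pixels brighter
   than `t` are root.
2. **Connected components.** The foreground is labeled with
   8-connectivity; small components are noise, and the surviving
   components are grouped into up to three left-to-right bounding boxes
   (one per root), merging fragments whose horizontal extents overlap.
3. **Skeletonize.** Each cropped root mask is thinned to a one-pixel
   medial skeleton.
4. **Pixel graph.** Every skeleton pixel becomes a vertex; nearest-
   neighbor pixels are joined by edges of weight 1 (orthogonal) or √2
   (diagonal), so shortest-path length approximates Euclidean arc length.
   Rare loops (a lateral curling back onto the axis) are opened before
   path analysis.
5. **Primary vs. lateral roots.** Dijkstra's algorithm computes shortest
   paths between all free ends (degree-1 vertices); the longest such
   shortest path is the primary root, oriented from its topmost (kernel)
   end. Removing the primary leaves connected components — the lateral
   (secondary) roots.
6. **Traits.** The mask, skeleton and partition yield 27 traits: total /
   primary / secondary root length (TRL = PRL + SEL holds exactly), depth,
   width, width:depth ratio, perimeter, convex area, network area,
   solidity, per-row root counts (84th-percentile maximum MNR, median MED,
   bushiness BSH = MNR/MED), tip count TNR, length distribution LED,
   vertical centroid descriptors (COM, COP and per-third variants
   CMT/CMM/CMB, CPT/CPM/CPB), and primary-tube geometry from the distance
   transform (diameter DIA, volume VOL, surface area SUA, specific root
   length SRL = TRL/VOL).

With a `--pixels-per-cm` calibration, lengths are reported in cm (areas
cm², volumes cm³); otherwise everything stays in pixel units and rows are
flagged `px`.

## Worked example

Generate a synthetic root with known geometry and analyze it in-process:

```python
import rhizograph as rg
from rhizograph.synthetic_roots import SyntheticRootSpec, generate_root

img, truth = generate_root(SyntheticRootSpec(seed=11))
root = rg.analyze_image(img)[0]
tv = root.traits
print(truth.primary_length_px, truth.total_length_px, truth.n_branches)
print(tv["TRL"], tv["PRL"], tv["SEL"], tv["BSH"])
```

The generated root has a 300.0 px primary axis, 5 laterals and a total
polyline length of 536.4 px. The pipeline measures (pixel units):

```
TRL  546.019   total root length, ~1.8% above the generative arc length
PRL  303.556   primary root length (truth 300.0)
SEL  242.463   cumulative lateral length; TRL = PRL + SEL exactly
DEP  303.000   depth;  WID 100.000;  WDR 0.330
TNR    7.000   skeleton tips (2 primary ends + 5 lateral tips)
MNR    3.000   84th-percentile per-row root count;  MED 1.000;  BSH 3.000
SOL    0.029   skeleton pixels / convex-hull area
LED    0.244   fraction of length in the top third of the root's depth
DIA    2.916   mean primary diameter;  VOL 2044.790;  SRL = TRL/VOL 0.267
```

Small overestimates of TRL are expected: the 1/√2 chain metric slightly
overstates the length of strokes at intermediate angles.

Batch use from the shell:

```bash
rhizograph synth --out demo/ --seed 3 --n-images 2   # synthetic fixtures
rhizograph run --input demo/ --output traits.csv --max-roots 3
```

`traits.csv` holds one row per detected root (`image`, `root_index`,
`status`, `units`, then the 27 traits in fixed order); `--xlsx` adds an
Excel copy, `--save-crops` writes per-root mask crops, and a `--config`
file can hold any flag as `key = value`.

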