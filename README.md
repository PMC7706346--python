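# rootcrown

Batch image analysis for **root crown phenotyping**: converting backlit
silhouette photographs of excavated crop root crowns into 27 quantitative
root phenes, for breeding, genetic mapping, and root-system-architecture
research.

Root crowns — the excavated top portion of a root system — are commonly
photographed against a bright backlight, which yields a near-binary image:
a near-white background with the root system as a dark silhouette.
`rootcrown` turns a folder of such images into a tidy CSV of measurements,
one row per image, fully automatically.

## What is measured and how

The pipeline per image:

1. **Segmentation** — a global grayscale threshold (default 128) separates
   the dark silhouette from the bright background.
2. **Edge smoothing** — each contour is simplified with the
   Ramer–Douglas–Peucker algorithm (distance threshold ε = 2 px) and
   re-rasterized, removing the 1–2 px edge jags that would otherwise spawn
   spurious lateral roots in the skeleton.
3. **Distance transform** — an exact Euclidean distance transform (EDT)
   d(p) = min distance from foreground pixel p to background.
4. **Medial axis** — ridge pixels of the EDT (loci equidistant from at
   least two stretches of background) are detected from the divergence of
   the EDT's nearest-background (feature) points and repaired into a
   connected, single-pixel-wide skeleton by distance-ordered,
   connectivity-preserving thinning.  Each skeleton pixel carries the EDT
   value as a local root radius r, so the local diameter is 2r.
5. **Topology** — end points (degree 1) and branch points (degree ≥ 3) of
   the skeleton graph split it into root segments; end points are counted
   as root tips.
6. **Traits** — 27 phenes: median/maximum number of roots (per-row
   background→foreground transition counts), number of root tips, total
   root length (Σ chain steps: 1 orthogonal, √2 diagonal), depth, maximum
   width and their ratio, network area, convex area, solidity =
   network/convex, perimeter, average/median/maximum diameter,
   volume = Σ πr², surface area = Σ 2πr, lower root area, hole count and
   average hole size, average root orientation (per-pixel PCA slope in a
   40×40 window, folded to [0°, 90°] from horizontal), three diameter
   frequency bins, three angle frequency bins (0–30°, 30–60°, 60–90°),
   and per-image computational time.

With a pixels-per-millimeter scale, lengths, areas and volumes are
reported in mm, mm² and mm³.

A synthetic silhouette generator (`rootcrown.synthetic`) renders wires of
known physical diameter and branching crowns with exact ground truth
(length, tips, angles, widths), and is the basis of the validation suite.

## Worked example

```python
import imageio.v3 as iio
from rootcrown import AnalyzerConfig, make_synthetic_crown, run_batch

# three synthetic crowns stand in for a folder of camera images
for s in range(3):
    img, truth = make_synthetic_crown(24, "mixed", seed=s)
    iio.imwrite(f"crowns/crown_{s}.png", img)

cfg = AnalyzerConfig(pixels_per_mm=12.7787)   # field imaging resolution
result = run_batch("crowns", "out", cfg)
fs = result.rows[0]
print(fs.number_of_root_tips, fs.total_root_length, fs.depth,
      fs.median_diameter, fs.solidity, fs.average_root_orientation)
```

prints (units mm, since a scale was given):

```
26.0 333.78 48.60 0.443 0.137 46.84
```

i.e. the first crown has 26 root tips, 334 mm of visible root length, a
48.6 mm deep silhouette, a median root diameter of 0.44 mm, occupies 14%
of its convex hull, and its roots run on average at 47° from the
horizontal.  `out/features.csv` holds one such row per image plus a
`metadata.csv` recording every analysis option.

The same analysis from a shell:

```sh
rootcrown --input-dir crowns --output-dir out --pixels-per-mm 12.7787 \
          --save-segmented --save-feature-image
```

## Layout

- `src/rootcrown/config.py` — options, the 27-field feature record, unit
  conversion, CSV serialization
- `src/rootcrown/segmentation.py` — thresholding, contour tracing, RDP
  smoothing
- `src/rootcrown/skeleton.py` — EDT, medial axis, connected thinning
- `src/rootcrown/topology.py` — branch/end points, root segments
- `src/rootcrown/features.py` — the 27 phenes
- `src/rootcrown/synthetic.py` — ground-truth silhouette generator
- `src/rootcrown/batch.py`, `cli.py` — folder driver, renderers, CLI
- `docs/methods.md` — models, parameters, numerical choices, limitations
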