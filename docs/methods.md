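# Methods

## Imaging model and coordinate conventions

The analyzer assumes backlit silhouette imaging: a bright, even
background (intensity near 245) and a dark, connected root structure
(near 15), so that a single global threshold segments the image with
minimal loss.  Grayscale or pre-thresholded images from other rigs work
as long as foreground is darker than background (or
`invert_foreground` is set).

Coordinates are 0-based `(row, col)`; rows increase downward, so the row
axis is the depth axis of the hanging root crown and the column axis is
its width.  Angles are measured in degrees from the horizontal and
folded into [0°, 90°]; direction along a root is not distinguished.
Foreground connectivity is 8, background connectivity 4 (the standard
dual pair for binary images).

## Edge smoothing

Thresholded silhouettes carry 1–2 px boundary jags from sensor noise and
sampling.  Each contour (outer boundaries and enclosed holes) is traced
at pixel resolution (Moore-neighbor tracing; contours touching the frame
close along it), simplified with Ramer–Douglas–Peucker, and
re-rasterized as a filled polygon, holes re-subtracted.  The RDP
distance is the clamped point-to-segment distance; closed rings are
anchored at two extremal points (farthest from the centroid, then
farthest from the first anchor), so anchors land on true corners rather
than on jags.

* `rdp_epsilon_px` (default **2 px**): matches the amplitude of the edge
  jags at the imaging rig's working resolution.  Smaller values readmit
  spurious lateral roots; larger values oversimplify real topology.

Smoothing leaves the segmentation nearly unchanged at field resolution:
on synthetic crowns with root widths of 14–24 px (a ~1.4 mm median root
diameter at ~13 px/mm) the Jaccard overlap of raw and smoothed masks
exceeds 0.95.  For much thinner strokes (3–7 px) the ±0.4 px
re-rasterization wobble is a larger *fraction* of the root, and the
overlap drops toward ~0.87 — the traits themselves are unaffected, since
they are computed from the smoothed mask consistently.

## Distance transform and medial axis

The Euclidean distance transform is exact (scipy's EDT on a
zero-padded frame, so the image border counts as background).  The
medial axis — loci equidistant from at least two background points — is
detected from the EDT's *feature transform*: adjacent foreground pixels
whose nearest-background points lie farther apart than
`RIDGE_DIVERGENCE_PX = 2.4` px **and** subtend at least
`RIDGE_MIN_ANGLE_DEG = 150°` at the pair's midpoint straddle the axis;
the pixel with the larger distance value is kept (ties keep both).
Non-strict local maxima of the EDT with radius ≤ 1.5 px are added so
that 1–2 px wide lines, which cannot show feature divergence, survive.

Rationale for the two constants:

* 2.4 px sits below the narrowest resolvable root width (3 px, whose
  across-axis feature divergence is 3 px) and above the 1–2 px feature
  drift along smoothed straight edges.
* 150° encodes "the two background witnesses lie on opposite sides".
  It suppresses the short medial branches that would otherwise run into
  the wedge-shaped notches at branch junctions (for wedges narrower
  than ~30°) and the discrete-EDT noise of rounded tips, while leaving
  3 px strokes (which subtend ~180°) intact.  A straight wire rendered
  at any angle yields exactly two skeleton end points under these
  settings.

The ridge set is then repaired into the final skeleton: ridge end points
are extended along steepest-ascent paths of the EDT (deterministic
N…NW tie-break, capped at 4× the local radius) so collinear fragments
merge, and the mask is eroded down to the ridge set by a
distance-ordered, connectivity-preserving thinning.  A pixel is removed
only if it is *simple* (removal preserves local 8-foreground /
4-background topology, decided by a 256-entry lookup table); non-ridge
pixels are removed in ascending EDT order with no end-point protection,
so unanchored protrusions erode away completely and the surviving
non-ridge pixels are exactly the bridges connectivity requires; finally
ridge plateaus are reduced to single-pixel width (end points protected).
The result is 8-connected per mask component, single-pixel wide, and
carries the EDT value of each pixel as its radius.

No pruning of short skeletal segments is performed; short branches that
survive the ridge criteria are reported as-is.

Diameters are 2·d(p) with no pixel-center correction, which biases
odd-width bars by about +1 px; the wire-calibration regression absorbs
this as an intercept and its slope stays within 5% of unity.

## Topology

Skeleton adjacency is 8-connected with redundant diagonals removed (a
diagonal neighbor is ignored when an orthogonal neighbor adjacent to
both exists), so staircases are paths, not triangle meshes.  Degree-1
pixels are end points (= root tips, including the stem's attachment at
the top border), degree ≥ 3 pixels are branch points.  Root segments run
terminal-to-terminal with no interior branch point; a branch point of
degree d terminates exactly d segments, end points exactly one, and pure
cycles become a single closed segment anchored at their scan-order-first
pixel.  Traversal order is fixed (scan-order start, N, NE, E, SE, S, SW,
W, NW neighbor order), so output is byte-for-byte reproducible.  The
union of segments is verified to reconstruct the skeleton exactly on
every analysis.

## Traits

* **Root count profile**: per-row background→foreground transitions over
  the rows spanning the foreground's vertical extent (not the full
  frame, which would drag the median toward 0 for small crowns); interior
  rows with zero transitions are included.  A foreground pixel in column
  0 counts as a transition.
* **Convex area** is the shoelace area of the hull of foreground pixel
  centers.  Solidity = network / convex is clamped at 1: the hull of
  pixel centers slightly underestimates pixel area, so near-solid blobs
  would otherwise nominally exceed 1.  Real crowns sit far from the
  clamp (solidity ~0.2–0.3).
* **Perimeter** and **total root length** are chain lengths: 1 per
  orthogonal, √2 per diagonal step.  Digital straight lines at angles
  near 22.5° overestimate true Euclidean length by up to ~8% — an
  intrinsic property of chain-code length on which the recovery results
  below should be read.
* **Orientation**: for each skeleton pixel, all skeleton pixels in the
  centered `angle_window_px` × `angle_window_px` box (default **40**,
  large enough to ignore small direction wiggles) enter a 2×2 coordinate
  covariance; the principal eigenvector's slope, folded to [0°, 90°], is
  the pixel's angle.  Windows are not restricted to the pixel's own
  segment, so junction neighborhoods mix directions; windows with < 2
  pixels or an isotropic covariance fall back to the chord angle of the
  pixel's segment.  Histogram bins are lower-inclusive ([0, 30), [30,
  60), [60, 90]), and the same convention holds for the diameter bins
  (`diameter_bin_edges`, default 2 and 5 mm when a scale is given —
  arbitrary user-facing defaults, recorded in the metadata CSV).
* **computational_time** is wall-clock seconds per image; it is excluded
  from unit conversion and from all correctness guarantees.

Unit conversion divides lengths by s = pixels/mm, areas by s², volume by
s³.  `surface_area` (Σ 2πr over unit-length skeleton steps) and
`volume` (Σ πr²) are treated as area- and volume-like respectively,
keeping the quantities dimensionally consistent.

## Synthetic silhouettes

The generator emulates the imaging rig's output: capsule strokes
(segments with round caps) rendered by 4× supersampled coverage and
box-downsampling onto a 245/15 background/foreground intensity pair, so
edges carry mild anti-aliased jaggedness and genuinely exercise the
smoothing stage.  Edge placement is quantized to ~¼ px per side by the
supersampling.

* **Wires**: one straight capsule of exact physical diameter at a given
  px/mm scale and angle; sub-pixel diameters are rejected.
* **Crowns**: a main axis entering from the top border (default length
  480 px on a 640×720 canvas) with n laterals (width 3–7 px, length
  110–200 px) attached at evenly spaced points, alternating sides.
  Same-side laterals are ordered steeper-downward so strokes do not
  cross, and each tip is kept ≥ 14 px from other tips and clear of other
  strokes — the preconditions under which every drawn lateral yields a
  distinct silhouette tip.  Angle regimes: `shallow` (8–28°), `steep`
  (62–85°), `mixed` (8–85°), or a fixed numeric angle applied to every
  segment (the axis mirrored against the laterals) for single-angle
  recovery experiments.  The truth record (total polyline length, tip
  count = laterals + bottom tip + top attachment, per-segment angles and
  widths, bounding box) is exact and reproducible from the seed.

What the generator does **not** emulate: curved roots, root hairs,
overlapping/occluding 3-D structure projected to 2-D, soil debris,
uneven illumination, and sensor blur.  Passing recovery tests therefore
demonstrate correctness of the measurement chain on clean geometry, not
robustness to field imaging artifacts.

## Validation protocol and problem sizes

The test suite checks, among others: exact equivalence of the distance
transform with a brute-force nearest-background search on 40×40 masks;
hole counts against a flood-fill oracle; convex areas against a
monotone-chain + shoelace oracle; and, on 50 seeded mixed-regime crowns
(24 laterals each), recovery of tip count within ±10%, depth and width
within ±2 px, total length within ±5%, and median diameter within
±1.5 px of truth, plus ≥ 90% correct angle-bin assignment on
single-angle crowns at 15°/45°/75°.  `scripts/acceptance.py` re-enacts
the wire calibration (ten wires, 0.20–2.57 mm at 13.63866 px/mm) and
reports the diameter regression R².  These sizes keep the whole suite
within a few minutes on one CPU while leaving the statistics stable
across seeds.

## Known limitations

* Tips are end-point counts; no distinction between axial and lateral
  roots, and no branching-hierarchy inference.
* Chain-code length bias (above) makes single-angle length recovery at
  ~22° systematically high by a few percent.
* The medial-axis radius carries a ~+1 px diameter bias on odd-width
  structures (no pixel-center correction).
* Degree-4 skeleton crossings are handled by the same rule as degree-3
  (a degree-d branch point terminates d segments).
* Orientation windows mix directions near junctions; with well-separated
  branches the effect is confined to ~window-sized neighborhoods.
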