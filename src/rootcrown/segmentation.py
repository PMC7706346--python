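"""Silhouette segmentation: thresholding, contour tracing and edge smoothing.

Backlit imaging yields near-binary grayscale images, so segmentation is a
single global threshold.  Raw silhouette edges carry single-pixel jags
that spawn spurious lateral roots during skeletonization; each contour is
therefore simplified with the Ramer-Douglas-Peucker (RDP) algorithm and
re-rasterized as a filled polygon, which straightens edges while leaving
the overall shape essentially unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

# 8-neighborhood in clockwise order starting north, in (row, col) offsets.
_CLOCKWISE8 = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)
)

_STRUCT8 = np.ones((3, 3), bool)


@dataclass(frozen=True)
class Contour:
    """Closed ring of boundary pixels of one foreground region.

    ``points`` is an (n, 2) integer array of (row, col) pixel
    coordinates, consecutive points 8-adjacent, first adjacent to last.
    ``kind`` is ``"outer"`` for the external boundary of a component and
    ``"hole"`` for the foreground ring surrounding an enclosed
    background region.
    """

    points: np.ndarray
    kind: str

    def __len__(self) -> int:
        return len(self.points)


def load_gray_image(path) -> np.ndarray:
    """Read an image file as an 8-bit grayscale array.

    Color images are averaged across channels; 16-bit inputs are
    right-shifted to 8 bits.
    """
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    if img.dtype == np.uint16:
        img = (img >> 8).astype(np.uint8)
    return np.clip(np.asarray(img, dtype=float), 0, 255).astype(np.uint8)


def threshold_image(
    img: np.ndarray, level: int, invert_foreground: bool = False
) -> np.ndarray:
    """Binary foreground mask: pixels darker than ``level`` (a dark root
    against the bright backlight), or >= ``level`` when inverted."""
    img = np.asarray(img)
    if invert_foreground:
        return img >= level
    return img < level


def _trace_moore(mask: np.ndarray, start: tuple[int, int],
                 backtrack: tuple[int, int]) -> np.ndarray:
    """Moore-neighbor boundary trace from ``start`` with initial
    backtrack position ``backtrack`` (a non-foreground neighbor).

    Walks the boundary clockwise in the row-down frame, terminating with
    Jacob's criterion (the start pixel re-entered from the start
    direction).  Returns the closed ring of boundary pixels (without the
    repeated first point).
    """
    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(mask[r, c])

    # Index of backtrack in the clockwise ring around start.
    b_off = (backtrack[0] - start[0], backtrack[1] - start[1])
    b_idx = _CLOCKWISE8.index(b_off)

    ring = [start]
    p, bidx = start, b_idx
    first_move: tuple[int, int] | None = None
    while True:
        nxt = None
        for k in range(1, 9):
            i = (bidx + k) % 8
            dr, dc = _CLOCKWISE8[i]
            q = (p[0] + dr, p[1] + dc)
            if fg(*q):
                nxt = q
                # new backtrack = position checked just before q
                pdr, pdc = _CLOCKWISE8[(i - 1) % 8]
                new_b = (p[0] + pdr, p[1] + pdc)
                break
        if nxt is None:  # isolated pixel
            break
        move = (nxt[0] - p[0], nxt[1] - p[1])
        if p == start:
            if first_move is None:
                first_move = move
            elif move == first_move:
                break  # closed the loop entering the same way
        bidx = _CLOCKWISE8.index((new_b[0] - nxt[0], new_b[1] - nxt[1]))
        p = nxt
        if p == start and first_move is not None:
            # check on next iteration whether we leave the same way;
            # but also guard against infinite loops on degenerate shapes
            if len(ring) > 4 * (h * w):
                break
        ring.append(p)
        if len(ring) > 8 * h * w:  # safety net, never hit on valid masks
            break
    # Drop the duplicated closing start pixel if present.
    while len(ring) > 1 and ring[-1] == start:
        ring.pop()
    return np.array(ring, dtype=np.intp)


def _outer_contour(comp: np.ndarray) -> np.ndarray:
    """Outer boundary ring of a single-component mask."""
    rows, cols = np.nonzero(comp)
    i = np.lexsort((cols, rows))[0]
    start = (int(rows[i]), int(cols[i]))
    # Topmost-leftmost pixel: the pixel above is background.
    return _trace_moore(comp, start, (start[0] - 1, start[1]))


def extract_contours(mask: np.ndarray) -> list[Contour]:
    """Trace all boundaries of a binary mask.

    One outer contour per 8-connected foreground component, plus one
    hole contour (traced over the surrounding foreground pixels) per
    enclosed background region.  Contours touching the image frame are
    closed along the frame.
    """
    mask = np.asarray(mask, bool)
    out: list[Contour] = []
    if not mask.any():
        return out
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    holes, hole_slices = _hole_regions(mask)
    for lab in range(1, n + 1):
        comp = labels == lab
        out.append(Contour(points=_outer_contour(comp), kind="outer"))
    for hid, sl in enumerate(hole_slices, start=1):
        hole = holes[sl] == hid
        # Topmost-leftmost hole pixel; the pixel above it is foreground.
        hr, hc = np.nonzero(hole)
        i = np.lexsort((hc, hr))[0]
        r0 = int(hr[i]) + sl[0].start
        c0 = int(hc[i]) + sl[1].start
        start = (r0 - 1, c0)
        ring = _trace_moore(mask, start, (r0, c0))
        out.append(Contour(points=ring, kind="hole"))
    return out


def _hole_regions(mask: np.ndarray):
    """Label 4-connected background regions not touching the frame."""
    bg = ~mask
    labels, n = ndimage.label(bg)  # 4-connectivity default
    if n == 0:
        return labels, []
    border = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border = set(int(b) for b in border if b != 0)
    keep = [lab for lab in range(1, n + 1) if lab not in border]
    relabel = np.zeros(n + 1, dtype=np.int32)
    for new, lab in enumerate(keep, start=1):
        relabel[lab] = new
    holes = relabel[labels]
    slices = ndimage.find_objects(holes)
    return holes, [s for s in slices if s is not None]


def _point_segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray
                            ) -> np.ndarray:
    """Euclidean distance from each point to the segment a-b (clamped)."""
    ab = (b - a).astype(float)
    ap = pts.astype(float) - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.hypot(ap[:, 0], ap[:, 1])
    t = np.clip((ap @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = pts - proj
    return np.hypot(d[:, 0], d[:, 1])


def rdp(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Ramer-Douglas-Peucker simplification of an open polyline.

    Recursively keeps the point farthest from the chord whenever that
    distance exceeds ``epsilon``; every input point ends up within
    ``epsilon`` of the returned polyline.  Vertices are a subsequence of
    the input points.
    """
    pts = np.asarray(points)
    if len(pts) <= 2:
        return pts.copy()
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        d = _point_segment_distance(pts[i + 1:j], pts[i], pts[j])
        k = int(np.argmax(d))
        if d[k] > epsilon:
            m = i + 1 + k
            keep[m] = True
            stack.append((i, m))
            stack.append((m, j))
    return pts[keep]


def simplify_contour(contour: Contour | np.ndarray, epsilon_px: float
                     ) -> np.ndarray:
    """RDP-simplify a closed contour ring.

    The ring is split at its start pixel and at the pixel farthest from
    it, each half simplified independently, and the halves rejoined, so
    no artificial chord spans the whole ring.
    """
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour)
    if len(pts) <= 3:
        return pts.copy()
    # Anchor the ring at two extremal points (farthest from the
    # centroid, then farthest from that): anchors land on true corners
    # rather than on edge jags, which would otherwise be pinned.
    centroid = pts.mean(axis=0)
    a = int(np.argmax(((pts - centroid) ** 2).sum(axis=1)))
    pts = np.roll(pts, -a, axis=0)
    d = np.hypot(*(pts.astype(float) - pts[0]).T)
    split = int(np.argmax(d))
    if split == 0:
        return pts[:1].copy()
    first = rdp(pts[: split + 1], epsilon_px)
    second = rdp(np.vstack([pts[split:], pts[:1]]), epsilon_px)
    return np.vstack([first[:-1], second[:-1]])


def _rasterize_ring(poly: np.ndarray, shape: tuple[int, int],
                    fill: bool = True) -> np.ndarray:
    """Filled polygon plus its drawn boundary, on a canvas of ``shape``."""
    canvas = np.zeros(shape, dtype=bool)
    if len(poly) == 0:
        return canvas
    if len(poly) == 1:
        canvas[poly[0, 0], poly[0, 1]] = True
        return canvas
    if fill and len(poly) >= 3:
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
        canvas[rr, cc] = True
    closed = np.vstack([poly, poly[:1]])
    for a, b in zip(closed[:-1], closed[1:]):
        rr, cc = draw_line(int(a[0]), int(a[1]), int(b[0]), int(b[1]))
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[ok], cc[ok]] = True
    return canvas


def smooth_mask(mask: np.ndarray, epsilon_px: float) -> np.ndarray:
    """Straighten silhouette edges by RDP-simplifying every contour and
    re-rasterizing the simplified polygons.

    Outer boundaries are filled; enclosed background regions (holes) are
    simplified the same way and re-subtracted.  Pixels may be both added
    and removed relative to the input; components too small to carry a
    polygon are kept unchanged.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    out = np.zeros_like(mask)
    for lab in range(1, n + 1):
        comp = labels == lab
        ring = _outer_contour(comp)
        if len(ring) < 4:
            out |= comp
            continue
        poly = simplify_contour(Contour(ring, "outer"), epsilon_px)
        filled = _rasterize_ring(poly, mask.shape)
        if filled.sum() < 1:
            out |= comp
            continue
        out |= filled
    # Subtract smoothed holes, traced over the hole's own background pixels.
    holes, hole_slices = _hole_regions(mask)
    for hid, sl in enumerate(hole_slices, start=1):
        hole_full = holes == hid
        hr, hc = np.nonzero(hole_full)
        if len(hr) <= 2:
            out[hr, hc] = False
            continue
        i = np.lexsort((hc, hr))[0]
        start = (int(hr[i]), int(hc[i]))
        ring = _trace_moore(hole_full, start, (start[0] - 1, start[1]))
        if len(ring) < 4:
            out[hr, hc] = False
            continue
        poly = simplify_contour(Contour(ring, "hole"), epsilon_px)
        interior = _rasterize_ring(poly, mask.shape)
        if interior.any():
            out &= ~interior
        else:
            out[hr, hc] = False
    return out


def perimeter_length(contours: list[Contour]) -> float:
    """Total Euclidean chain length of all contours: each step between
    consecutive boundary pixels counts 1 (orthogonal) or sqrt(2)
    (diagonal); single-pixel contours contribute 0."""
    total = 0.0
    for c in contours:
        pts = c.points
        if len(pts) < 2:
            continue
        closed = np.vstack([pts, pts[:1]])
        steps = np.abs(np.diff(closed, axis=0))
        total += float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    return total
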