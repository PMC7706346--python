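"""Medial-axis skeletonization driven by the Euclidean distance transform.

The skeleton is built in three passes:

1. an exact Euclidean distance transform (EDT) of the smoothed mask,
   with the image frame counting as background;
2. ridge detection on the EDT -- pixels equidistant from two distinct
   stretches of background, found where the nearest-background (feature)
   points of adjacent pixels diverge, plus local maxima of the EDT for
   structures too thin to show divergence;
3. repair and thinning -- ridge end points are extended along the
   steepest-ascent direction of the EDT, then the mask is eroded down
   to the ridge set by a distance-ordered, connectivity-preserving
   (simple-point) thinning: unanchored pixels survive only where they
   are needed to keep the skeleton connected, and anchored plateaus are
   finally reduced to single-pixel width.

Each skeleton pixel carries the EDT value at that pixel as its radius
estimate; twice the radius is the local root diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_STRUCT8 = np.ones((3, 3), bool)

# Fixed neighbor order N, NE, E, SE, S, SW, W, NW used for all
# deterministic tie-breaking walks.
NEIGHBOR_ORDER = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)
)

#: Feature-point divergence (px) above which two adjacent pixels are taken
#: to straddle the medial axis.  Below the narrowest resolvable root
#: width (3 px), above the 1-2 px feature drift along smoothed edges.
RIDGE_DIVERGENCE_PX = 2.4

#: Minimum angle (degrees) subtended at the pixel pair's midpoint by the
#: two feature points.  Pixels straddling the axis see their features on
#: opposite sides (~180 deg); staircase noise on oblique edges sees them
#: on the same side at a shallow angle.
RIDGE_MIN_ANGLE_DEG = 150.0

#: EDT value below which a non-strict local maximum is accepted as ridge
#: (1-2 px wide lines cannot show feature divergence).
THIN_STRUCTURE_RADIUS = 1.5


@dataclass
class Skeleton:
    """Single-pixel-wide medial axis with per-pixel radii.

    ``mask`` is a boolean image marking skeleton pixels; ``radius``
    holds the EDT value at skeleton pixels and 0 elsewhere.
    """

    mask: np.ndarray
    radius: np.ndarray

    @property
    def pixels(self) -> np.ndarray:
        """(n, 2) array of (row, col) skeleton coordinates in scan order."""
        return np.argwhere(self.mask)

    def radii(self) -> np.ndarray:
        """Radii of skeleton pixels, in scan order."""
        return self.radius[self.mask]

    def __len__(self) -> int:
        return int(self.mask.sum())


def distance_transform(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance of each foreground pixel to the nearest
    background pixel center; the frame beyond the image is background."""
    mask = np.asarray(mask, bool)
    padded = np.pad(mask, 1, constant_values=False)
    d = ndimage.distance_transform_edt(padded)
    return d[1:-1, 1:-1]


def _shifted(d: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """d sampled at (r+dr, c+dc), 0 outside the frame."""
    out = np.zeros_like(d)
    h, w = d.shape
    rs = slice(max(0, -dr), min(h, h - dr))
    cs = slice(max(0, -dc), min(w, w - dc))
    rs2 = slice(max(0, dr), min(h, h + dr))
    cs2 = slice(max(0, dc), min(w, w + dc))
    out[rs, cs] = d[rs2, cs2]
    return out


def extract_medial_axis(dmap: np.ndarray, mask: np.ndarray) -> Skeleton:
    """Ridge pixels of the distance map.

    The medial axis consists of loci equidistant from at least two
    background points.  That is tested on the EDT's feature transform:
    where the nearest-background points of two adjacent foreground
    pixels lie farther apart than ``RIDGE_DIVERGENCE_PX`` *and* on
    opposite sides of the pair (subtending at least
    ``RIDGE_MIN_ANGLE_DEG`` at the pair's midpoint), the pixel with the
    larger distance value is a ridge pixel (ties keep both).  Non-strict
    local maxima of the EDT with radius <= ``THIN_STRUCTURE_RADIUS``
    are kept as well, so 1-2 px wide lines survive.
    """
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    ridge = np.zeros_like(mask)
    if not mask.any():
        return Skeleton(mask=ridge, radius=np.zeros_like(dmap))

    padded = np.pad(mask, 1, constant_values=False)
    _, inds = ndimage.distance_transform_edt(padded, return_indices=True)
    fr = inds[0][1:-1, 1:-1].astype(np.float64)
    fc = inds[1][1:-1, 1:-1].astype(np.float64)

    tau2 = RIDGE_DIVERGENCE_PX ** 2
    cos_min = np.cos(np.radians(RIDGE_MIN_ANGLE_DEG))
    # padded-frame coordinates of each pixel
    rg = np.arange(1, h + 1, dtype=np.float64)[:, None] * np.ones((1, w))
    cg = np.ones((h, 1)) * np.arange(1, w + 1, dtype=np.float64)[None, :]
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        pr = slice(max(0, -dr), min(h, h - dr))
        pc = slice(max(0, -dc), min(w, w - dc))
        qr = slice(max(0, dr), min(h, h + dr))
        qc = slice(max(0, dc), min(w, w + dc))
        both = mask[pr, pc] & mask[qr, qc]
        dfr = fr[pr, pc] - fr[qr, qc]
        dfc = fc[pr, pc] - fc[qr, qc]
        div = (dfr ** 2 + dfc ** 2) > tau2
        # angle subtended by the two features at the pair midpoint
        mr = 0.5 * (rg[pr, pc] + rg[qr, qc])
        mc = 0.5 * (cg[pr, pc] + cg[qr, qc])
        ur, uc = fr[pr, pc] - mr, fc[pr, pc] - mc
        vr, vc = fr[qr, qc] - mr, fc[qr, qc] - mc
        dot = ur * vr + uc * vc
        norm = np.sqrt((ur ** 2 + uc ** 2) * (vr ** 2 + vc ** 2))
        wide = dot <= cos_min * np.maximum(norm, 1e-12)
        hit = both & div & wide
        p_ge = dmap[pr, pc] >= dmap[qr, qc]
        q_ge = dmap[qr, qc] >= dmap[pr, pc]
        ridge[pr, pc] |= hit & p_ge
        ridge[qr, qc] |= hit & q_ge

    # thin structures: non-strict local maxima at small radii
    local_max = mask & (dmap <= THIN_STRUCTURE_RADIUS)
    for dr, dc in NEIGHBOR_ORDER:
        local_max &= dmap >= _shifted(dmap, dr, dc)
    ridge |= local_max
    ridge &= mask
    return Skeleton(mask=ridge, radius=np.where(ridge, dmap, 0.0))


def _build_simple_lut() -> np.ndarray:
    """256-entry table: is the center of a 3x3 patch an (8,4)-simple
    pixel for each configuration of its 8 neighbors?

    Simple means removal preserves local topology: exactly one
    8-connected foreground component among the neighbors and exactly one
    4-connected background component touching a 4-neighbor.
    """
    offsets = NEIGHBOR_ORDER
    lut = np.zeros(256, dtype=bool)
    for pat in range(256):
        cells = np.zeros((3, 3), bool)
        for i, (dr, dc) in enumerate(offsets):
            if pat >> i & 1:
                cells[dr + 1, dc + 1] = True
        fg = cells.copy()
        fg[1, 1] = False
        n_fg = ndimage.label(fg, structure=_STRUCT8)[1]
        bg = ~cells
        bg[1, 1] = False
        lab_bg, _ = ndimage.label(bg)  # 4-connectivity
        touching = {lab_bg[0, 1], lab_bg[1, 0], lab_bg[1, 2], lab_bg[2, 1]}
        n_bg = len(touching - {0})
        lut[pat] = (n_fg == 1) and (n_bg == 1)
    return lut


_SIMPLE_LUT = _build_simple_lut()
_PATTERN_KERNEL = np.zeros((3, 3), dtype=np.int32)
for _i, (_dr, _dc) in enumerate(NEIGHBOR_ORDER):
    _PATTERN_KERNEL[_dr + 1, _dc + 1] = 1 << _i
del _i, _dr, _dc


def _patterns(sk: np.ndarray) -> np.ndarray:
    """8-bit neighborhood code of every pixel (frame = background)."""
    return ndimage.convolve(sk.astype(np.int32), _PATTERN_KERNEL[::-1, ::-1],
                            mode="constant")


def _pattern_at(sk: np.ndarray, r: int, c: int) -> int:
    pat = 0
    h, w = sk.shape
    for i, (dr, dc) in enumerate(NEIGHBOR_ORDER):
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and sk[rr, cc]:
            pat |= 1 << i
    return pat


def _neighbor_count(sk: np.ndarray) -> np.ndarray:
    return ndimage.convolve(sk.astype(np.uint8), _STRUCT8.astype(np.uint8),
                            mode="constant") - sk.astype(np.uint8)


def _end_points(sk: np.ndarray) -> np.ndarray:
    """Skeleton pixels with at most one 8-neighbor, as (n, 2) coords."""
    cnt = _neighbor_count(sk)
    return np.argwhere(sk & (cnt <= 1))


def _anchored_thin(mask: np.ndarray, anchor: np.ndarray, dmap: np.ndarray
                   ) -> np.ndarray:
    """Erode the mask down to the anchor set.

    Phase 1 removes simple (connectivity-preserving) non-anchor pixels
    in ascending EDT order, so erosion proceeds from the boundary inward
    and unanchored protrusions vanish entirely; surviving non-anchor
    pixels are exactly the bridges connectivity requires.  Phase 2 then
    reduces anchored plateaus to single-pixel width by removing simple
    anchor pixels that are not end points.
    """
    cur = mask.copy()

    def sweep(candidate_mask: np.ndarray, protect_ends: bool) -> bool:
        changed = False
        cand = np.argwhere(candidate_mask & cur
                           & _SIMPLE_LUT[_patterns(cur)])
        if len(cand) == 0:
            return False
        order = np.argsort(dmap[cand[:, 0], cand[:, 1]], kind="stable")
        for r, c in cand[order]:
            if not cur[r, c]:
                continue
            pat = _pattern_at(cur, r, c)
            if not _SIMPLE_LUT[pat]:
                continue
            if protect_ends and bin(pat).count("1") <= 1:
                continue
            cur[r, c] = False
            changed = True
        return changed

    not_anchor = ~anchor
    while sweep(not_anchor, protect_ends=False):
        pass
    while sweep(anchor, protect_ends=True):
        pass
    return cur


def _steepest_ascent_path(dmap: np.ndarray, mask: np.ndarray,
                          start: tuple[int, int], sk: np.ndarray,
                          max_len: int) -> list[tuple[int, int]]:
    """Walk from a ridge end point to the 8-neighbor of maximal distance
    value until another skeleton pixel is met or a local maximum is
    reached; ties break in fixed N..NW order."""
    h, w = dmap.shape
    path: list[tuple[int, int]] = []
    r, c = start
    visited = {start}
    for _ in range(max_len):
        best = None
        best_val = dmap[r, c]
        for dr, dc in NEIGHBOR_ORDER:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w):
                continue
            if not mask[rr, cc] or (rr, cc) in visited:
                continue
            if dmap[rr, cc] > best_val:
                best_val = dmap[rr, cc]
                best = (rr, cc)
        if best is None:
            break
        r, c = best
        visited.add(best)
        if sk[r, c]:
            return path  # bridged into existing skeleton
        path.append(best)
    return path


def connect_skeleton(skel: Skeleton, dmap: np.ndarray,
                     mask: np.ndarray | None = None) -> Skeleton:
    """Turn the raw ridge set into a connected, single-pixel skeleton.

    Ridge end points are first extended along steepest-ascent paths of
    the distance map (capped at 4x the local radius) so collinear ridge
    fragments merge; the mask is then thinned down to the ridge set with
    the connectivity-preserving simple-point condition, which keeps
    exactly the extra pixels needed to hold each component's skeleton
    together.  The result is 8-connected per mask component, single
    pixel wide, and contained in the foreground.
    """
    if mask is None:
        mask = dmap > 0
    mask = np.asarray(mask, bool)
    sk = skel.mask & mask

    # seed components that produced no ridge pixel with their EDT max
    comp_labels, n_comp = ndimage.label(mask, structure=_STRUCT8)
    if n_comp:
        has_anchor = ndimage.sum_labels(sk.astype(np.int64), comp_labels,
                                        index=np.arange(1, n_comp + 1))
        for lab in np.flatnonzero(has_anchor == 0) + 1:
            comp = comp_labels == lab
            if comp.sum() < 4:
                continue
            idx = np.unravel_index(
                np.argmax(np.where(comp, dmap, -1.0)), dmap.shape)
            sk[idx] = True

    # steepest-ascent extension of ridge end points
    for r, c in _end_points(sk):
        cap = max(4, int(np.ceil(4 * dmap[r, c])))
        path = _steepest_ascent_path(dmap, mask, (int(r), int(c)), sk, cap)
        for p in path:
            sk[p] = True

    sk = _anchored_thin(mask, sk, dmap)
    return Skeleton(mask=sk, radius=np.where(sk, dmap, 0.0))


def skeletonize_mask(mask: np.ndarray) -> tuple[np.ndarray, Skeleton]:
    """Convenience pipeline: EDT plus connected skeleton for a mask."""
    dmap = distance_transform(mask)
    skel = extract_medial_axis(dmap, np.asarray(mask, bool))
    skel = connect_skeleton(skel, dmap, np.asarray(mask, bool))
    return dmap, skel
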