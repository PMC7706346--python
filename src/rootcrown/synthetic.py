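"""Synthetic backlit silhouettes with exact ground truth.

The generator emulates the imaging rig's output: a near-white background
(intensity 245) with near-black (intensity 15) connected root
structures.  Strokes are rendered as capsules (segments with round
caps) on a 4x supersampled grid and box-downsampled, so silhouette
edges carry the mild anti-aliased jaggedness of a real camera and
exercise the contour-smoothing stage.

Two families are provided: straight wires of known physical diameter
(the physical-calibration stand-in) and branching crowns with known
total length, tip count, per-segment angles and widths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BACKGROUND = 245
FOREGROUND = 15
_SS = 4  # supersampling factor


@dataclass
class CrownTruth:
    """Exact ground truth attached to a generated silhouette."""

    total_length_px: float = 0.0
    tip_count: int = 0
    max_width_px: float = 0.0
    depth_px: float = 0.0
    angles_deg: list[float] = field(default_factory=list)
    widths_px: list[float] = field(default_factory=list)
    seed: int = 0


def _render_capsules(shape: tuple[int, int],
                     segments: list[tuple[float, float, float, float, float]]
                     ) -> np.ndarray:
    """Rasterize capsule strokes (r0, c0, r1, c1, width) into a
    grayscale image via 4x supersampled coverage."""
    h, w = shape
    cov = np.zeros((h * _SS, w * _SS), dtype=bool)
    # supersample pixel centers in original pixel coordinates
    rr = (np.arange(h * _SS) + 0.5) / _SS - 0.5
    cc = (np.arange(w * _SS) + 0.5) / _SS - 0.5
    for (r0, c0, r1, c1, width) in segments:
        rad = width / 2.0
        rmin = max(0, int((min(r0, r1) - rad - 1) * _SS))
        rmax = min(h * _SS, int((max(r0, r1) + rad + 2) * _SS))
        cmin = max(0, int((min(c0, c1) - rad - 1) * _SS))
        cmax = min(w * _SS, int((max(c0, c1) + rad + 2) * _SS))
        if rmin >= rmax or cmin >= cmax:
            continue
        R = rr[rmin:rmax][:, None]
        C = cc[cmin:cmax][None, :]
        ar, ac = r0, c0
        br, bc = r1 - r0, c1 - c0
        denom = br * br + bc * bc
        if denom == 0:
            d2 = (R - ar) ** 2 + (C - ac) ** 2
        else:
            t = np.clip(((R - ar) * br + (C - ac) * bc) / denom, 0.0, 1.0)
            d2 = (R - (ar + t * br)) ** 2 + (C - (ac + t * bc)) ** 2
        cov[rmin:rmax, cmin:cmax] |= d2 <= rad * rad
    coverage = cov.reshape(h, _SS, w, _SS).mean(axis=(1, 3))
    img = BACKGROUND - (BACKGROUND - FOREGROUND) * coverage
    return np.round(img).astype(np.uint8)


def _bbox_of_capsules(segments) -> tuple[float, float, float, float]:
    rmin = min(min(s[0], s[2]) - s[4] / 2 for s in segments)
    rmax = max(max(s[0], s[2]) + s[4] / 2 for s in segments)
    cmin = min(min(s[1], s[3]) - s[4] / 2 for s in segments)
    cmax = max(max(s[1], s[3]) + s[4] / 2 for s in segments)
    return rmin, rmax, cmin, cmax


def make_wire_image(diameter_mm: float, length_mm: float, px_per_mm: float,
                    angle_deg: float = 90.0
                    ) -> tuple[np.ndarray, CrownTruth]:
    """Straight wire of known physical diameter on a bright background.

    The wire is drawn at the stated angle from the horizontal, centered
    in a canvas with a comfortable margin.  Sub-pixel diameters are
    rejected: the rasterizer cannot represent them faithfully.
    """
    width_px = diameter_mm * px_per_mm
    if width_px < 1.0:
        raise ValueError(
            f"wire diameter {diameter_mm} mm at {px_per_mm} px/mm is below "
            "the 1 px rendering floor"
        )
    length_px = length_mm * px_per_mm
    th = math.radians(angle_deg)
    dr = math.sin(th) * length_px / 2
    dc = math.cos(th) * length_px / 2
    margin = width_px + 10
    h = int(math.ceil(2 * abs(dr) + 2 * margin))
    w = int(math.ceil(2 * abs(dc) + 2 * margin))
    ctr_r, ctr_c = h / 2, w / 2
    seg = (ctr_r - dr, ctr_c - dc, ctr_r + dr, ctr_c + dc, width_px)
    img = _render_capsules((h, w), [seg])
    rmin, rmax, cmin, cmax = _bbox_of_capsules([seg])
    truth = CrownTruth(
        total_length_px=length_px,
        tip_count=2,
        max_width_px=cmax - cmin,
        depth_px=rmax - rmin,
        angles_deg=[angle_deg % 180],
        widths_px=[width_px],
    )
    return img, truth


def _point_seg_dist(p: tuple[float, float], seg) -> float:
    r0, c0, r1, c1, _ = seg
    br, bc = r1 - r0, c1 - c0
    denom = br * br + bc * bc
    if denom == 0:
        return math.hypot(p[0] - r0, p[1] - c0)
    t = max(0.0, min(1.0, ((p[0] - r0) * br + (p[1] - c0) * bc) / denom))
    return math.hypot(p[0] - (r0 + t * br), p[1] - (c0 + t * bc))


def _tip_clear(tip: tuple[float, float], width: float,
               tips: list[tuple[float, float]], segments) -> bool:
    """A lateral tip must stay clear of other tips and of every other
    stroke, so each drawn tip yields one skeleton end point."""
    if any(math.hypot(tip[0] - tr, tip[1] - tc) < 14.0 for tr, tc in tips):
        return False
    for seg in segments:
        if _point_seg_dist(tip, seg) < (width + seg[4]) / 2 + 5.0:
            return False
    return True


def _regime_angle(rng: np.random.Generator, regime) -> float:
    """Draw a lateral angle (degrees from horizontal) for a regime, or
    return the regime itself when it is already a number."""
    if isinstance(regime, (int, float)):
        return float(regime)
    if regime == "shallow":
        return float(rng.uniform(8.0, 28.0))
    if regime == "steep":
        return float(rng.uniform(62.0, 85.0))
    if regime == "mixed":
        return float(rng.uniform(8.0, 85.0))
    raise ValueError(f"unknown angle regime {regime!r}")


def make_synthetic_crown(
    n_laterals: int,
    angle_regime="mixed",
    width_range_px: tuple[float, float] = (3.0, 7.0),
    seed: int = 0,
    axis_angle_deg: float = 90.0,
    axis_length_px: float = 480.0,
    lateral_length_px: tuple[float, float] = (110.0, 200.0),
    canvas: tuple[int, int] = (640, 720),
) -> tuple[np.ndarray, CrownTruth]:
    """Branching crown silhouette: a main axis entering from the top
    border with ``n_laterals`` straight laterals.

    Laterals attach at well-separated points along the axis, alternate
    left/right, and are trimmed to keep their tips inside the frame and
    apart from each other.  ``angle_regime`` may be ``"shallow"``,
    ``"mixed"``, ``"steep"`` or a number fixing every segment's angle
    (the axis included) for single-angle recovery experiments.  The
    truth records exact polyline lengths, tip count (laterals + bottom
    tip + top attachment), per-segment angles and widths, and is
    reproducible from the seed.
    """
    if n_laterals < 0:
        raise ValueError("n_laterals must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = canvas
    wlo, whi = width_range_px

    single_angle = isinstance(angle_regime, (int, float))
    axis_theta = float(angle_regime) if single_angle else axis_angle_deg
    th = math.radians(axis_theta)
    axis_w = float(rng.uniform(max(wlo, 4.0), max(whi, 5.0)))

    # Axis from the top border downward at axis_theta from horizontal.
    top_c = w * (0.5 if not single_angle else 0.25)
    a0 = (0.0, top_c)
    dr, dc = math.sin(th), math.cos(th)
    L_axis = float(axis_length_px)
    a1 = (a0[0] + dr * L_axis, a0[1] + dc * L_axis)
    segments = [(a0[0], a0[1], a1[0], a1[1], axis_w)]
    angles = [axis_theta]
    widths = [axis_w]
    total_len = L_axis
    tips: list[tuple[float, float]] = [a1]

    attach_ts = np.linspace(0.15, 0.97, n_laterals) if n_laterals else []
    drawn = [_regime_angle(rng, angle_regime) for _ in range(int(n_laterals))]
    # Same-side laterals must not cross: per side, steeper angles attach
    # deeper.  (An upper lateral steeper than a lower one on the same
    # side would dive through it.)
    left = sorted(drawn[0::2])
    right = sorted(drawn[1::2])
    ordered = [0.0] * int(n_laterals)
    ordered[0::2] = left
    ordered[1::2] = right
    for i in range(int(n_laterals)):
        t = float(attach_ts[i])
        base = (a0[0] + dr * L_axis * t, a0[1] + dc * L_axis * t)
        theta = ordered[i]
        side = 1 if i % 2 == 0 else -1
        ldr = math.sin(math.radians(theta))
        ldc = side * math.cos(math.radians(theta))
        if single_angle:
            # every stroke at exactly theta: laterals mirror the axis
            # direction so they stay parallel to each other and distinct
            # from the axis (the fold to [0, 90] is direction-agnostic)
            ldc = -math.cos(math.radians(theta))
        L = float(rng.uniform(*lateral_length_px))
        lw = float(rng.uniform(wlo, whi))
        # trim to stay inside the frame with a margin
        margin = lw + 4
        for _ in range(60):
            er, ec = base[0] + ldr * L, base[1] + ldc * L
            if margin <= er < h - margin and margin <= ec < w - margin:
                break
            L *= 0.9
        er, ec = base[0] + ldr * L, base[1] + ldc * L
        # keep tips well apart from each other and off other strokes
        for _ in range(40):
            if _tip_clear((er, ec), lw, tips, segments):
                break
            L *= 0.85
            er, ec = base[0] + ldr * L, base[1] + ldc * L
        else:
            continue  # unplaceable lateral: skip, truth stays consistent
        if L < 25.0:
            continue
        segments.append((base[0], base[1], er, ec, lw))
        angles.append(theta)
        widths.append(lw)
        total_len += L
        tips.append((er, ec))

    img = _render_capsules((h, w), segments)
    rmin, rmax, cmin, cmax = _bbox_of_capsules(segments)
    rmin = max(rmin, -0.5)  # the frame clips the axis at the top border
    truth = CrownTruth(
        total_length_px=total_len,
        tip_count=len(segments) + 1,  # lateral tips + bottom tip + top
        max_width_px=cmax - cmin,
        depth_px=rmax - rmin,
        angles_deg=angles,
        widths_px=widths,
        seed=int(seed),
    )
    return img, truth


def make_degenerate_suite(shape: tuple[int, int] = (32, 32)
                          ) -> list[tuple[str, np.ndarray, dict]]:
    """Edge-case silhouettes paired with hand-computed expectations.

    Returns (name, gray image, notes) triples; notes record the
    behaviors a correct analyzer must show (all exact).
    """
    h, w = shape
    bg = np.full(shape, BACKGROUND, np.uint8)
    suite: list[tuple[str, np.ndarray, dict]] = []

    suite.append(("empty", bg.copy(), {"all_zero": True}))

    allfg = np.full(shape, FOREGROUND, np.uint8)
    suite.append(("all_foreground", allfg,
                  {"holes": 0, "network_area": float(h * w)}))

    single = bg.copy()
    single[h // 2, w // 2] = FOREGROUND
    suite.append(("single_pixel", single,
                  {"network_area": 1.0, "depth": 1.0, "maximum_width": 1.0}))

    line = bg.copy()
    line[h // 2, 4:w - 4] = FOREGROUND
    suite.append(("one_px_line", line,
                  {"depth": 1.0, "maximum_width": float(w - 8)}))

    border = bg.copy()
    border[0:h // 2, w // 2 - 2:w // 2 + 3] = FOREGROUND
    suite.append(("border_touching", border, {"touches_border": True}))

    ring = bg.copy()
    ring[8:24, 8:24] = FOREGROUND
    ring[13:19, 13:19] = BACKGROUND
    suite.append(("ring", ring, {"holes": 1, "average_hole_size": 36.0}))

    return suite
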