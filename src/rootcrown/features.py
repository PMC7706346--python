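"""Trait extraction: the 27 phenes measured on one root crown image.

All metrics are computed on the smoothed binary mask, its distance
transform, the medial-axis skeleton and the skeleton topology.  Counts
and frequencies are dimensionless; everything else is in pixel units
until converted with the imaging resolution.
"""

from __future__ import annotations

import time

import numpy as np
from scipy import ndimage

from .config import AnalyzerConfig, FeatureSet, convert_units
from .segmentation import (Contour, extract_contours, perimeter_length,
                           smooth_mask, threshold_image)
from .skeleton import Skeleton, skeletonize_mask
from .topology import (TopologyGraph, build_topology, count_tips,
                       total_root_length, validate_reconstruction)


def root_count_profile(mask: np.ndarray) -> np.ndarray:
    """Per-row count of background-to-foreground transitions in a
    left-to-right horizontal scan, over the rows spanning the
    foreground's vertical extent.

    A foreground pixel in the first column counts as one transition.
    Returns an empty array for an empty mask.
    """
    mask = np.asarray(mask, bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return np.zeros(0, dtype=np.int64)
    r0, r1 = int(rows[0]), int(rows[-1])
    band = mask[r0:r1 + 1]
    padded = np.concatenate(
        [np.zeros((band.shape[0], 1), bool), band], axis=1
    )
    transitions = (~padded[:, :-1]) & padded[:, 1:]
    return transitions.sum(axis=1).astype(np.int64)


def median_max_roots(profile: np.ndarray) -> tuple[float, int]:
    """Median (even length: mean of the central pair) and maximum of the
    per-row root counts; (0, 0) for an empty profile."""
    if len(profile) == 0:
        return 0.0, 0
    return float(np.median(profile)), int(profile.max())


def extent_metrics(mask: np.ndarray) -> tuple[float, float, float]:
    """(maximum_width, depth, width_to_depth_ratio) from the bounding
    box of the foreground; zeros for an empty mask."""
    mask = np.asarray(mask, bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return 0.0, 0.0, 0.0
    depth = float(rows[-1] - rows[0] + 1)
    width = float(cols[-1] - cols[0] + 1)
    return width, depth, width / depth


def convex_hull_area(mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Shoelace area of the convex hull of foreground pixel centers and
    the hull vertices as an (n, 2) array of (row, col).  Degenerate
    (collinear or < 3 pixels) foregrounds have area 0."""
    pts = np.argwhere(np.asarray(mask, bool))
    if len(pts) < 3:
        return 0.0, pts.astype(float)
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:  # collinear points
        return 0.0, pts.astype(float)
    return float(hull.volume), pts[hull.vertices].astype(float)


def area_metrics(mask: np.ndarray,
                 contours: list[Contour] | None = None
                 ) -> tuple[float, float, float, float]:
    """(network_area, convex_area, solidity, perimeter).

    network_area counts foreground pixels; convex_area is the shoelace
    area of the hull of pixel centers; solidity is their ratio (0 when
    the hull is degenerate); perimeter sums chain-step lengths over all
    traced contours.
    """
    mask = np.asarray(mask, bool)
    network = float(mask.sum())
    convex, _ = convex_hull_area(mask)
    # Hull of pixel centers slightly underestimates pixel area, so the
    # ratio can nominally exceed 1 for near-solid blobs; clamp it.
    solidity = min(1.0, network / convex) if convex > 0 else 0.0
    if contours is None:
        contours = extract_contours(mask)
    return network, convex, solidity, perimeter_length(contours)


def diameter_metrics(skel: Skeleton, bin_edges: tuple[float, float]
                     ) -> dict[str, float]:
    """Diameter statistics over the skeleton's per-pixel radii.

    diameter = 2 * radius; volume sums the circular cross-section
    pi*r**2 per unit-length skeleton pixel; surface_area sums the circle
    perimeter 2*pi*r.  Frequencies are the normalized histogram of
    diameters over [0, e1), [e1, e2), [e2, inf).
    """
    radii = skel.radii()
    if radii.size == 0:
        return dict(average_diameter=0.0, median_diameter=0.0,
                    maximum_diameter=0.0, volume=0.0, surface_area=0.0,
                    fine_diameter_frequency=0.0,
                    medium_diameter_frequency=0.0,
                    coarse_diameter_frequency=0.0)
    diam = 2.0 * radii
    e1, e2 = bin_edges
    n = float(diam.size)
    return dict(
        average_diameter=float(diam.mean()),
        median_diameter=float(np.median(diam)),
        maximum_diameter=float(diam.max()),
        volume=float(np.pi * (radii ** 2).sum()),
        surface_area=float(2.0 * np.pi * radii.sum()),
        fine_diameter_frequency=float((diam < e1).sum() / n),
        medium_diameter_frequency=float(((diam >= e1) & (diam < e2)).sum() / n),
        coarse_diameter_frequency=float((diam >= e2).sum() / n),
    )


def lower_root_area(mask: np.ndarray, skel: Skeleton) -> float:
    """Foreground area strictly below the maximum-radius skeleton pixel
    (ties on radius broken by smallest row, then smallest col)."""
    pix = skel.pixels
    if len(pix) == 0:
        return 0.0
    radii = skel.radius[pix[:, 0], pix[:, 1]]
    best = np.lexsort((pix[:, 1], pix[:, 0], -radii))[0]
    row = int(pix[best, 0])
    return float(np.asarray(mask, bool)[row + 1:].sum())


def hole_metrics(mask: np.ndarray) -> tuple[int, float]:
    """(holes, average_hole_size): 4-connected background components not
    touching the image border, and their mean pixel count."""
    mask = np.asarray(mask, bool)
    labels, n = ndimage.label(~mask)  # 4-connectivity
    if n == 0:
        return 0, 0.0
    border = set(np.unique(np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    ))) - {0}
    sizes = ndimage.sum_labels(np.ones(mask.shape, dtype=np.int64), labels,
                               index=np.arange(1, n + 1))
    keep = [sizes[i - 1] for i in range(1, n + 1) if i not in border]
    if not keep:
        return 0, 0.0
    return len(keep), float(np.mean(keep))


def _box_sums(ind: np.ndarray, values: list[np.ndarray], half: int
              ) -> list[np.ndarray]:
    """Sums of each value image over the (2*half+1)-square window
    centered at every pixel, via summed-area tables."""
    outs = []
    for v in values:
        s = np.zeros((v.shape[0] + 1, v.shape[1] + 1))
        np.cumsum(np.cumsum(v, axis=0), axis=1, out=s[1:, 1:])
        h, w = v.shape
        r = np.arange(h)
        c = np.arange(w)
        r0 = np.clip(r - half, 0, h)
        r1 = np.clip(r + half + 1, 0, h)
        c0 = np.clip(c - half, 0, w)
        c1 = np.clip(c + half + 1, 0, w)
        outs.append(
            s[np.ix_(r1, c1)] - s[np.ix_(r0, c1)]
            - s[np.ix_(r1, c0)] + s[np.ix_(r0, c0)]
        )
    return outs


def orientation_metrics(skel: Skeleton, g: TopologyGraph, window_px: int
                        ) -> dict[str, float]:
    """Per-pixel root orientation and its 3-bin angle histogram.

    For each skeleton pixel, all skeleton pixels within the centered
    window contribute to a 2x2 coordinate covariance; the principal
    eigenvector's slope gives the local angle, folded into [0, 90]
    degrees from the horizontal.  Bins are [0, 30), [30, 60), [60, 90].
    Windows with < 2 pixels or an isotropic covariance fall back to the
    chord angle of the pixel's segment.
    """
    sk = skel.mask
    npix = int(sk.sum())
    if npix == 0:
        return dict(average_root_orientation=0.0,
                    shallow_angle_frequency=0.0,
                    medium_angle_frequency=0.0,
                    steep_angle_frequency=0.0)
    if npix == 1:
        return dict(average_root_orientation=0.0,
                    shallow_angle_frequency=1.0,
                    medium_angle_frequency=0.0,
                    steep_angle_frequency=0.0)

    half = max(1, int(window_px) // 2)
    ind = sk.astype(float)
    rows = np.arange(sk.shape[0], dtype=float)[:, None] * ind
    cols = np.arange(sk.shape[1], dtype=float)[None, :] * ind
    S1, Sr, Sc, Srr, Scc, Src = _box_sums(
        ind,
        [ind, rows, cols,
         rows * np.arange(sk.shape[0], dtype=float)[:, None],
         cols * np.arange(sk.shape[1], dtype=float)[None, :],
         rows * np.arange(sk.shape[1], dtype=float)[None, :]],
        half,
    )
    pr, pc = np.nonzero(sk)
    n = S1[pr, pc]
    mr = Sr[pr, pc] / n
    mc = Sc[pr, pc] / n
    crr = Srr[pr, pc] / n - mr ** 2
    ccc = Scc[pr, pc] / n - mc ** 2
    crc = Src[pr, pc] / n - mr * mc
    # principal-axis angle from the horizontal (col axis), radians
    theta = 0.5 * np.arctan2(2.0 * crc, ccc - crr)
    angles = np.degrees(np.abs(theta))
    angles = np.where(angles > 90.0, 180.0 - angles, angles)

    # Degenerate windows: < 2 pixels or numerically isotropic covariance.
    degen = (n < 2) | ((np.abs(crc) < 1e-12) & (np.abs(ccc - crr) < 1e-12))
    if degen.any():
        chord = _segment_chord_angles(g, sk.shape)
        for i in np.flatnonzero(degen):
            angles[i] = chord.get((int(pr[i]), int(pc[i])), 0.0)

    shallow = float((angles < 30.0).sum() / angles.size)
    medium = float(((angles >= 30.0) & (angles < 60.0)).sum() / angles.size)
    steep = float((angles >= 60.0).sum() / angles.size)
    return dict(
        average_root_orientation=float(angles.mean()),
        shallow_angle_frequency=shallow,
        medium_angle_frequency=medium,
        steep_angle_frequency=steep,
    )


def _segment_chord_angles(g: TopologyGraph, shape) -> dict[tuple[int, int], float]:
    """Fallback angle per pixel: the chord angle of its segment."""
    out: dict[tuple[int, int], float] = {}
    for s in g.segments:
        a = np.asarray(s.pixels[0], float)
        b = np.asarray(s.pixels[-1], float)
        dr, dc = b - a
        if dr == 0 and dc == 0:
            ang = 0.0
        else:
            ang = abs(np.degrees(np.arctan2(abs(dr), abs(dc))))
        for p in s.pixels:
            out[p] = ang
    return out


def assemble_features(
    mask: np.ndarray,
    dmap: np.ndarray,
    skel: Skeleton,
    g: TopologyGraph,
    config: AnalyzerConfig,
    file_name: str = "",
    elapsed_seconds: float = 0.0,
    contours: list[Contour] | None = None,
) -> FeatureSet:
    """Populate the full 27-field feature record from the pipeline
    stages of one image, in pixel units."""
    profile = root_count_profile(mask)
    med_roots, max_roots = median_max_roots(profile)
    width, depth, ratio = extent_metrics(mask)
    network, convex, solidity, perim = area_metrics(mask, contours)
    # diameter bin edges are mm when a scale is given; work in px here
    e1, e2 = config.diameter_bin_edges
    if config.pixels_per_mm is not None:
        e1, e2 = e1 * config.pixels_per_mm, e2 * config.pixels_per_mm
    diam = diameter_metrics(skel, (e1, e2))
    holes, avg_hole = hole_metrics(mask)
    orient = orientation_metrics(skel, g, config.angle_window_px)
    fs = FeatureSet(
        file_name=file_name,
        units="px",
        median_number_of_roots=med_roots,
        maximum_number_of_roots=float(max_roots),
        number_of_root_tips=float(count_tips(g)),
        total_root_length=total_root_length(g),
        depth=depth,
        maximum_width=width,
        width_to_depth_ratio=ratio,
        network_area=network,
        convex_area=convex,
        solidity=solidity,
        perimeter=perim,
        lower_root_area=lower_root_area(mask, skel),
        holes=float(holes),
        average_hole_size=avg_hole,
        computational_time=elapsed_seconds,
        **diam,
        **orient,
    )
    return fs


def analyze_mask(mask: np.ndarray, config: AnalyzerConfig | None = None,
                 file_name: str = "", presmoothed: bool = False
                 ) -> tuple[FeatureSet, dict]:
    """Run the full pipeline on a binary mask.

    Returns the feature record (converted to mm when the config carries
    a scale) and a dict of intermediate artifacts (smoothed mask, dmap,
    skeleton, topology, contours) for rendering and diagnostics.
    """
    t0 = time.perf_counter()
    config = config or AnalyzerConfig()
    mask = np.asarray(mask, bool)
    smoothed = mask if presmoothed else smooth_mask(mask, config.rdp_epsilon_px)
    contours = extract_contours(smoothed)
    dmap, skel = skeletonize_mask(smoothed)
    g = build_topology(skel)
    ok = validate_reconstruction(g, skel)
    fs = assemble_features(
        smoothed, dmap, skel, g, config, file_name=file_name,
        contours=contours,
    )
    if config.pixels_per_mm is not None:
        fs = convert_units(fs, config.pixels_per_mm)
    fs.computational_time = time.perf_counter() - t0
    artifacts = dict(mask=smoothed, dmap=dmap, skeleton=skel, topology=g,
                     contours=contours, reconstruction_ok=ok)
    return fs, artifacts


def analyze_image(img: np.ndarray, config: AnalyzerConfig | None = None,
                  file_name: str = "") -> tuple[FeatureSet, dict]:
    """Threshold a grayscale image and run :func:`analyze_mask`."""
    config = config or AnalyzerConfig()
    mask = threshold_image(img, config.threshold_level,
                           config.invert_foreground)
    return analyze_mask(mask, config, file_name=file_name)
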