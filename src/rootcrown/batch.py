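"""Batch analysis driver and diagnostic image rendering.

Processes every image in a folder in lexicographic order, writes a
features CSV (one row per image) and a metadata CSV of the options
used, and optionally writes per-image segmented and feature-overlay
images.  A failure on one image is logged and never aborts the batch.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import (AnalyzerConfig, FeatureSet, write_features_csv,
                     write_metadata_csv)
from .features import analyze_image
from .segmentation import load_gray_image
from .skeleton import Skeleton
from .topology import TopologyGraph

IMAGE_EXTENSIONS = (".png", ".bmp", ".jpg", ".jpeg", ".tif", ".tiff")

log = logging.getLogger("rootcrown")


@dataclass
class BatchResult:
    rows: list[FeatureSet] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)
    elapsed: dict[str, float] = field(default_factory=dict)


def _deterministic_color(seed: int, index: int) -> np.ndarray:
    rng = np.random.default_rng((seed, index))
    return rng.integers(40, 220, size=3).astype(np.uint8)


def render_segmented(mask: np.ndarray) -> np.ndarray:
    """Black silhouette on a white canvas, as the batch writes it."""
    img = np.full(mask.shape, 255, np.uint8)
    img[np.asarray(mask, bool)] = 0
    return img


def render_feature_image(mask: np.ndarray, dmap: np.ndarray,
                         skel: Skeleton, g: TopologyGraph,
                         hull: np.ndarray, seed: int = 0) -> np.ndarray:
    """Diagnostic overlay: convex hull polyline in blue, contour and
    skeleton pixels in red, distance transform in the green channel,
    and each enclosed hole filled with a deterministic pseudo-random
    color keyed by (seed, hole index)."""
    from scipy import ndimage
    from skimage.draw import line as draw_line

    from .segmentation import extract_contours

    mask = np.asarray(mask, bool)
    h, w = mask.shape
    img = np.zeros((h, w, 3), np.uint8)
    if dmap.max() > 0:
        img[..., 1] = (dmap / dmap.max() * 255).astype(np.uint8)

    # holes, randomly colored
    labels, n = ndimage.label(~mask)
    border = set(np.unique(np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    ))) - {0}
    hole_idx = 0
    for lab in range(1, n + 1):
        if lab in border:
            continue
        img[labels == lab] = _deterministic_color(seed, hole_idx)
        hole_idx += 1

    # contours and skeleton in red
    for c in extract_contours(mask):
        img[c.points[:, 0], c.points[:, 1]] = (255, 0, 0)
    img[skel.mask] = (255, 0, 0)

    # convex hull polyline in blue
    if len(hull) >= 2:
        closed = np.vstack([hull, hull[:1]]).astype(int)
        for a, b in zip(closed[:-1], closed[1:]):
            rr, cc = draw_line(a[0], a[1], b[0], b[1])
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            img[rr[ok], cc[ok]] = (0, 0, 255)
    return img


def run_batch(input_dir, output_dir, config: AnalyzerConfig | None = None,
              seed: int = 0) -> BatchResult:
    """Analyze every supported image under ``input_dir``.

    Writes ``features.csv`` and ``metadata.csv`` into ``output_dir``
    (plus ``<name>_seg.png`` / ``<name>_features.png`` when the config
    asks for them) and returns the in-memory result.
    """
    import imageio.v3 as iio

    config = config or AnalyzerConfig()
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    result = BatchResult()

    paths = sorted(p for p in input_dir.iterdir()
                   if p.suffix.lower() in IMAGE_EXTENSIONS)
    for path in paths:
        t0 = time.perf_counter()
        try:
            gray = load_gray_image(path)
            fs, art = analyze_image(gray, config, file_name=path.name)
            result.rows.append(fs)
            if config.save_segmented:
                iio.imwrite(output_dir / f"{path.stem}_seg.png",
                            render_segmented(art["mask"]))
            if config.save_feature_image:
                from .features import convex_hull_area

                _, hull = convex_hull_area(art["mask"])
                overlay = render_feature_image(
                    art["mask"], art["dmap"], art["skeleton"],
                    art["topology"], hull, seed=seed,
                )
                iio.imwrite(output_dir / f"{path.stem}_features.png", overlay)
            log.info("analyzed %s (%.3f s)", path.name,
                     time.perf_counter() - t0)
        except Exception as exc:  # fault isolation: log and continue
            result.failures.append((path.name, str(exc)))
            log.warning("failed on %s: %s", path.name, exc)
        result.elapsed[path.name] = time.perf_counter() - t0

    write_features_csv(output_dir / "features.csv", result.rows)
    write_metadata_csv(output_dir / "metadata.csv", config)
    return result
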