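"""Analysis configuration and the extracted feature record.

A root crown silhouette is reduced to 27 quantitative phenes.  All
measurements are made in pixel units; when the imaging resolution
(pixels per millimeter) is known they are converted to physical units:
lengths scale with 1/s, areas with 1/s**2 and volume with 1/s**3, while
counts, ratios, frequencies and angles are dimensionless and unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional, Sequence


class ConfigurationError(ValueError):
    """Raised when an analysis option is out of its valid range."""


@dataclass(frozen=True)
class AnalyzerConfig:
    """User-facing options of the analysis pipeline.

    Parameters
    ----------
    threshold_level : int
        Grayscale cutoff in [0, 255].  Pixels darker than this level are
        foreground (the root silhouette) unless ``invert_foreground``.
    rdp_epsilon_px : float
        Distance threshold of the Ramer-Douglas-Peucker contour
        simplification, in pixels.  2 px removes the jagged single-pixel
        edge noise of backlit silhouettes without altering root shape.
    angle_window_px : int
        Side of the square neighborhood used for the local orientation
        of each skeletal pixel (principal-component slope).
    diameter_bin_edges : (float, float)
        Ascending edges splitting root diameters into fine / medium /
        coarse classes.  Interpreted in mm when ``pixels_per_mm`` is
        given, else in px.
    pixels_per_mm : float or None
        Imaging resolution; when given, output switches to mm units.
    save_segmented, save_feature_image : bool
        Whether the batch driver writes per-image diagnostic images.
    invert_foreground : bool
        False (default) selects pixels *darker* than the threshold, the
        convention of a bright backlight behind a dark root.
    """

    threshold_level: int = 128
    rdp_epsilon_px: float = 2.0
    angle_window_px: int = 40
    diameter_bin_edges: tuple[float, float] = (2.0, 5.0)
    pixels_per_mm: Optional[float] = None
    save_segmented: bool = False
    save_feature_image: bool = False
    invert_foreground: bool = False

    def __post_init__(self) -> None:
        if not (0 <= int(self.threshold_level) <= 255):
            raise ConfigurationError(
                f"threshold_level must be in [0, 255], got {self.threshold_level}"
            )
        if not self.rdp_epsilon_px > 0:
            raise ConfigurationError("rdp_epsilon_px must be positive")
        if int(self.angle_window_px) < 3:
            raise ConfigurationError("angle_window_px must be >= 3")
        e1, e2 = self.diameter_bin_edges
        if not (0 < e1 < e2):
            raise ConfigurationError(
                "diameter_bin_edges must be two ascending positive values"
            )
        if self.pixels_per_mm is not None and not self.pixels_per_mm > 0:
            raise ConfigurationError("pixels_per_mm must be positive")

    def to_metadata_rows(self) -> list[tuple[str, str]]:
        """Key/value rows for the metadata CSV written next to results."""
        rows: list[tuple[str, str]] = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "diameter_bin_edges":
                rows.append(("diameter_bin_edge_1", repr(v[0])))
                rows.append(("diameter_bin_edge_2", repr(v[1])))
            else:
                rows.append((f.name, "" if v is None else repr(v)))
        return rows


# Canonical ordering of the 27 extracted features, used for the CSV header.
FEATURE_NAMES: tuple[str, ...] = (
    "median_number_of_roots",
    "maximum_number_of_roots",
    "number_of_root_tips",
    "total_root_length",
    "depth",
    "maximum_width",
    "width_to_depth_ratio",
    "network_area",
    "convex_area",
    "solidity",
    "perimeter",
    "average_diameter",
    "median_diameter",
    "maximum_diameter",
    "volume",
    "surface_area",
    "lower_root_area",
    "holes",
    "average_hole_size",
    "average_root_orientation",
    "fine_diameter_frequency",
    "medium_diameter_frequency",
    "coarse_diameter_frequency",
    "shallow_angle_frequency",
    "medium_angle_frequency",
    "steep_angle_frequency",
    "computational_time",
)

# Dimension of each feature under a px -> mm rescale by s = pixels_per_mm:
# value_mm = value_px / s**dim.  Dimensionless entries have dim 0.
_LENGTH_FEATURES = frozenset(
    {"total_root_length", "depth", "maximum_width", "perimeter",
     "average_diameter", "median_diameter", "maximum_diameter",
     "surface_area"}
)
_AREA_FEATURES = frozenset(
    {"network_area", "convex_area", "lower_root_area", "average_hole_size"}
)
_VOLUME_FEATURES = frozenset({"volume"})


@dataclass
class FeatureSet:
    """The 27 phenes measured on one root crown image.

    ``units`` is ``"px"`` or ``"mm"``; ``computational_time`` is seconds
    and never rescaled.
    """

    file_name: str = ""
    units: str = "px"

    median_number_of_roots: float = 0.0
    maximum_number_of_roots: float = 0.0
    number_of_root_tips: float = 0.0
    total_root_length: float = 0.0
    depth: float = 0.0
    maximum_width: float = 0.0
    width_to_depth_ratio: float = 0.0
    network_area: float = 0.0
    convex_area: float = 0.0
    solidity: float = 0.0
    perimeter: float = 0.0
    average_diameter: float = 0.0
    median_diameter: float = 0.0
    maximum_diameter: float = 0.0
    volume: float = 0.0
    surface_area: float = 0.0
    lower_root_area: float = 0.0
    holes: float = 0.0
    average_hole_size: float = 0.0
    average_root_orientation: float = 0.0
    fine_diameter_frequency: float = 0.0
    medium_diameter_frequency: float = 0.0
    coarse_diameter_frequency: float = 0.0
    shallow_angle_frequency: float = 0.0
    medium_angle_frequency: float = 0.0
    steep_angle_frequency: float = 0.0
    computational_time: float = 0.0

    def to_dict(self) -> dict[str, object]:
        d: dict[str, object] = {"file_name": self.file_name, "units": self.units}
        for name in FEATURE_NAMES:
            d[name] = getattr(self, name)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, object]) -> "FeatureSet":
        kwargs = {"file_name": str(d.get("file_name", "")),
                  "units": str(d.get("units", "px"))}
        for name in FEATURE_NAMES:
            kwargs[name] = float(d[name])  # type: ignore[arg-type]
        return cls(**kwargs)  # type: ignore[arg-type]


def surface_area_dimension() -> int:
    """surface_area is a sum of circle perimeters (px) over 1-px skeleton
    steps, i.e. px^2 in total -- it rescales as an area."""
    return 2


def convert_units(features_px: FeatureSet, pixels_per_mm: float) -> FeatureSet:
    """Convert a pixel-unit feature set to millimeters.

    Lengths divide by s, areas by s**2, volume by s**3; counts, ratios,
    frequencies, the orientation angle and the elapsed time are
    unchanged.
    """
    if not pixels_per_mm > 0:
        raise ConfigurationError("pixels_per_mm must be positive")
    if features_px.units != "px":
        raise ConfigurationError(
            f"expected pixel-unit features, got units={features_px.units!r}"
        )
    s = float(pixels_per_mm)
    updates: dict[str, float] = {}
    for name in FEATURE_NAMES:
        v = getattr(features_px, name)
        if name in _LENGTH_FEATURES and name != "surface_area":
            updates[name] = v / s
        elif name == "surface_area" or name in _AREA_FEATURES:
            updates[name] = v / s**2
        elif name in _VOLUME_FEATURES:
            updates[name] = v / s**3
    # width_to_depth_ratio is scale-invariant and left untouched
    return replace(features_px, units="mm", **updates)


def write_features_csv(path, feature_sets: Iterable[FeatureSet]) -> None:
    """Write one row per image; header is file_name, units, then the 27
    feature names in canonical order."""
    header = ["file_name", "units", *FEATURE_NAMES]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for fs in feature_sets:
            d = fs.to_dict()
            w.writerow([d[k] for k in header])


def read_features_csv(path) -> list[FeatureSet]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [FeatureSet.from_dict(row) for row in csv.DictReader(fh)]


def write_metadata_csv(path, config: AnalyzerConfig) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["key", "value"])
        w.writerows(config.to_metadata_rows())
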