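import numpy as np
import pytest

from rootcrown import AnalyzerConfig, make_synthetic_crown


@pytest.fixture(scope="session")
def mixed_crown():
    """One mid-size branching crown silhouette with its ground truth."""
    img, truth = make_synthetic_crown(24, "mixed", seed=3)
    return img, truth


@pytest.fixture(scope="session")
def crown_analysis(mixed_crown):
    from rootcrown import analyze_image

    img, truth = mixed_crown
    fs, art = analyze_image(img, AnalyzerConfig())
    return fs, art, truth


def bar_mask(rows: int, cols: int, width: int, shape=None) -> np.ndarray:
    """Vertical bar of the given pixel width centered in a canvas."""
    h, w = shape or (rows + 10, cols)
    m = np.zeros((h, w), bool)
    c0 = (w - width) // 2
    m[5:5 + rows, c0:c0 + width] = True
    return m


def y_mask() -> np.ndarray:
    """Hand-drawn Y: two diagonal arms joining into a vertical stem."""
    m = np.zeros((16, 13), bool)
    for i in range(5):
        m[1 + i, 2 + i] = True      # left arm
        m[1 + i, 10 - i] = True     # right arm
    m[6:14, 6] = True               # stem
    return m
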