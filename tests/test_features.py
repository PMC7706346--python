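import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from rootcrown import AnalyzerConfig, FEATURE_NAMES, analyze_mask
from rootcrown.features import (area_metrics, convex_hull_area,
                                diameter_metrics, extent_metrics,
                                hole_metrics, lower_root_area,
                                median_max_roots, orientation_metrics,
                                root_count_profile)
from rootcrown.skeleton import Skeleton, skeletonize_mask
from rootcrown.topology import build_topology


def skel_of(mask, radii=None):
    radius = np.where(mask, 1.0 if radii is None else radii, 0.0)
    return Skeleton(mask=np.asarray(mask, bool), radius=radius)


class TestRootCountProfile:
    def test_solid_bar_counts_one(self):
        m = np.zeros((10, 7), bool)
        m[2:9, 3] = True
        assert (root_count_profile(m) == 1).all()
        assert len(root_count_profile(m)) == 7

    def test_two_bars_count_two(self):
        m = np.zeros((10, 9), bool)
        m[2:9, 2] = True
        m[2:9, 6] = True
        assert (root_count_profile(m) == 2).all()

    def test_scan_oracle_row(self):
        m = np.array([[0, 1, 1, 0, 1]], dtype=bool)
        assert root_count_profile(m).tolist() == [2]

    def test_foreground_at_first_column_counts(self):
        m = np.array([[1, 1, 0, 1]], dtype=bool)
        assert root_count_profile(m).tolist() == [2]

    def test_empty(self):
        assert len(root_count_profile(np.zeros((4, 4), bool))) == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_translation_and_mirror(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((12, 20), bool)
        m[3:9, 2:10] = rng.random((6, 8)) < 0.5
        med, mx = median_max_roots(root_count_profile(m))
        shifted = np.roll(m, 7, axis=1)
        mirrored = m[:, ::-1]
        assert median_max_roots(root_count_profile(shifted)) == (med, mx)
        assert median_max_roots(root_count_profile(mirrored)) == (med, mx)


class TestMedianMaxRoots:
    @pytest.mark.parametrize("profile,expected", [
        ([1, 1, 1], (1.0, 1)),
        ([1, 1, 3, 5, 5], (3.0, 5)),
        ([2, 4], (3.0, 4)),
        ([], (0.0, 0)),
    ])
    def test_examples(self, profile, expected):
        assert median_max_roots(np.array(profile)) == expected


class TestExtentMetrics:
    @pytest.mark.parametrize("build,expected", [
        (lambda m: m.__setitem__((2, 3), True), (1.0, 1.0, 1.0)),
        (lambda m: m.__setitem__((slice(0, 10), slice(1, 4)), True),
         (3.0, 10.0, 0.3)),
        (lambda m: None, (0.0, 0.0, 0.0)),
    ])
    def test_examples(self, build, expected):
        m = np.zeros((10, 6), bool)
        build(m)
        w, d, r = extent_metrics(m)
        assert (w, d, r) == pytest.approx(expected)


class TestAreaMetrics:
    def test_filled_square(self):
        m = np.zeros((12, 12), bool)
        m[1:11, 1:11] = True
        network, convex, solidity, perim = area_metrics(m)
        assert network == 100
        assert convex == pytest.approx(81.0)  # hull of pixel centers: 9x9
        assert perim == pytest.approx(36.0)
        assert solidity == 1.0  # clamped ratio

    def test_single_pixel_degenerate(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        network, convex, solidity, perim = area_metrics(m)
        assert (network, convex, solidity, perim) == (1.0, 0.0, 0.0, 0.0)

    def test_l_hexomino_brute_force_hull(self):
        m = np.zeros((6, 6), bool)
        pts = [(1, 1), (2, 1), (3, 1), (4, 1), (4, 2), (4, 3)]
        for p in pts:
            m[p] = True
        network, convex, _, _ = area_metrics(m)
        assert network == 6
        # brute-force hull: all points, shoelace over the convex polygon
        from itertools import combinations

        def cross(o, a, b):
            return ((a[0] - o[0]) * (b[1] - o[1])
                    - (a[1] - o[1]) * (b[0] - o[0]))

        hull_pts = [(1, 1), (4, 1), (4, 3)]  # triangle
        area2 = abs(cross(*hull_pts)) / 2
        assert convex == pytest.approx(area2)


class TestDiameterMetrics:
    def test_single_pixel_radius_one(self):
        sk = skel_of(np.array([[1]], bool))
        d = diameter_metrics(sk, (3.0, 5.0))
        assert d["average_diameter"] == d["median_diameter"] == 2.0
        assert d["maximum_diameter"] == 2.0
        assert d["volume"] == pytest.approx(np.pi)
        assert d["surface_area"] == pytest.approx(2 * np.pi)

    def test_uniform_radius_two_bins(self):
        m = np.zeros((1, 10), bool)
        m[0, :] = True
        sk = skel_of(m, radii=2.0)
        d = diameter_metrics(sk, (3.0, 5.0))
        assert (d["fine_diameter_frequency"],
                d["medium_diameter_frequency"],
                d["coarse_diameter_frequency"]) == (0.0, 1.0, 0.0)

    def test_mixed_radii_median_max(self):
        m = np.array([[1, 1, 1]], bool)
        sk = skel_of(m, radii=np.array([[1.0, 1.0, 3.0]]))
        d = diameter_metrics(sk, (3.0, 5.0))
        assert d["median_diameter"] == 2.0
        assert d["maximum_diameter"] == 6.0

    def test_empty_skeleton_zeros(self):
        d = diameter_metrics(skel_of(np.zeros((2, 2), bool)), (3.0, 5.0))
        assert all(v == 0.0 for v in d.values())

    def test_bin_edges_are_lower_inclusive(self):
        m = np.array([[1, 1]], bool)
        sk = skel_of(m, radii=np.array([[1.5, 2.5]]))  # diameters 3 and 5
        d = diameter_metrics(sk, (3.0, 5.0))
        assert d["fine_diameter_frequency"] == 0.0
        assert d["medium_diameter_frequency"] == 0.5
        assert d["coarse_diameter_frequency"] == 0.5


class TestLowerRootArea:
    def test_max_on_last_row_gives_zero(self):
        m = np.ones((4, 3), bool)
        smask = np.zeros((4, 3), bool)
        smask[3, 1] = True  # lone max-radius pixel on the last row
        sk = skel_of(smask)
        assert lower_root_area(m, sk) == 0.0

    def test_widened_bar(self):
        # 3-px bar over 11 rows, widened to 5 px at row 4 only
        m = np.zeros((11, 9), bool)
        m[:, 3:6] = True
        m[4, 2:7] = True
        dmap, skel = skeletonize_mask(m)
        area = lower_root_area(m, skel)
        assert area == float(m[5:].sum())

    def test_tie_broken_by_topmost(self):
        m = np.zeros((8, 5), bool)
        m[1:7, 2] = True  # uniform bar: all radii tie at 1
        sk = skel_of(m)
        assert lower_root_area(m, sk) == float(m[2:].sum())


class TestHoleMetrics:
    def test_solid_square(self):
        m = np.zeros((8, 8), bool)
        m[1:7, 1:7] = True
        assert hole_metrics(m) == (0, 0.0)

    def test_single_pixel_hole(self):
        m = np.zeros((8, 8), bool)
        m[1:7, 1:7] = True
        m[3, 3] = False
        assert hole_metrics(m) == (1, 1.0)

    def test_ring_plus_blob_flood_fill_oracle(self):
        m = np.zeros((14, 20), bool)
        m[1:10, 1:10] = True
        m[3:6, 3:6] = False      # 3x3 enclosed hole
        m[11:13, 12:18] = True   # separate solid blob
        holes, avg = hole_metrics(m)
        assert (holes, avg) == (1, 9.0)

    def test_border_gap_is_not_a_hole(self):
        m = np.zeros((6, 6), bool)
        m[0, :] = True
        m[2, :] = True  # stripe of background between rows touches sides
        assert hole_metrics(m)[0] == 0


class TestOrientationMetrics:
    def _metrics(self, mask, window=40):
        sk = skel_of(mask)
        g = build_topology(sk)
        return orientation_metrics(sk, g, window)

    def test_horizontal_line(self):
        m = np.zeros((5, 60), bool)
        m[2, 2:58] = True
        o = self._metrics(m)
        assert o["average_root_orientation"] == pytest.approx(0.0, abs=1e-6)
        assert o["shallow_angle_frequency"] == 1.0

    def test_vertical_line(self):
        m = np.zeros((60, 5), bool)
        m[2:58, 2] = True
        o = self._metrics(m)
        assert o["average_root_orientation"] == pytest.approx(90.0, abs=1e-6)
        assert o["steep_angle_frequency"] == 1.0

    def test_perfect_diagonal_is_medium(self):
        m = np.eye(60, dtype=bool)
        o = self._metrics(m)
        assert o["average_root_orientation"] == pytest.approx(45.0, abs=1e-6)
        assert o["medium_angle_frequency"] == 1.0
        assert o["shallow_angle_frequency"] == 0.0

    def test_single_pixel_is_shallow(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        o = self._metrics(m)
        assert o["average_root_orientation"] == 0.0
        assert o["shallow_angle_frequency"] == 1.0

    def test_frequencies_sum_to_one(self, crown_analysis):
        fs, _, _ = crown_analysis
        assert (fs.shallow_angle_frequency + fs.medium_angle_frequency
                + fs.steep_angle_frequency) == pytest.approx(1.0, abs=1e-9)
        assert (fs.fine_diameter_frequency + fs.medium_diameter_frequency
                + fs.coarse_diameter_frequency) == pytest.approx(1.0, abs=1e-9)


class TestAssembleFeatures:
    def test_empty_image_all_zero(self):
        fs, _ = analyze_mask(np.zeros((10, 10), bool))
        for name in FEATURE_NAMES:
            if name == "computational_time":
                continue
            assert getattr(fs, name) == 0.0

    def test_vertical_bar_consistency(self):
        m = np.zeros((40, 15), bool)
        m[5:35, 5:10] = True
        fs, _ = analyze_mask(m)
        assert fs.maximum_number_of_roots == 1
        assert fs.number_of_root_tips == 2
        assert fs.width_to_depth_ratio == pytest.approx(
            fs.maximum_width / fs.depth)
        assert fs.depth == 30 and fs.maximum_width == 5

    def test_field_count_is_27(self, crown_analysis):
        fs, _, _ = crown_analysis
        assert len([n for n in FEATURE_NAMES if hasattr(fs, n)]) == 27

    def test_invariant_bounds(self, crown_analysis):
        fs, _, _ = crown_analysis
        assert 0.0 <= fs.solidity <= 1.0
        assert fs.median_diameter <= fs.maximum_diameter
        assert 0.0 <= fs.average_root_orientation <= 90.0
        assert fs.depth > 0 and fs.maximum_width > 0
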