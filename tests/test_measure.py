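import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fociquant as fq
from conftest import random_foci_image
from fociquant.foci import FociImage
from oracle_utils import loop_area, loop_count, loop_intensity


def _foci_from_grid(grid):
    grid = np.asarray(grid)
    return FociImage(grid=grid, support=grid > 0)


class TestCountAndArea:
    def test_two_disjoint_blobs(self):
        grid = np.zeros((10, 10), dtype=np.uint16)
        grid[1:4, 1:4] = 5
        grid[6:9, 6:9] = 7
        foci = _foci_from_grid(grid)
        assert fq.count_foci(foci, min_focus_px=1) == 2
        assert fq.total_foci_area(foci, min_focus_px=1) == 18

    def test_diagonal_touch_connectivity_semantics(self):
        grid = np.zeros((8, 8), dtype=np.uint16)
        grid[1:3, 1:3] = 5
        grid[3:5, 3:5] = 5  # touches the first blob only diagonally
        foci = _foci_from_grid(grid)
        assert fq.count_foci(foci, connectivity=8, min_focus_px=1) == 1
        assert fq.count_foci(foci, connectivity=4, min_focus_px=1) == 2

    def test_min_focus_px_filters_small_components(self):
        grid = np.zeros((10, 10), dtype=np.uint16)
        grid[1:4, 1:4] = 9  # 9 px
        grid[7, 7] = 9  # 1 px speck
        foci = _foci_from_grid(grid)
        assert fq.count_foci(foci, min_focus_px=4) == 1
        assert fq.total_foci_area(foci, min_focus_px=4) == 9

    def test_empty_support(self):
        foci = _foci_from_grid(np.zeros((6, 6), dtype=np.uint16))
        assert fq.count_foci(foci) == 0
        assert fq.total_foci_area(foci) == 0
        assert fq.integrate_intensity(foci) == 0

    def test_twelve_separated_spots(self):
        grid = np.zeros((40, 40), dtype=np.uint16)
        k = 0
        for r in range(3, 40, 10):
            for c in range(3, 40, 10):
                if k < 12:
                    grid[r : r + 2, c : c + 2] = 100
                    k += 1
        assert fq.count_foci(_foci_from_grid(grid), min_focus_px=1) == 12

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_images_match_loop_oracles(self, rng, connectivity):
        for _ in range(25):
            foci = random_foci_image(rng, shape=(14, 14))
            assert fq.count_foci(foci, connectivity, min_focus_px=1) == loop_count(
                foci.support, connectivity
            )
            assert fq.total_foci_area(foci, connectivity, min_focus_px=1) == loop_area(
                foci.support, connectivity
            )


class TestIntegrateIntensity:
    def test_three_pixels(self):
        grid = np.zeros((4, 4), dtype=np.uint16)
        grid[0, 0] = grid[1, 2] = grid[3, 3] = 7
        assert fq.integrate_intensity(_foci_from_grid(grid)) == 21

    def test_matches_double_loop_on_random_images(self, rng):
        for _ in range(20):
            foci = random_foci_image(rng, shape=(12, 12))
            assert fq.integrate_intensity(foci) == loop_intensity(foci.grid)

    def test_wide_accumulator_no_overflow(self):
        grid = np.full((512, 512), 65535, dtype=np.uint16)
        total = fq.integrate_intensity(_foci_from_grid(grid))
        assert total == 512 * 512 * 65535  # exceeds 32-bit range


class TestColocRatio:
    def test_red_identical_to_green_is_one(self, rng):
        foci = random_foci_image(rng)
        assert fq.coloc_ratio(foci, foci) == pytest.approx(1.0)

    def test_disjoint_supports_zero(self):
        g = np.zeros((6, 6), dtype=np.uint16)
        r = np.zeros((6, 6), dtype=np.uint16)
        g[0:2, 0:2] = 10
        r[4:6, 4:6] = 10
        assert fq.coloc_ratio(_foci_from_grid(g), _foci_from_grid(r)) == 0.0

    def test_worked_pixel_example(self):
        green = _foci_from_grid(np.array([[0, 10], [20, 0]], dtype=np.uint16))
        red = _foci_from_grid(np.array([[5, 0], [8, 4]], dtype=np.uint16))
        # S_G = {(0,1),(1,0)}; numerator 0 + 8 = 8; denominator 30
        assert fq.coloc_ratio(green, red) == pytest.approx(8 / 30, abs=1e-12)

    def test_empty_green_support_undefined(self):
        g = _foci_from_grid(np.zeros((4, 4), dtype=np.uint16))
        r = _foci_from_grid(np.full((4, 4), 9, dtype=np.uint16))
        assert math.isnan(fq.coloc_ratio(g, r))

    def test_dimension_mismatch_rejected(self):
        g = _foci_from_grid(np.zeros((4, 4), dtype=np.uint16))
        r = _foci_from_grid(np.zeros((5, 4), dtype=np.uint16))
        with pytest.raises(fq.DimensionError):
            fq.coloc_ratio(g, r)

    def test_red_linearity_and_green_intensity_scaling(self, rng):
        """Scaling red by k scales Ra by k; scaling green intensities (same
        support) divides Ra by k."""
        g = random_foci_image(rng, dtype=np.uint16)
        r = random_foci_image(rng, dtype=np.uint16)
        base = fq.coloc_ratio(g, r)
        r3 = FociImage(grid=(r.grid.astype(np.int64) * 3), support=r.support)
        assert fq.coloc_ratio(g, r3) == pytest.approx(3 * base)
        g2 = FociImage(grid=(g.grid.astype(np.int64) * 2), support=g.support)
        assert fq.coloc_ratio(g2, r) == pytest.approx(base / 2)


class TestColocMetrics:
    def test_red_subset_of_green(self):
        g = np.zeros((12, 12), dtype=np.uint16)
        g[2:10, 2:10] = 50
        r = np.zeros((12, 12), dtype=np.uint16)
        r[3:6, 3:6] = 40
        r[7:9, 7:9] = 40
        cc, ca, ra = fq.coloc_metrics(_foci_from_grid(g), _foci_from_grid(r), min_focus_px=4)
        assert cc == fq.count_foci(_foci_from_grid(r), min_focus_px=4)
        assert ca == fq.total_foci_area(_foci_from_grid(r), min_focus_px=4)

    def test_disjoint_gives_zeroes(self):
        g = np.zeros((8, 8), dtype=np.uint16)
        r = np.zeros((8, 8), dtype=np.uint16)
        g[0:3, 0:3] = 10
        r[5:8, 5:8] = 10
        cc, ca, ra = fq.coloc_metrics(_foci_from_grid(g), _foci_from_grid(r))
        assert (cc, ca, ra) == (0, 0, 0.0)

    def test_constructed_scene_four_of_seven_overlap(self):
        g = np.zeros((40, 40), dtype=np.uint16)
        g[0:40, 0:20] = 30  # green covers the left half
        r = np.zeros((40, 40), dtype=np.uint16)
        placed = [(2, 2), (12, 10), (22, 16), (32, 4), (2, 30), (18, 32), (34, 28)]
        for r0, c0 in placed:  # first 4 inside green, last 3 outside
            r[r0 : r0 + 3, c0 : c0 + 3] = 25
        cc, ca, _ = fq.coloc_metrics(_foci_from_grid(g), _foci_from_grid(r), min_focus_px=4)
        assert cc == 4
        assert ca == 4 * 9

    def test_coloc_area_bounded_by_each_support(self, rng):
        g = random_foci_image(rng)
        r = random_foci_image(rng)
        _, ca, _ = fq.coloc_metrics(g, r, min_focus_px=1)
        assert ca <= r.support.sum()
        assert ca <= g.support.sum()


class TestPercentageDifference:
    @pytest.mark.parametrize(
        "d1, d2, expected",
        [
            (27, 30, 11.11),  # foci number
            (637, 462, 37.88),  # total foci area
            (154479, 92493, 67.02),  # integrated intensity
            (46, 43, 6.98),
            (522845, 920712, 76.09),
        ],
    )
    def test_published_two_cell_comparisons(self, d1, d2, expected):
        assert fq.percentage_difference(d1, d2) == pytest.approx(expected, abs=0.01)

    def test_identity_zero(self):
        assert fq.percentage_difference(5.5, 5.5) == 0.0

    def test_nonpositive_min_undefined(self):
        assert math.isnan(fq.percentage_difference(0, 10))
        assert math.isnan(fq.percentage_difference(-1, 10))

    @given(
        st.floats(0.001, 1e9, allow_nan=False),
        st.floats(0.001, 1e9, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, a, b):
        assert fq.percentage_difference(a, b) == fq.percentage_difference(b, a)
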