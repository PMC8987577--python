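"""Cortex segmentation: morphology stages, composition, validation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import oracles
from gliaquant import binarize, cortex
from gliaquant.cortex import SegmentationParams
from gliaquant.synth import FixtureSpec, generate_plane

bool_masks = hnp.arrays(bool, (16, 16), elements=st.booleans())


class TestMergeMasks:
    def test_disjoint_union(self):
        a = np.zeros((30, 30), bool)
        b = np.zeros((30, 30), bool)
        a[:10, :10] = True  # 100 px
        b[15:25, 5:25] = True  # 200 px
        assert cortex.merge_masks(a, b).sum() == 300

    def test_idempotent_and_identity(self):
        a = np.zeros((10, 10), bool)
        a[2:6, 2:6] = True
        np.testing.assert_array_equal(cortex.merge_masks(a, a), a)
        np.testing.assert_array_equal(cortex.merge_masks(a, np.zeros_like(a)), a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cortex.merge_masks(np.zeros((5, 5), bool), np.zeros((6, 6), bool))


class TestDilationFill:
    def test_uniform_masks_unchanged(self):
        empty = np.zeros((20, 20), bool)
        full = np.ones((20, 20), bool)
        np.testing.assert_array_equal(cortex.dilation_fill(empty, 4, 0.1), empty)
        np.testing.assert_array_equal(cortex.dilation_fill(full, 4, 0.1), full)

    @pytest.mark.parametrize("n,thresh", [(2, 0.1), (4, 0.1), (4, 0.25)])
    def test_matches_brute_force_oracle(self, rng, n, thresh):
        for _ in range(5):
            mask = rng.random((24, 24)) < 0.35
            np.testing.assert_array_equal(
                cortex.dilation_fill(mask, n, thresh),
                oracles.dilation_fill(mask, n, thresh),
            )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(mask=bool_masks)
    def test_output_superset_of_input(self, mask):
        out = cortex.dilation_fill(mask, 3, 0.2)
        assert not (mask & ~out).any()


class TestFillHoles:
    @staticmethod
    def _ring(outer, inner_side):
        mask = np.ones((outer, outer), bool)
        lo = (outer - inner_side) // 2
        mask[lo : lo + inner_side, lo : lo + inner_side] = False
        padded = np.zeros((outer + 4, outer + 4), bool)
        padded[2:-2, 2:-2] = mask
        return padded

    def test_small_hole_filled(self):
        ring = self._ring(20, 10)  # 100-px hole
        out = cortex.fill_holes(ring, 5000)
        assert out[12, 12] and out.sum() == ring.sum() + 100

    def test_large_hole_preserved(self):
        ring = self._ring(90, 78)  # 6084-px hole >= 5000
        out = cortex.fill_holes(ring, 5000)
        np.testing.assert_array_equal(out, ring)

    def test_border_bay_untouched(self):
        mask = np.ones((20, 20), bool)
        mask[0:10, 8:12] = False  # bay open to the top border
        np.testing.assert_array_equal(cortex.fill_holes(mask, 5000), mask)

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((24, 24)) < 0.55
            np.testing.assert_array_equal(
                cortex.fill_holes(mask, 12), oracles.fill_holes(mask, 12)
            )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(mask=bool_masks)
    def test_output_superset_of_input(self, mask):
        out = cortex.fill_holes(mask, 10)
        assert not (mask & ~out).any()


class TestErode:
    def test_single_pixel_vanishes(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert not cortex.erode(mask, 1).any()

    def test_block_shrinks_to_interior(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        out = cortex.erode(mask, 1)
        expected = np.zeros((9, 9), bool)
        expected[3:6, 3:6] = True
        np.testing.assert_array_equal(out, expected)

    def test_zero_iterations_identity(self, rng):
        mask = rng.random((12, 12)) < 0.5
        np.testing.assert_array_equal(cortex.erode(mask, 0), mask)

    def test_border_counts_as_background(self):
        full = np.ones((6, 6), bool)
        out = cortex.erode(full, 1)
        assert out.sum() == 16 and out[1:-1, 1:-1].all()

    @pytest.mark.parametrize("k,i", [(7, 1), (7, 2), (7, 3), (7, 4), (10, 3)])
    def test_square_area_law(self, k, i):
        mask = np.zeros((k + 4, k + 4), bool)
        mask[2 : 2 + k, 2 : 2 + k] = True
        expected = (k - 2 * i) ** 2 if k > 2 * i else 0
        assert cortex.erode(mask, i).sum() == expected

    def test_matches_per_pixel_oracle(self, rng):
        for _ in range(5):
            mask = rng.random((24, 24)) < 0.6
            np.testing.assert_array_equal(cortex.erode(mask, 2), oracles.erode(mask, 2))


class TestSegmentCortex:
    def test_empty_inputs_give_empty_cortex(self):
        empty = np.zeros((64, 64), bool)
        seg = cortex.segment_cortex(empty, empty)
        assert seg.area == 0

    def test_solid_rectangle_shrinks_by_erosions(self):
        cg = np.zeros((60, 60), bool)
        cg[10:50, 10:50] = True
        params = SegmentationParams(n=3, thresh=0.6, hole_size=10, erosions=2)
        seg = cortex.segment_cortex(cg, np.zeros_like(cg), params)
        expected = np.zeros((60, 60), bool)
        expected[12:48, 12:48] = True
        np.testing.assert_array_equal(seg.mask, expected)

    def test_fixture_recovery_at_default_params(self):
        spec = FixtureSpec(noise_sd=0.0, blur_sigma=0.0, globularity=0.0, seed=11)
        channels, truth = generate_plane(spec)
        cg, _ = binarize.select_threshold(channels[1], "cortex_glia")
        nuclei, _ = binarize.select_threshold(channels[2], "nuclei")
        seg = cortex.segment_cortex(cg, nuclei)
        metrics = cortex.overlap_metrics(seg.mask, truth.cortex_mask)
        assert metrics.ol_m >= 85.0 and metrics.ol_a >= 85.0


class TestOverlapMetrics:
    def test_identical_masks(self):
        mask = np.zeros((40, 40), bool)
        mask[5:25, 5:30] = True
        m = cortex.overlap_metrics(mask, mask)
        assert m.ol_m == 100.0 and m.ol_a == 100.0

    def test_subset_arithmetic(self):
        manual = np.zeros((40, 40), bool)
        manual[0:20, 0:25] = True  # 500 px
        auto = np.zeros((40, 40), bool)
        auto[0:10, 0:25] = True  # 250 px, subset
        m = cortex.overlap_metrics(auto, manual)
        assert m.ol_m == 50.0 and m.ol_a == 100.0
        assert m.overlap_px <= min(m.manual_px, m.auto_px)

    def test_disjoint_masks(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[:5, :5] = True
        b[10:, 10:] = True
        m = cortex.overlap_metrics(a, b)
        assert m.ol_m == 0.0 and m.ol_a == 0.0

    def test_empty_inputs_rejected(self):
        full = np.ones((10, 10), bool)
        with pytest.raises(ValueError, match="manual"):
            cortex.overlap_metrics(full, np.zeros((10, 10), bool))
        with pytest.raises(ValueError, match="automated"):
            cortex.overlap_metrics(np.zeros((10, 10), bool), full)

    def test_symmetric_iff_equal_area(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True
        b[5:15, 5:15] = True  # equal areas, partial overlap
        m1 = cortex.overlap_metrics(a, b)
        m2 = cortex.overlap_metrics(b, a)
        assert m1.ol_m == m2.ol_m == m1.ol_a == m2.ol_a


class TestGridSearch:
    def test_exact_recovery_scores_100(self):
        cg = np.zeros((40, 40), bool)
        cg[8:32, 8:32] = True
        params = SegmentationParams(n=2, thresh=0.5, hole_size=10, erosions=1)
        manual = cortex.segment_cortex(cg, np.zeros_like(cg), params).mask
        grid = {"n": [2], "thresh": [0.5], "hole_size": [10], "erosions": [1]}
        table = cortex.parameter_grid_search([(cg, np.zeros_like(cg), manual)], grid)
        assert len(table) == 1
        assert table.iloc[0]["mean_ol_m"] == 100.0
        assert table.iloc[0]["mean_ol_a"] == 100.0

    def test_dominant_combination_ranked_first(self):
        # over-eroding provably destroys overlap with the true mask
        cg = np.zeros((40, 40), bool)
        cg[5:35, 5:35] = True
        true_params = SegmentationParams(n=2, thresh=0.5, hole_size=10, erosions=1)
        manual = cortex.segment_cortex(cg, np.zeros_like(cg), true_params).mask
        grid = {"n": [2], "thresh": [0.5], "hole_size": [10], "erosions": [1, 8, 14]}
        table = cortex.parameter_grid_search([(cg, np.zeros_like(cg), manual)], grid)
        assert table.iloc[0]["erosions"] == 1
        assert table["mean_ol_m"].is_monotonic_decreasing
        assert bool(table.iloc[0]["pareto"])

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="missing"):
            cortex.parameter_grid_search(
                [(np.ones((5, 5), bool),) * 3], {"n": [2]}
            )
        with pytest.raises(ValueError, match="image"):
            cortex.parameter_grid_search([], None)
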