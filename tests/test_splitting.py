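import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from nucleisplit import (
    ObjectCrop,
    build_saliency,
    clustered_fixture,
    distance_map,
    extract_large_objects,
    fill_small_holes,
    normalize_unit,
    quantize_and_clean,
    split_clusters,
    split_object,
)
from nucleisplit.splitting import _n_levels

import oracles


class TestFillSmallHoles:
    def test_fills_below_mean_keeps_above(self):
        fx = clustered_fixture("small_holes")
        filled = fill_small_holes(fx["mask"])
        for y, x in fx["small_holes"]:
            assert filled[y, x]
        assert (~filled[28:31, 26:29]).all()  # the big hole survives

    def test_single_hole_is_kept(self):
        mask = np.ones((9, 9), dtype=bool)
        mask[4, 4] = False
        filled = fill_small_holes(mask)
        assert not filled[4, 4]  # size not strictly below the mean of itself

    def test_hole_free_mask_unchanged(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        np.testing.assert_array_equal(fill_small_holes(mask), mask)

    def test_filling_raises_distance_peak(self):
        fx = clustered_fixture("small_holes")
        before = distance_map(fx["mask"]).max()
        after = distance_map(fill_small_holes(fx["mask"])).max()
        assert after > before


class TestExtractLargeObjects:
    def test_size_threshold_strict(self):
        B = np.zeros((30, 30), dtype=bool)
        B[1:6, 1:9] = True   # 40 px
        B[15:21, 10:20] = True  # 60 px
        crops, _ = extract_large_objects(B, omega_min=50)
        assert len(crops) == 1 and crops[0].size == 60

    def test_tight_bounding_box(self):
        B = np.zeros((20, 20), dtype=bool)
        B[3:10, 5:13] = True
        crops, _ = extract_large_objects(B, omega_min=10)
        assert crops[0].offset == (3, 5)
        assert crops[0].mask.shape == (7, 8)
        # the object touches every face of its box
        m = crops[0].mask
        assert m[0].any() and m[-1].any() and m[:, 0].any() and m[:, -1].any()

    def test_empty_mask_gives_no_crops(self):
        crops, lab = extract_large_objects(np.zeros((5, 5), dtype=bool), omega_min=1)
        assert crops == [] and lab.max() == 0


class TestDistanceMap:
    def test_strip_distances(self):
        mask = np.zeros((3, 7), dtype=bool)
        mask[1, 1:6] = True
        d = distance_map(mask)
        np.testing.assert_allclose(d[1, 1:6], [1, 1, 1, 1, 1])  # row above/below is bg

    def test_1d_strip_profile(self):
        mask = np.ones(5, dtype=bool)  # frame edge counts as background
        np.testing.assert_allclose(distance_map(mask), [1, 2, 3, 2, 1])

    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        assert distance_map(mask)[1, 1] == 1.0

    def test_disk_peaks_at_center(self):
        yy, xx = np.indices((21, 21))
        mask = (yy - 10) ** 2 + (xx - 10) ** 2 <= 64
        d = distance_map(mask)
        assert np.unravel_index(d.argmax(), d.shape) == (10, 10)

    def test_agrees_with_allpairs_search(self, rng):
        for _ in range(8):
            mask = rng.random((16, 16)) < 0.5
            np.testing.assert_allclose(
                distance_map(mask), oracles.distance_map_bruteforce(mask), atol=1e-9
            )

    def test_3d_agrees_with_allpairs_search(self, rng):
        mask = rng.random((6, 8, 8)) < 0.5
        np.testing.assert_allclose(
            distance_map(mask), oracles.distance_map_bruteforce(mask), atol=1e-9
        )


class TestNormalize:
    def test_simple_triplet(self):
        np.testing.assert_allclose(normalize_unit(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])

    def test_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize_unit(np.full(5, 3.3)), np.zeros(5))

    @settings(deadline=None, max_examples=50)
    @given(
        hnp.arrays(
            float,
            hnp.array_shapes(min_dims=1, max_dims=2, max_side=20),
            elements=st.floats(0, 1e6, allow_nan=False),
        )
    )
    def test_range_contract(self, A):
        out = normalize_unit(A)
        if A.max() > A.min():
            assert out.min() == 0.0 and out.max() == 1.0
        else:
            assert (out == 0).all()
        assert out.shape == A.shape


class TestSaliency:
    def test_uniform_intensity_reduces_to_negative_distance(self):
        yy, xx = np.indices((15, 15))
        mask = (yy - 7) ** 2 + (xx - 7) ** 2 <= 25
        crop = ObjectCrop(mask, np.full(mask.shape, 0.4), (0, 0), int(mask.sum()))
        S = build_saliency(crop)
        np.testing.assert_allclose(S, -normalize_unit(distance_map(mask)))
        assert np.unravel_index(S.argmin(), S.shape) == (7, 7)

    def test_dumbbell_has_one_minimum_per_lobe(self):
        fx = clustered_fixture("dumbbell")
        mask = fx["mask"]
        crop = ObjectCrop(mask, np.full(mask.shape, 0.5), (0, 0), int(mask.sum()))
        S = build_saliency(crop)
        left = S[:, :10][mask[:, :10]]
        neckv = S[5, 10]
        assert left.min() < neckv and S[:, 11:][mask[:, 11:]].min() < neckv

    def test_intensity_valleys_create_minima_on_flat_distance_ridge(self, valley_clump):
        mask = valley_clump["mask"]
        img = valley_clump["image"].data
        sl = np.s_[10:31, 4:73]
        crop = ObjectCrop(mask[sl], img[sl], (10, 4), int(mask[sl].sum()))
        S = build_saliency(crop)
        D = -normalize_unit(distance_map(crop.mask))
        # the intensity term at least doubles the valley modulation that the
        # distance term alone leaves along the clump's interior spine
        spine_D = D[10, 10:59]
        spine_S = S[10, 10:59]
        assert np.ptp(spine_D) < 0.5 * np.ptp(spine_S)
        # and S dips at every one of the five nucleus centers
        centers = [10, 22, 34, 46, 58]
        mids = [16, 28, 40, 52]
        assert max(S[10, c] for c in centers) < min(S[10, m] for m in mids)


class TestQuantizeAndSplit:
    def test_level_count_formula_floor(self):
        assert _n_levels(51, 50) == 2
        assert _n_levels(500, 50) == 6
        assert _n_levels(10_000, 50) == 10

    def test_no_small_pieces_survive_cleaning(self, valley_clump):
        mask = valley_clump["mask"]
        img = valley_clump["image"].data
        crop = ObjectCrop(mask, img, (0, 0), int(mask.sum()))
        S = build_saliency(crop)
        q = quantize_and_clean(S, crop, omega_min=50)
        from skimage.measure import label as cc_label

        floor_unit = int(np.ceil(0.1 * 50))
        n_levels = q.max() + 1
        for level in range(n_levels - 1):
            pieces = cc_label(q == level, connectivity=2)
            for pid in range(1, pieces.max() + 1):
                assert (pieces == pid).sum() >= (level + 1) * floor_unit

    def test_single_minimum_landscape_gives_one_label(self):
        yy, xx = np.indices((15, 15))
        mask = (yy - 7) ** 2 + (xx - 7) ** 2 <= 25
        crop = ObjectCrop(mask, np.full(mask.shape, 0.4), (0, 0), int(mask.sum()))
        q = quantize_and_clean(build_saliency(crop), crop, omega_min=20)
        labels = split_object(q, crop)
        assert labels.max() == 1
        np.testing.assert_array_equal(labels > 0, mask)

    def test_dumbbell_splits_into_two(self):
        fx = clustered_fixture("dumbbell")
        mask = fx["mask"]
        crop = ObjectCrop(mask, np.full(mask.shape, 0.5), (0, 0), int(mask.sum()))
        q = quantize_and_clean(build_saliency(crop), crop, omega_min=30)
        labels = split_object(q, crop)
        assert labels.max() == 2
        np.testing.assert_array_equal(labels > 0, mask)


class TestSplitClusters:
    def test_pixel_conservation(self, small_scene):
        from nucleisplit import global_binarize, build_watershed_regions, local_threshold

        img = small_scene["image"]
        G = global_binarize(img)
        B = local_threshold(img, build_watershed_regions(G), G, 50)
        R = split_clusters(img, B, 50)
        np.testing.assert_array_equal(R > 0, fill_small_holes(B))

    def test_intensity_term_needed_for_gapless_clumps(self, valley_clump):
        with_i = split_clusters(valley_clump["image"], valley_clump["mask"], 50)
        without = split_clusters(
            valley_clump["image"], valley_clump["mask"], 50, use_intensity=False
        )
        assert with_i.max() == valley_clump["n_true"]
        assert without.max() < valley_clump["n_true"]

    def test_labels_are_connected_and_disjoint(self, valley_clump):
        from skimage.measure import label as cc_label

        R = split_clusters(valley_clump["image"], valley_clump["mask"], 50)
        for i in range(1, R.max() + 1):
            assert cc_label(R == i, connectivity=2).max() == 1

    def test_empty_mask_gives_empty_labels(self):
        R = split_clusters(np.full((10, 10), 0.5), np.zeros((10, 10), bool), 10)
        assert R.max() == 0
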