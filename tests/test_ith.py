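"""ITH branch: slice selection, per-pixel features, clustering, score axioms."""

import numpy as np
import pytest

from dpetfusion.io import RoiMask, Volume
from dpetfusion.ith import (
    cluster_pixels,
    fit_ith_model,
    ith_for_case,
    ith_score,
    pixel_feature_names,
    pixel_features,
    pixel_features_reference,
    select_max_slice,
)


class TestSelectMaxSlice:
    def test_max_area_with_tie_break(self):
        mask = np.zeros((4, 6, 6))
        mask[0, :5, 0] = 1  # area 5
        mask[1, :3, :3] = 1  # area 9
        mask[2, 3:, 3:] = 1  # area 9 (tie)
        mask[3, :3, 0] = 1  # area 3
        vol = Volume(np.random.default_rng(0).random((4, 6, 6)))
        _, _, idx = select_max_slice(vol, RoiMask(mask))
        assert idx == 1  # ties broken by lowest index

    def test_single_slice_mask(self):
        mask = np.zeros((3, 5, 5))
        mask[2, 1:4, 1:4] = 1
        _, m2d, idx = select_max_slice(Volume(np.ones((3, 5, 5))), RoiMask(mask))
        assert idx == 2 and m2d.sum() == 9

    def test_invariant_to_intensities(self, rng):
        mask = np.zeros((3, 5, 5))
        mask[1, :, :] = 1
        for _ in range(3):
            vol = Volume(rng.random((3, 5, 5)))
            assert select_max_slice(vol, RoiMask(mask))[2] == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            select_max_slice(Volume(np.ones((3, 5, 5))), RoiMask(np.zeros((3, 5, 5))))


class TestPixelFeatures:
    def test_dimension_is_104(self, rng):
        img = rng.normal(size=(8, 8))
        mask = np.ones((8, 8), bool)
        fmap = pixel_features(img, mask)
        assert fmap.features.shape == (64, 104)
        assert len(pixel_feature_names()) == 104

    def test_constant_image_interior_vectors_identical(self):
        img = np.full((7, 7), 4.0)
        mask = np.ones((7, 7), bool)
        fmap = pixel_features(img, mask)
        interior = [
            i for i, (r, c) in enumerate(fmap.pixels) if 1 <= r <= 5 and 1 <= c <= 5
        ]
        block = fmap.features[interior]
        assert np.ptp(block, axis=0).max() == 0.0
        # all texture contrasts vanish on a constant image
        contrast_idx = fmap.names.index("glcm|Contrast")
        np.testing.assert_array_equal(fmap.features[:, contrast_idx], 0.0)

    def test_window_mean_max_hand_oracle(self):
        img = np.arange(25.0).reshape(5, 5)
        mask = np.ones((5, 5), bool)
        fmap = pixel_features(img, mask)
        center = [i for i, p in enumerate(fmap.pixels) if tuple(p) == (2, 2)][0]
        window = img[1:4, 1:4]
        assert fmap.features[center, fmap.names.index("firstorder|Mean")] == pytest.approx(window.mean())
        assert fmap.features[center, fmap.names.index("firstorder|Maximum")] == window.max()
        assert fmap.features[center, fmap.names.index("firstorder|Minimum")] == window.min()

    def test_batched_equals_reference_implementation(self, rng):
        img = rng.normal(size=(9, 11)) * 5 + 20
        mask = rng.random((9, 11)) > 0.35
        mask[4, 5] = True
        if mask.sum() < 9:
            mask[:3, :3] = True
        fast = pixel_features(img, mask)
        ref = pixel_features_reference(img, mask)
        np.testing.assert_allclose(fast.features, ref.features, rtol=1e-8, atol=1e-10)

    def test_small_mask_rejected(self):
        with pytest.raises(ValueError):
            pixel_features(np.ones((4, 4)), np.eye(4, dtype=bool))


class TestClusterPixels:
    def test_two_homogeneous_halves_recovered(self, rng):
        # halves differ in texture (flat vs coarse checkerboard), the masked
        # boundary column keeps every window purely one-sided: two separated
        # feature clouds whose interior pixels must split along the halves
        img = np.full((10, 11), 2.0)
        zz, yy = np.indices((10, 11))
        img[:, 6:] = 20.0 + 18.0 * ((zz[:, 6:] + yy[:, 6:]) % 2)
        img += rng.normal(0, 0.05, (10, 11))
        mask = np.ones((10, 11), bool)
        mask[:, 5] = False
        fmap = pixel_features(img, mask)
        label_map, k, _ = cluster_pixels(fmap, k=2, seed=0)
        left = label_map[1:9, 1:4].ravel()
        right = label_map[1:9, 7:10].ravel()
        assert len(set(left)) == 1 and len(set(right)) == 1
        assert left[0] != right[0]

    def test_k_equals_n_gives_singletons(self, rng):
        img = rng.normal(size=(3, 3))
        mask = np.ones((3, 3), bool)
        fmap = pixel_features(img, mask)
        label_map, k, _ = cluster_pixels(fmap, k=9, seed=0)
        assert len(np.unique(label_map[label_map > 0])) == 9

    def test_seeded_reproducibility(self, rng):
        img = rng.normal(size=(8, 8))
        mask = np.ones((8, 8), bool)
        fmap = pixel_features(img, mask)
        a, _, _ = cluster_pixels(fmap, seed=5)
        b, _, _ = cluster_pixels(fmap, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_more_clusters_than_pixels_rejected(self, rng):
        img = rng.normal(size=(4, 4))
        fmap = pixel_features(img, np.ones((4, 4), bool))
        with pytest.raises(ValueError):
            cluster_pixels(fmap, k=50, seed=0)


class TestIthScore:
    def test_single_cluster_single_component_zero(self):
        m = np.zeros((6, 6), int)
        m[1:5, 1:5] = 1
        assert ith_score(m).ith_score == 0.0

    def test_one_cluster_two_equal_components_half(self):
        m = np.zeros((5, 7), int)
        m[1:4, 0:2] = 1
        m[1:4, 5:7] = 1  # two 6-pixel components, 4-disconnected
        r = ith_score(m)
        assert r.ith_score == pytest.approx(0.5)
        assert r.component_counts[0] == 2

    def test_two_single_component_clusters_zero(self):
        m = np.zeros((6, 6), int)
        m[:3, :] = 1
        m[3:, :] = 2
        assert ith_score(m).ith_score == 0.0

    def test_diagonal_touch_counts_as_disconnected(self):
        # 4-connectivity: diagonal neighbours are separate components
        m = np.zeros((4, 4), int)
        m[0, 0] = 1
        m[1, 1] = 1
        r = ith_score(m)
        assert r.component_counts[0] == 2
        assert r.ith_score == pytest.approx(0.5)

    def test_fragmentation_never_decreases_score(self):
        base = np.zeros((6, 12), int)
        base[1:5, 1:11] = 1
        base[1:5, 1:3] = 2
        s0 = ith_score(base).ith_score
        frag = base.copy()
        frag[:, 6] = 0  # split cluster 1's largest component in two
        s1 = ith_score(frag).ith_score
        assert s1 >= s0

    def test_invariant_to_cluster_relabeling(self, rng):
        m = rng.integers(0, 4, size=(8, 8))
        relabeled = np.where(m > 0, 4 - m, 0)
        assert ith_score(m).ith_score == pytest.approx(ith_score(relabeled).ith_score)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            ith_score(np.zeros((4, 4), int))


class TestIthModel:
    def test_scores_equal_labels_auc_one(self):
        y = np.array([0, 1] * 20)
        _, a, _ = fit_ith_model(y + np.random.default_rng(0).normal(0, 0.01, 40), y)
        assert a > 0.99

    def test_label_independent_scores_near_chance(self, rng):
        scores = rng.random(200)
        y = rng.integers(0, 2, 200)
        _, a, p = fit_ith_model(scores, y)
        assert 0.4 <= a <= 0.6
        assert p > 0.001

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(60)
        y = rng.integers(0, 2, 60)
        _, a1, p1 = fit_ith_model(scores, y)
        _, a2, p2 = fit_ith_model(np.exp(3 * scores), y)
        assert a1 == pytest.approx(a2)
        assert p1 == pytest.approx(p2)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_ith_model(np.ones(20), np.array([0, 1] * 10))


def test_full_case_chain_in_unit_interval(synthetic_case):
    r = ith_for_case(synthetic_case.volume, synthetic_case.mask, seed=0)
    assert 0.0 <= r.ith_score < 1.0
    assert r.area_fractions.sum() == pytest.approx(1.0)
    assert r.k >= 2
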