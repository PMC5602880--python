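import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from nucfuse.image import SeedSet, TwoChannelImage
from nucfuse.segment import (
    ConstantImageError,
    FusionParams,
    binarize,
    detect_seeds,
    distance_map,
    filter_regions,
    fuse_channels,
    merge_seeds,
    otsu_threshold,
    split_clusters,
)

from conftest import disk_mask


# ---------------------------------------------------------------------------
# fusion


class TestFuseChannels:
    def test_worked_example(self):
        img = TwoChannelImage(
            green=np.array([[100, 0], [100, 0]]),
            red=np.array([[50, 80], [60, 0]]),
            P=200.0,
        )
        fused, i_b = fuse_channels(img, FusionParams(0.6, 0.4))
        np.testing.assert_array_equal(i_b, [[1, 0], [1, 0]])
        np.testing.assert_allclose(fused, [[170.0, 0.0], [180.0, 0.0]])

    def test_zero_red_reduces_to_scaled_green(self):
        img = TwoChannelImage(
            green=np.array([[10.0, 50.0], [90.0, 5.0]]),
            red=np.zeros((2, 2)),
            P=100.0,
        )
        fused, _ = fuse_channels(img)
        np.testing.assert_allclose(fused, img.green * (100.0 * 0.6 / 90.0))

    def test_red_masked_outside_green_foreground(self):
        green = np.array([[100, 0], [100, 0]], dtype=float)
        red = np.array([[0, 999], [0, 999]], dtype=float)
        img = TwoChannelImage(green=green, red=red, P=1000.0)
        fused, i_b = fuse_channels(img)
        assert i_b[0, 1] == 0 and fused[0, 1] == 0.0

    def test_all_zero_green_raises(self):
        img = TwoChannelImage(green=np.zeros((4, 4)), red=np.ones((4, 4)) * 5, P=10.0)
        with pytest.raises(ValueError):
            fuse_channels(img)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_fusion_linearity(self, scale):
        rng = np.random.default_rng(0)
        green = rng.uniform(0, 100, (16, 16))
        green[:8] += 150  # bimodal so Otsu is stable under scaling
        red = rng.uniform(0, 80, (16, 16))
        a, ba = fuse_channels(TwoChannelImage(green=green, red=red, P=300.0))
        b, bb = fuse_channels(
            TwoChannelImage(green=green * scale, red=red * scale, P=300.0 * scale)
        )
        np.testing.assert_array_equal(ba, bb)
        np.testing.assert_allclose(b, a * scale, rtol=1e-9)


# ---------------------------------------------------------------------------
# Otsu


def brute_force_otsu(values: np.ndarray) -> float:
    """Oracle: exhaustive between-class-variance maximization over integer
    cut points, computed straight from the pixel values."""
    values = values.ravel().astype(float)
    best_t, best_v = None, -1.0
    for t in range(int(values.min()), int(values.max())):
        lo = values[values <= t]
        hi = values[values > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return float(best_t)


class TestOtsu:
    def test_two_level_image(self):
        img = np.array([10] * 50 + [200] * 50)
        t = otsu_threshold(img)
        assert 10 <= t < 200

    def test_matches_exhaustive_oracle_on_random_8bit(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            img = np.concatenate(
                [
                    rng.integers(0, 120, rng.integers(20, 200)),
                    rng.integers(100, 256, rng.integers(20, 200)),
                ]
            ).astype(np.uint8)
            if img.min() == img.max():
                continue
            assert otsu_threshold(img) == brute_force_otsu(img)

    def test_bimodal_gaussian_misclassification_below_1pct(self):
        rng = np.random.default_rng(7)
        lo = rng.normal(50, 10, 5000)
        hi = rng.normal(180, 10, 5000)
        img = np.clip(np.concatenate([lo, hi]), 0, 255).astype(np.uint8)
        t = otsu_threshold(img)
        wrong = (lo > t).sum() + (hi <= t).sum()
        assert wrong / img.size < 0.01

    def test_constant_image_raises(self):
        with pytest.raises(ConstantImageError):
            otsu_threshold(np.full((5, 5), 7))


class TestBinarize:
    def test_stationary_scene_local_equals_global(self):
        img = np.full((120, 120), 10.0)
        for c in ((30, 30), (80, 80)):
            img[disk_mask(img.shape, c, 12)] = 200.0
        g = binarize(img, window=701)
        local = binarize(img, window=61, fg_bounds=(1.1, 1.2))  # force local path
        np.testing.assert_array_equal(g, local)

    def test_shaded_scene_recovered_by_local(self):
        rng = np.random.default_rng(0)
        truth = np.zeros((200, 200), dtype=bool)
        for c in ((40, 40), (40, 160), (160, 40), (160, 160), (100, 100)):
            truth[disk_mask(truth.shape, c, 12)] = True
        shading = np.linspace(0, 400, 200)[None, :] * np.ones((200, 1))
        img = np.where(truth, 180.0, 10.0) + shading + rng.normal(0, 2, truth.shape)
        t = np.nan
        from nucfuse.segment import global_otsu_failed, otsu_threshold as ot

        assert global_otsu_failed(img, ot(img))
        mask = binarize(img, window=81)
        recovered = (mask.astype(bool) & truth).sum() / truth.sum()
        assert recovered >= 0.95

    def test_all_background_gives_empty_mask(self):
        assert binarize(np.zeros((30, 30)), window=9).sum() == 0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((10, 10)), window=8)


# ---------------------------------------------------------------------------
# distance map


def brute_force_distance(mask: np.ndarray) -> np.ndarray:
    """Oracle: O(n^2) scan for the nearest zero pixel."""
    zeros = np.argwhere(mask == 0)
    out = np.zeros(mask.shape, dtype=float)
    for r, c in np.argwhere(mask != 0):
        out[r, c] = np.sqrt(((zeros - (r, c)) ** 2).sum(axis=1).min())
    return out


class TestDistanceMap:
    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        assert distance_map(m)[2, 2] == 1.0

    def test_square_center(self):
        m = np.zeros((13, 13), dtype=np.uint8)
        m[1:12, 1:12] = 1  # 11x11 solid square, zeros on the border
        assert distance_map(m)[6, 6] == 6.0

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = (rng.random((32, 32)) < 0.6).astype(np.uint8)
            m[0, 0] = 0
            np.testing.assert_allclose(distance_map(m), brute_force_distance(m))

    def test_all_ones_raises(self):
        with pytest.raises(ValueError):
            distance_map(np.ones((4, 4), dtype=np.uint8))

    def test_lipschitz_property(self):
        rng = np.random.default_rng(5)
        m = (rng.random((24, 24)) < 0.7).astype(np.uint8)
        m[0] = 0
        D = distance_map(m)
        assert np.all(np.abs(np.diff(D, axis=0)) <= 1.0 + 1e-9)
        assert np.all(np.abs(np.diff(D, axis=1)) <= 1.0 + 1e-9)


# ---------------------------------------------------------------------------
# seeds


def dumbbell_mask(separation: int = 20, radius: int = 30) -> np.ndarray:
    """Two overlapping disks; the separation controls the neck depth."""
    m = np.zeros((140, 220), dtype=bool)
    m |= disk_mask(m.shape, (70, 80), radius)
    m |= disk_mask(m.shape, (70, 80 + separation), radius)
    return m.astype(np.uint8)


class TestDetectSeeds:
    def test_single_disk_one_seed_near_center(self):
        m = disk_mask((64, 64), (32, 32), 20).astype(np.uint8)
        seeds = detect_seeds(distance_map(m), sigma=2)
        assert len(seeds) == 1
        assert abs(seeds.locations[0][0] - 32) <= 1
        assert abs(seeds.locations[0][1] - 32) <= 1

    def test_two_disjoint_disks_two_seeds(self):
        m = (
            disk_mask((64, 128), (32, 32), 15) | disk_mask((64, 128), (32, 96), 15)
        ).astype(np.uint8)
        seeds = detect_seeds(distance_map(m), sigma=2)
        assert len(seeds) == 2

    def test_dumbbell_two_seeds_before_merge(self):
        seeds = detect_seeds(distance_map(dumbbell_mask()), sigma=2)
        assert len(seeds) == 2

    def test_empty_foreground(self):
        assert len(detect_seeds(np.zeros((10, 10)), sigma=1)) == 0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            detect_seeds(np.zeros((5, 5)), sigma=-1)


class TestMergeSeeds:
    def _map_with_line(self, v_a, v_b, v_neck):
        D = np.zeros((11, 21))
        D[5, :] = v_neck
        D[5, 2] = v_a
        D[5, 18] = v_b
        return D

    def test_qualifying_pair_merges_to_midpoint(self):
        D = self._map_with_line(10.0, 8.0, 7.5)
        seeds = SeedSet([(5, 2), (5, 18)], [10.0, 8.0])
        out = merge_seeds(seeds, D, r=0.928)  # 7.5 > 8*0.928 = 7.424
        assert len(out) == 1
        assert out.locations[0] == (5, 10)

    def test_non_qualifying_pair_kept(self):
        D = self._map_with_line(10.0, 8.0, 7.0)
        seeds = SeedSet([(5, 2), (5, 18)], [10.0, 8.0])
        out = merge_seeds(seeds, D, r=0.928)  # 7.0 < 7.424
        assert len(out) == 2

    def test_strict_inequality_at_r_equal_one(self):
        D = self._map_with_line(8.0, 8.0, 8.0)
        seeds = SeedSet([(5, 2), (5, 18)], [8.0, 8.0])
        assert len(merge_seeds(seeds, D, r=1.0)) == 2

    def test_monotone_in_r(self):
        rng = np.random.default_rng(11)
        m = dumbbell_mask(6)
        D = distance_map(m)
        smoothed = ndimage.gaussian_filter(D, 2.0)
        seeds = detect_seeds(D, sigma=2)
        counts = [
            len(merge_seeds(seeds, smoothed, r=r)) for r in (0.5, 0.7, 0.9, 0.99, 1.0)
        ]
        assert counts == sorted(counts)

    def test_bad_r_rejected(self):
        with pytest.raises(ValueError):
            merge_seeds(SeedSet([], []), np.zeros((3, 3)), r=0.0)


class TestSplitClusters:
    def test_one_seed_takes_whole_blob(self):
        m = disk_mask((40, 40), (20, 20), 12).astype(np.uint8)
        D = distance_map(m)
        seeds = SeedSet([(20, 20)], [float(D[20, 20])])
        labels = split_clusters(m, seeds, D)
        np.testing.assert_array_equal(labels > 0, m.astype(bool))
        assert labels.max() == 1

    def test_two_overlapping_disks_balanced_split(self):
        m = (
            disk_mask((70, 100), (35, 35), 20) | disk_mask((70, 100), (35, 65), 20)
        ).astype(np.uint8)
        D = distance_map(m)
        seeds = SeedSet([(35, 35), (35, 65)], [float(D[35, 35]), float(D[35, 65])])
        labels = split_clusters(m, seeds, D)
        a1 = (labels == labels[35, 35]).sum()
        a2 = (labels == labels[35, 65]).sum()
        assert labels.max() == 2
        assert abs(a1 - a2) / max(a1, a2) < 0.05

    def test_three_chained_disks(self):
        centers = [(30, 30), (30, 60), (30, 90)]
        m = np.zeros((60, 120), dtype=bool)
        for c in centers:
            m |= disk_mask(m.shape, c, 18)
        D = distance_map(m.astype(np.uint8))
        seeds = SeedSet(centers, [float(D[c]) for c in centers])
        labels = split_clusters(m.astype(np.uint8), seeds, D)
        assert labels.max() == 3
        assert len({labels[c] for c in centers}) == 3

    def test_partition_properties(self):
        m = dumbbell_mask()
        D = distance_map(m)
        seeds = detect_seeds(D, sigma=2)
        labels = split_clusters(m, seeds, D)
        assert set(np.unique(labels)) == set(range(len(seeds) + 1))
        np.testing.assert_array_equal(labels > 0, m.astype(bool))

    def test_seed_on_background_raises(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[4:7, 4:7] = 1
        with pytest.raises(ValueError):
            split_clusters(m, SeedSet([(0, 0)], [1.0]), distance_map(m))


class TestFilterRegions:
    def test_zero_thresholds_identity(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:8, 2:8] = 1
        labels[12:18, 12:18] = 2
        out = filter_regions(labels, np.full_like(labels, 50.0, dtype=float), 0, 0)
        np.testing.assert_array_equal(out, labels)

    def test_small_speck_removed(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[2:12, 2:12] = 1  # 100 px
        labels[20:22, 20:25] = 2  # 10 px speck
        fused = np.full(labels.shape, 100.0)
        out = filter_regions(labels, fused, min_area=80, min_mean_intensity=0)
        assert out.max() == 1
        assert (out == 1).sum() == 100

    def test_dim_region_removed_and_relabelled(self):
        labels = np.zeros((30, 60), dtype=np.int32)
        labels[5:25, 5:25] = 1  # dim
        labels[5:25, 35:55] = 2  # bright
        fused = np.where(labels == 2, 200.0, 5.0)
        out = filter_regions(labels, fused, min_area=10, min_mean_intensity=50.0)
        assert set(np.unique(out)) == {0, 1}
        assert (out == 1).sum() == (labels == 2).sum()


class TestEndToEnd:
    def test_noiseless_unclumped_recovery(self):
        from nucfuse.pipeline import run_pipeline
        from nucfuse.evaluate import object_iou
        from nucfuse.synthetic import generate_scene

        img, truth = generate_scene(
            12, clump_fraction=0.0, noise_level=0, seed=5, shape=(512, 512)
        )
        result = run_pipeline(img, compute_features=False)
        assert result.labels.max() == len(truth.classes)
        ious = object_iou(truth.label_map, result.labels)
        assert np.mean(list(ious.values())) >= 0.9
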