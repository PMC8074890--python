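import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import soilct as sc
from soilct.object_classes import (BinaryVolume, ObjectClassScheme,
                                   trim_small_clusters)

from .oracles import flood_fill_trim


class TestScheme:
    def test_default_bands(self, scheme):
        assert scheme.bands == ((0, 1023), (1024, 2047), (2048, 3071),
                                (3072, 4095), (4096, 5119), (5120, 6144))

    def test_rejects_gap(self):
        with pytest.raises(ValueError):
            ObjectClassScheme(((0, 1000), (1002, 6144)))

    def test_rejects_partial_cover(self):
        with pytest.raises(ValueError):
            ObjectClassScheme(((0, 6000),))


class TestClassifyVoxel:
    def test_second_band(self, scheme):
        assert sc.classify_voxel(1500, scheme) == 2

    def test_endpoints(self, scheme):
        assert sc.classify_voxel(0, scheme) == 1
        assert sc.classify_voxel(6144, scheme) == 6

    def test_out_of_range_errors(self, scheme):
        with pytest.raises(ValueError):
            sc.classify_voxel(-1, scheme)
        with pytest.raises(ValueError):
            sc.classify_voxel(6145, scheme)

    @given(st.integers(0, 6144))
    def test_matches_linear_scan(self, value):
        scheme = sc.default_scheme()
        # brute-force interval scan oracle
        expected = next(i + 1 for i, (lo, hi) in enumerate(scheme.bands)
                        if lo <= value <= hi)
        assert sc.classify_voxel(value, scheme) == expected

    def test_band_edges_all_schemes(self, scheme):
        for i, (lo, hi) in enumerate(scheme.bands, start=1):
            assert sc.classify_voxel(lo, scheme) == i
            assert sc.classify_voxel(hi, scheme) == i


class TestBinarize:
    def test_all_zero_volume_class1(self, scheme):
        v = sc.CTVolume(np.zeros((2, 3, 3), dtype=int))
        assert np.all(sc.binarize(v, {1}, scheme).mask == 1)

    def test_band_membership(self, scheme):
        v = sc.CTVolume(np.full((2, 3, 3), 2500, dtype=int))
        assert np.all(sc.binarize(v, {3}, scheme).mask == 1)
        assert np.all(sc.binarize(v, {2}, scheme).mask == 0)

    def test_multiband_union(self, rng, scheme):
        v = sc.CTVolume(rng.integers(0, 6145, size=(4, 8, 8)))
        union = sc.binarize(v, {5, 6}, scheme).mask
        per_band = sc.binarize(v, {5}, scheme).mask | sc.binarize(v, {6}, scheme).mask
        assert np.array_equal(union, per_band)

    def test_empty_selection_errors(self, scheme):
        v = sc.CTVolume(np.zeros((2, 2, 2), dtype=int))
        with pytest.raises(ValueError):
            sc.binarize(v, set(), scheme)

    def test_unknown_index_errors(self, scheme):
        v = sc.CTVolume(np.zeros((2, 2, 2), dtype=int))
        with pytest.raises(ValueError):
            sc.binarize(v, {7}, scheme)

    def test_partition_disjoint_and_exhaustive(self, rng, scheme):
        v = sc.CTVolume(rng.integers(0, 6145, size=(4, 8, 8)))
        total = sum(sc.binarize(v, {c}, scheme).mask.astype(int)
                    for c in range(1, 7))
        assert np.all(total == 1)


class TestTrimSmallClusters:
    def test_empty_mask(self):
        mask = BinaryVolume(np.zeros((4, 4, 4), dtype=np.uint8))
        out = trim_small_clusters(mask, min_size=60)
        assert np.all(out.mask == 0)

    def test_boundary_semantics(self):
        # a 60-voxel bar survives at min_size 60; a 59-voxel bar does not
        for n, survives in ((60, True), (59, False)):
            arr = np.zeros((1, 1, 80), dtype=np.uint8)
            arr[0, 0, :n] = 1
            out = trim_small_clusters(BinaryVolume(arr), min_size=60)
            assert bool(out.mask.any()) == survives

    def test_min_size_one_is_identity(self, rng):
        arr = (rng.random((6, 6, 6)) < 0.3).astype(np.uint8)
        out = trim_small_clusters(BinaryVolume(arr), min_size=1)
        assert np.array_equal(out.mask, arr)

    def test_monotone_solid_count(self, rng):
        arr = (rng.random((8, 8, 8)) < 0.2).astype(np.uint8)
        mask = BinaryVolume(arr)
        previous = arr.sum()
        for min_size in (1, 3, 10, 60):
            out = trim_small_clusters(mask, min_size=min_size)
            assert out.mask.sum() <= previous
            previous = out.mask.sum()

    def test_porosity_never_decreases(self, rng):
        arr = (rng.random((8, 10, 10)) < 0.25).astype(np.uint8)
        mask = BinaryVolume(arr)
        before = sc.porosity_profile(mask).values
        after = sc.porosity_profile(trim_small_clusters(mask, min_size=5)).values
        assert np.all(after >= before)

    def test_connectivity_matters(self):
        # two diagonal voxels: one cluster at 26-connectivity, two at 6
        arr = np.zeros((2, 2, 2), dtype=np.uint8)
        arr[0, 0, 0] = arr[1, 1, 1] = 1
        mask = BinaryVolume(arr)
        assert trim_small_clusters(mask, min_size=2, connectivity=26).mask.sum() == 2
        assert trim_small_clusters(mask, min_size=2, connectivity=6).mask.sum() == 0

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            trim_small_clusters(BinaryVolume(np.zeros((2, 2, 2), dtype=np.uint8)),
                                connectivity=7)

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("min_size", [2, 5])
    def test_matches_flood_fill_oracle(self, rng, connectivity, min_size):
        for _ in range(10):
            extents = tuple(rng.integers(4, 16, size=3))
            arr = (rng.random(extents) < 0.3).astype(np.uint8)
            out = trim_small_clusters(BinaryVolume(arr), min_size=min_size,
                                      connectivity=connectivity)
            expected = flood_fill_trim(arr, min_size, connectivity)
            assert np.array_equal(out.mask, expected)

    def test_2d_mask(self):
        arr = np.zeros((5, 5), dtype=np.uint8)
        arr[0, :3] = 1
        out = trim_small_clusters(BinaryVolume(arr), min_size=4, connectivity=8)
        assert out.mask.sum() == 0


class TestSlicePorosity:
    def test_degenerate_phases(self):
        assert sc.slice_porosity(np.zeros((4, 4), dtype=np.uint8)) == 1.0
        assert sc.slice_porosity(np.ones((4, 4), dtype=np.uint8)) == 0.0

    def test_counting_oracle(self, rng):
        arr = np.zeros((10, 10), dtype=np.uint8)
        flat = rng.choice(100, size=37, replace=False)
        arr.flat[flat] = 1
        assert sc.slice_porosity(arr) == pytest.approx(0.63)

    @settings(max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_equals_one_minus_mean(self, seed):
        arr = (np.random.default_rng(seed).random((6, 7)) < 0.5).astype(np.uint8)
        assert sc.slice_porosity(arr) == pytest.approx(1.0 - arr.mean())

    def test_zero_size_errors(self):
        with pytest.raises(ValueError):
            sc.slice_porosity(np.zeros((0, 4), dtype=np.uint8))


class TestPorosityProfile:
    def test_blockwise_construction(self):
        arr = np.ones((20, 4, 4), dtype=np.uint8)
        arr[10:] = 0
        profile = sc.porosity_profile(BinaryVolume(arr))
        assert np.array_equal(profile.values, [0.0] * 10 + [1.0] * 10)

    def test_all_void(self):
        profile = sc.porosity_profile(BinaryVolume(np.zeros((5, 3, 3), dtype=np.uint8)))
        assert np.all(profile.values == 1.0)

    def test_length_matches_x_extent(self, rng):
        arr = (rng.random((7, 4, 4)) < 0.5).astype(np.uint8)
        assert len(sc.porosity_profile(BinaryVolume(arr))) == 7

    def test_csv_export(self, tmp_path):
        arr = np.zeros((3, 2, 2), dtype=np.uint8)
        profile = sc.porosity_profile(BinaryVolume(arr))
        profile.slice_thickness_mm = 0.25
        profile.to_csv(tmp_path / "p.csv")
        import pandas as pd
        frame = pd.read_csv(tmp_path / "p.csv")
        assert list(frame.columns) == ["slice_index", "depth_mm", "porosity"]
        assert frame["depth_mm"].tolist() == [0.0, 0.25, 0.5]


class TestAnnotateVolume:
    def test_trim_one_matches_untrimmed(self, small_core, scheme):
        volume, _ = small_core
        a = sc.annotate_volume(volume, scheme, {3}, trim_min_size=1)
        mask = sc.binarize(volume, {3}, scheme)
        b = sc.porosity_profile(mask)
        assert np.array_equal(a.values, b.values)

    def test_union_target(self, small_core, scheme):
        volume, _ = small_core
        profile = sc.annotate_volume(volume, scheme, {5, 6}, trim_min_size=1)
        mask = sc.binarize(volume, {5, 6}, scheme)
        assert np.array_equal(profile.values, sc.porosity_profile(mask).values)

    def test_six_class_sum_rule(self, small_core, scheme):
        # sum over classes of (1 - P_c) per slice equals 1 (partition)
        volume, _ = small_core
        solid_fractions = sum(
            1.0 - sc.annotate_volume(volume, scheme, {c}, trim_min_size=1).values
            for c in range(1, 7))
        assert np.allclose(solid_fractions, 1.0)

    def test_matches_ground_truth(self, small_core, scheme):
        volume, gt = small_core
        for classes in ({1}, {2}, {3}, {5}, {6}, {5, 6}):
            pipeline = sc.annotate_volume(volume, scheme, classes, trim_min_size=1)
            truth = sc.ground_truth_profile(gt, classes, scheme)
            assert np.array_equal(pipeline.values, truth.values)
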