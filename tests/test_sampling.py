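"""Patch grids, probability-map sampling, splits and augmentation."""

import warnings

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings, strategies as st

from mitoseg.reconstruct import merge_patches
from mitoseg.sampling import (
    SampleConfig,
    augment,
    probability_map,
    random_patches,
    split_train_val,
    systematic_grid,
)


def _grid_oracle_positions(size, patch, stride):
    """Independent loop oracle enumerating start positions along one axis."""
    pos, p = [], 0
    while p + patch < size:
        pos.append(p)
        p += stride
    pos.append(size - patch)
    return sorted(set(pos))


class TestSystematicGrid:
    @pytest.mark.parametrize(
        "shape,patch,overlap,expected",
        [
            ((512, 512), (256, 256), 0.0, 4),
            ((512, 512), (256, 256), 0.5, 9),   # ceil((512-256)/128)+1 = 3 per axis
            ((300, 300), (256, 256), 0.0, 4),   # last box shifted inward
        ],
    )
    def test_box_counts_match_position_oracle(self, shape, patch, overlap, expected):
        grid = systematic_grid(shape, patch, overlap)
        stride = max(1, round(patch[0] * (1 - overlap)))
        oracle = _grid_oracle_positions(shape[0], patch[0], stride)
        assert len(grid.boxes) == len(oracle) ** 2 == expected

    def test_boxes_are_full_sized_and_in_range(self):
        grid = systematic_grid((300, 300), (256, 256), 0.0)
        for box in grid.boxes:
            for (a, b), s in zip(box, (300, 300)):
                assert 0 <= a < b <= s and b - a == 256

    def test_every_voxel_covered_and_interior_coverage_count(self):
        grid = systematic_grid((8, 64, 64), (4, 32, 32), 0.5)
        cover = np.zeros((8, 64, 64), np.int32)
        for box in grid.boxes:
            cover[tuple(slice(a, b) for a, b in box)] += 1
        assert cover.min() >= 1
        assert cover[4, 32, 32] == 2 ** 3  # interior voxel, 50% overlap

    def test_overlap_one_rejected(self):
        with pytest.raises(ValueError):
            systematic_grid((64, 64), (32, 32), 1.0)

    def test_patch_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            systematic_grid((30, 30), (32, 32), 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        size=st.integers(40, 90),
        patch=st.integers(8, 40),
        overlap=st.sampled_from([0.0, 0.25, 0.5]),
    )
    def test_round_trip_identity_property(self, size, patch, overlap):
        """Cutting a grid and flat-merging it reproduces the volume exactly."""
        rng = np.random.default_rng(size * 100 + patch)
        vol = rng.random((size, size), dtype=np.float32)
        grid = systematic_grid(vol.shape, (patch, patch), overlap)
        rec = merge_patches(grid.extract(vol), grid, "flat")
        npt.assert_array_equal(rec, vol)

    def test_reflect_mode_round_trip(self, em_fixture):
        vol, _ = em_fixture
        grid = systematic_grid(vol.shape, (8, 48, 48), 0.5, pad_mode="reflect")
        rec = merge_patches(grid.extract(vol), grid, "flat")
        npt.assert_allclose(rec, vol, atol=1e-6)


class TestProbabilityMap:
    def test_uniform_on_empty_labels(self):
        pm = probability_map(np.zeros((4, 4), np.uint8))
        npt.assert_allclose(pm, 1 / 16)

    def test_single_foreground_voxel_weight(self):
        """Normalisation oracle: w/(w + N - 1) for one fg voxel of weight w."""
        lab = np.zeros((5, 5), np.uint8)
        lab[2, 2] = 1
        pm = probability_map(lab)
        n = lab.size
        w = (n - 1) / 1  # class-balancing weight: fg mass = bg mass
        assert pm[2, 2] == pytest.approx(w / (w + n - 1))
        assert pm.sum() == pytest.approx(1.0)

    def test_foreground_mass_balanced(self, em_fixture):
        _, lab = em_fixture
        pm = probability_map(lab)
        assert pm[lab > 0].sum() == pytest.approx(0.5)
        assert pm[lab > 0].min() >= pm[lab == 0].max()

    def test_permutation_equivariance(self, rng):
        lab = (rng.random((6, 6)) > 0.7).astype(np.uint8)
        pm = probability_map(lab)
        perm = rng.permutation(36)
        pm_perm = probability_map(lab.ravel()[perm].reshape(6, 6))
        npt.assert_allclose(pm.ravel()[perm].reshape(6, 6), pm_perm)

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            probability_map(np.zeros((0,), np.uint8))


class TestRandomPatches:
    def test_deterministic_for_fixed_seed(self, em_fixture):
        vol, lab = em_fixture
        cfg = SampleConfig(patch_shape=(8, 32, 32), patches_per_image=5, seed=11)
        a = random_patches(vol, lab, cfg)
        b = random_patches(vol, lab, cfg)
        for (ia, la, ba), (ib, lb, bb) in zip(a, b):
            npt.assert_array_equal(ia, ib)
            assert ba == bb

    def test_foreground_centers_oversampled(self):
        """Foreground-weighted draws hit a 32^2 square far above its area
        fraction; the Monte-Carlo frequency matches the map's foreground mass."""
        lab = np.zeros((128, 128), np.uint8)
        lab[48:80, 48:80] = 1
        vol = lab.astype(np.float32)
        cfg = SampleConfig(
            patch_shape=(16, 16), patches_per_image=400, seed=5
        )
        draws = random_patches(vol, lab, cfg)
        # recover centers from boxes: center was clipped to box start + p//2
        inside = 0
        for _, lab_patch, _ in draws:
            if lab_patch[8, 8]:
                inside += 1
        frac = inside / len(draws)
        area_frac = (32 * 32) / (128 * 128)
        assert frac > area_frac  # far above 6.25%
        assert frac == pytest.approx(0.5, abs=0.1)  # map assigns fg mass 0.5

    def test_min_fraction_filters_patches(self, em_fixture):
        vol, lab = em_fixture
        cfg = SampleConfig(
            patch_shape=(4, 24, 24), patches_per_image=6,
            foreground_min_fraction=0.01, seed=3,
        )
        for _, lab_patch, _ in random_patches(vol, lab, cfg):
            assert (lab_patch > 0).mean() >= 0.01

    def test_unattainable_fraction_warns_and_falls_back(self):
        vol = np.zeros((32, 32), np.float32)
        lab = np.zeros((32, 32), np.uint8)
        cfg = SampleConfig(patch_shape=(8, 8), patches_per_image=2,
                           foreground_min_fraction=0.5, seed=0)
        with pytest.warns(UserWarning, match="unattainable"):
            out = random_patches(vol, lab, cfg)
        assert len(out) == 2


class TestSplit:
    def test_lucchi_sized_split_consecutive(self):
        """165 slices at 10%: round-half-up gives 17 validation slices."""
        cfg = SampleConfig(val_mode="consecutive")
        train, val = split_train_val(165, cfg)
        assert len(val) == 17 and len(train) == 148
        npt.assert_array_equal(val, np.arange(148, 165))

    def test_minimum_one_validation_slice(self):
        train, val = split_train_val(10, SampleConfig())
        assert len(val) == 1 and len(train) == 9
        assert set(train) | set(val) == set(range(10))

    def test_random_split_seeded(self):
        a = split_train_val(50, SampleConfig(seed=2))
        b = split_train_val(50, SampleConfig(seed=2))
        npt.assert_array_equal(a[1], b[1])
        c = split_train_val(50, SampleConfig(seed=3))
        assert not np.array_equal(a[1], c[1])


class TestAugment:
    def test_flip_is_involution(self, rng):
        img = rng.random((16, 16))
        lab = (img > 0.5).astype(np.uint8)
        # force both flips via a seed scan: apply twice with identical rng states
        out_img, out_lab = augment(img, lab, ops=("flip",), seed=8)
        back_img, back_lab = augment(out_img, out_lab, ops=("flip",), seed=8)
        npt.assert_array_equal(back_img, img)
        npt.assert_array_equal(back_lab, lab)

    def test_rot90_preserves_content(self, rng):
        img = rng.random((16, 16))
        lab = (img > 0.5).astype(np.uint8)
        out_img, out_lab = augment(img, lab, ops=("rot90",), seed=4)
        assert sorted(out_img.ravel()) == sorted(img.ravel())
        npt.assert_array_equal(out_lab, (out_img > 0.5))

    def test_elastic_zero_amplitude_is_identity(self, rng):
        img = rng.random((4, 16, 16))
        lab = (img > 0.5).astype(np.uint8)
        out_img, out_lab = augment(
            img, lab, ops=("elastic",), seed=1, elastic_alpha=0.0
        )
        npt.assert_allclose(out_img, img, atol=1e-12)
        npt.assert_array_equal(out_lab, lab)

    def test_elastic_labels_stay_binary(self, em_fixture):
        vol, lab = em_fixture
        _, out_lab = augment(
            vol[:4, :64, :64], lab[:4, :64, :64],
            ops=("rot90", "flip", "elastic"), seed=9,
        )
        assert set(np.unique(out_lab)) <= {0, 1}
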