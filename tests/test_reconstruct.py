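"""Blending windows, patch merging, TTA, and inference orchestration."""

import numpy as np
import numpy.testing as npt
import pytest

from mitoseg.reconstruct import (
    ReconstructionPolicy,
    merge_patches,
    predict_volume,
    spline_window,
    tta_apply,
    tta_collapse,
    tta_expand,
    tta_invert,
)
from mitoseg.sampling import systematic_grid


class TestSplineWindow:
    def test_symmetric_under_reflection(self):
        w = spline_window((8, 8)).weights
        npt.assert_allclose(w, w[::-1, :])
        npt.assert_allclose(w, w[:, ::-1])

    def test_center_to_edge_ratio_matches_closed_form(self):
        """Direct evaluation oracle of the squared-sine taper at n=8."""
        n = 8
        w = spline_window((n,)).weights
        edge = max(np.sin(np.pi * 0.5 / n) ** 2, 1e-3)
        center = np.sin(np.pi * 3.5 / n) ** 2
        assert w[0] == pytest.approx(edge)
        assert w[3] == pytest.approx(center)
        assert w.max() == w[3] == w[4]
        assert (w > 0).all()

    def test_2d_window_is_outer_product_of_1d(self):
        w1 = spline_window((6,)).weights
        w2 = spline_window((6, 6)).weights
        # away from the floored border the product structure is exact
        npt.assert_allclose(w2[1:-1, 1:-1], np.outer(w1, w1)[1:-1, 1:-1])

    def test_power_must_be_positive(self):
        with pytest.raises(ValueError):
            spline_window((8, 8), power=0)


class TestMergePatches:
    def test_constant_patches_yield_constant_volume(self):
        grid = systematic_grid((40, 40), (16, 16), 0.5)
        patches = [np.full((16, 16), 0.37, np.float32) for _ in grid.boxes]
        out = merge_patches(patches, grid, spline_window((16, 16)))
        npt.assert_allclose(out, 0.37, atol=1e-6)

    def test_overlap_mean_matches_accumulation_oracle(self):
        """Two length-4 rows overlapping by 2: overlapped entries average."""
        vol_shape = (1, 6)
        grid = systematic_grid(vol_shape, (1, 4), 0.5)
        assert [b[1] for b in grid.boxes] == [(0, 4), (2, 6)]
        p1 = np.array([[1.0, 2.0, 3.0, 4.0]])
        p2 = np.array([[10.0, 20.0, 30.0, 40.0]])
        out = merge_patches([p1, p2], grid, "flat")
        # brute-force per-voxel accumulation
        acc = np.zeros(6)
        cnt = np.zeros(6)
        acc[0:4] += p1[0]; cnt[0:4] += 1
        acc[2:6] += p2[0]; cnt[2:6] += 1
        npt.assert_allclose(out[0], acc / cnt)

    def test_uncovered_voxel_raises(self):
        grid = systematic_grid((8, 8), (4, 4), 0.0)
        grid.boxes = grid.boxes[:-1]  # malformed: drop a corner
        with pytest.raises(ValueError, match="cover"):
            merge_patches([np.zeros((4, 4))] * len(grid.boxes), grid, "flat")

    def test_patch_count_mismatch_raises(self):
        grid = systematic_grid((8, 8), (4, 4), 0.0)
        with pytest.raises(ValueError):
            merge_patches([np.zeros((4, 4))], grid, "flat")


class TestTTA:
    def test_2d_yields_8_distinct_invertible_variants(self, rng):
        patch = rng.random((6, 6))
        variants, descs = tta_expand(patch)
        assert len(variants) == len(descs) == 8
        keys = {v.tobytes() for v in variants}
        assert len(keys) == 8  # all distinct for a generic patch
        for v, d in zip(variants, descs):
            npt.assert_array_equal(tta_invert(v, d), patch)

    def test_3d_yields_16_invertible_variants(self, rng):
        patch = rng.random((3, 4, 4))
        variants, descs = tta_expand(patch)
        assert len(variants) == 16
        for v, d in zip(variants, descs):
            npt.assert_array_equal(tta_invert(v, d), patch)

    def test_group_closure(self, rng):
        """Composing any two 2D variants lands back inside the variant set."""
        patch = rng.random((5, 5))
        variants, descs = tta_expand(patch)
        keys = {v.tobytes() for v in variants}
        for d1 in descs:
            for d2 in descs:
                assert tta_apply(tta_apply(patch, d1), d2).tobytes() in keys

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            tta_expand(np.zeros((4, 6)))

    def test_collapse_of_identical_predictions(self, rng):
        patch = rng.random((4, 4)).astype(np.float32)
        _, descs = tta_expand(patch)
        preds = [tta_apply(patch, d) for d in descs]
        npt.assert_allclose(tta_collapse(preds, descs), patch, atol=1e-7)

    def test_collapse_hand_computed_mean(self):
        """Two 2x2 predictions with known inverses, averaged by hand."""
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[10.0, 20.0], [30.0, 40.0]])
        descs = [(0, False, False), (1, False, False)]  # identity, rot90
        expected = (a + np.rot90(b, -1)) / 2
        npt.assert_allclose(tta_collapse([a, b], descs), expected)

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            tta_collapse([np.zeros((2, 2))], [(0, False, False), (1, False, False)])


class _StubModel:
    """Inference stub with the model surface predict_volume needs."""

    def __init__(self, fn, ndim=2, factor=None):
        self.fn = fn
        self.ndim = ndim
        self.downsample_factor = factor or (1,) * ndim

    def predict(self, patch):
        return self.fn(np.asarray(patch, dtype=np.float32))


class TestPredictVolume:
    @pytest.mark.parametrize("mode", ["per_patch", "overlap_50", "full_image"])
    def test_constant_stub_gives_constant_volume(self, mode, rng):
        model = _StubModel(lambda p: np.full_like(p, 0.25))
        vol = rng.random((64, 64), dtype=np.float32)
        policy = ReconstructionPolicy(mode=mode, patch_shape=(32, 32))
        npt.assert_allclose(predict_volume(model, vol, policy), 0.25, atol=1e-6)

    def test_identity_stub_overlap_flat_reproduces_volume(self, rng):
        model = _StubModel(lambda p: p)
        vol = rng.random((64, 64), dtype=np.float32)
        policy = ReconstructionPolicy(mode="overlap_50", patch_shape=(32, 32))
        npt.assert_allclose(predict_volume(model, vol, policy), vol, atol=1e-6)

    def test_equivariant_stub_tta_matches_no_tta(self, rng):
        """For a transform-equivariant model TTA must be a no-op."""
        model = _StubModel(lambda p: 1.0 - p)  # pointwise, hence equivariant
        vol = rng.random((32, 32), dtype=np.float32)
        for tta in (False, True):
            policy = ReconstructionPolicy(
                mode="overlap_50", tta=tta, patch_shape=(16, 16)
            )
            out = predict_volume(model, vol, policy)
            npt.assert_allclose(out, 1.0 - vol, atol=1e-6)

    def test_2d_model_processes_3d_stack_slicewise(self, rng):
        model = _StubModel(lambda p: p)
        vol = rng.random((3, 32, 32), dtype=np.float32)
        policy = ReconstructionPolicy(mode="overlap_50", patch_shape=(16, 16))
        npt.assert_allclose(predict_volume(model, vol, policy), vol, atol=1e-6)

    def test_3d_full_image_capacity_error(self):
        model = _StubModel(lambda p: p, ndim=3)
        vol = np.zeros((64, 64, 64), np.float32)
        policy = ReconstructionPolicy(
            mode="full_image", patch_shape=(16, 16, 16), max_full_voxels=1000
        )
        with pytest.raises(ValueError, match="overlap"):
            predict_volume(model, vol, policy)

    def test_3d_spline_requires_explicit_force(self):
        model = _StubModel(lambda p: p, ndim=3)
        vol = np.zeros((8, 16, 16), np.float32)
        with pytest.raises(ValueError, match="force_3d_blending"):
            predict_volume(
                model, vol,
                ReconstructionPolicy(mode="overlap_50", blending="spline",
                                     patch_shape=(4, 8, 8)),
            )

    def test_border_corrupting_stub_blending_beats_mosaic(self, rng):
        """Jagged tile borders: spline-blended 50%-overlap reconstruction has
        strictly lower error than the per-patch mosaic."""

        def corrupt_border(p):
            out = p.copy()
            out[:2, :] = out[-2:, :] = 0.0
            out[:, :2] = out[:, -2:] = 0.0
            return out

        model = _StubModel(corrupt_border)
        vol = 0.2 + 0.6 * rng.random((96, 96)).astype(np.float32)
        mosaic = predict_volume(
            model, vol, ReconstructionPolicy(mode="per_patch", patch_shape=(32, 32))
        )
        blended = predict_volume(
            model, vol,
            ReconstructionPolicy(mode="overlap_50", blending="spline",
                                 patch_shape=(32, 32)),
        )
        err_mosaic = np.abs(mosaic - vol).mean()
        err_blend = np.abs(blended - vol).mean()
        assert err_blend < err_mosaic
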