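"""Full-volume probability maps from per-patch predictions.

Three reconstruction strategies are supported: a plain per-patch mosaic, 50%
overlap with weighted averaging (optionally under a second-order spline
blending window that suppresses jagged tile borders), and single-shot
full-image inference.  Test-time augmentation runs the model on the 8 (2D)
or 16 (3D) right-angle rotation/flip variants of each patch, inverts each
prediction and averages in probability space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampling import PatchGrid, systematic_grid

__all__ = [
    "BlendWindow",
    "ReconstructionPolicy",
    "spline_window",
    "merge_patches",
    "tta_expand",
    "tta_apply",
    "tta_invert",
    "tta_collapse",
    "predict_volume",
]

_EPS = 1e-3  # floor for border weights; avoids zero-weight voxels


@dataclass
class BlendWindow:
    """Separable per-voxel blending weights matching one patch shape."""

    weights: np.ndarray
    power: int = 2

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)


def spline_window(patch_shape, power: int = 2) -> BlendWindow:
    """Second-order (by default) spline blending window.

    Separable product of the 1D taper ``s(t) = sin(pi * (t + 0.5) / n) **
    power`` — near zero at patch borders, 1 at the center, symmetric under
    reflection.  Border weights are floored at 1e-3 so every voxel keeps a
    strictly positive weight.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    axes = []
    for n in patch_shape:
        t = np.arange(n, dtype=np.float64)
        axes.append(np.sin(np.pi * (t + 0.5) / n) ** power)
    w = axes[0]
    for a in axes[1:]:
        w = np.multiply.outer(w, a)
    return BlendWindow(np.maximum(w, _EPS), power=power)


def merge_patches(
    patches,
    grid: PatchGrid,
    window: BlendWindow | str = "flat",
) -> np.ndarray:
    """Weighted-average patch predictions back into a full volume.

    ``output[v] = sum_i w_i(v) p_i(v) / sum_i w_i(v)`` over the patches
    covering voxel ``v``; the flat window reduces to plain averaging.
    Accumulation is double precision; the result is cast to float32.
    """
    patches = list(patches)
    if len(patches) != len(grid.boxes):
        raise ValueError(f"got {len(patches)} patches for {len(grid.boxes)} grid boxes")
    if isinstance(window, str):
        if window != "flat":
            raise ValueError("window must be 'flat' or a BlendWindow")
        w = np.ones(grid.patch_shape, dtype=np.float64)
    else:
        w = window.weights
        if w.shape != tuple(grid.patch_shape):
            raise ValueError("blend window shape does not match grid patch shape")
    shape = grid.padded_shape
    acc = np.zeros(shape, dtype=np.float64)
    wacc = np.zeros(shape, dtype=np.float64)
    for patch, box in zip(patches, grid.boxes):
        patch = np.asarray(patch, dtype=np.float64)
        if patch.shape != tuple(grid.patch_shape):
            raise ValueError(
                f"patch shape {patch.shape} != grid patch shape {grid.patch_shape}"
            )
        sl = tuple(slice(a, b) for a, b in box)
        acc[sl] += w * patch
        wacc[sl] += w
    if np.any(wacc == 0):
        raise ValueError("grid does not cover every voxel (uncovered voxels found)")
    out = acc / wacc
    if grid.pad:
        sl = tuple(
            slice(p[0], p[0] + s) for p, s in zip(grid.pad, grid.volume_shape)
        )
        out = out[sl]
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# test-time augmentation
# ---------------------------------------------------------------------------

def _check_square(patch: np.ndarray) -> None:
    if patch.shape[-1] != patch.shape[-2]:
        raise ValueError(
            "TTA requires square in-plane patches so right-angle rotations "
            f"preserve the shape; got {patch.shape}"
        )


def tta_apply(patch: np.ndarray, desc: tuple[int, bool, bool]) -> np.ndarray:
    """Apply a TTA descriptor ``(k_rot90, flip_x, flip_z)`` to a patch."""
    k, flip_x, flip_z = desc
    out = np.rot90(patch, k, axes=(-2, -1))
    if flip_x:
        out = np.flip(out, axis=-1)
    if flip_z:
        out = np.flip(out, axis=0)
    return np.ascontiguousarray(out)


def tta_invert(patch: np.ndarray, desc: tuple[int, bool, bool]) -> np.ndarray:
    """Undo ``tta_apply`` for the same descriptor."""
    k, flip_x, flip_z = desc
    out = patch
    if flip_z:
        out = np.flip(out, axis=0)
    if flip_x:
        out = np.flip(out, axis=-1)
    return np.ascontiguousarray(np.rot90(out, -k, axes=(-2, -1)))


def tta_expand(patch: np.ndarray, ndim: int | None = None):
    """Enumerate the geometric TTA variants of a patch.

    2D: the 8 elements of the dihedral group (4 right-angle rotations x
    optional horizontal flip).  3D: 16 variants (the 8 in-plane dihedral
    transforms x optional Z flip).  Returns ``(variants, descriptors)`` where
    each descriptor inverts its variant exactly via :func:`tta_invert`.
    """
    patch = np.asarray(patch)
    if ndim is None:
        ndim = patch.ndim
    if ndim not in (2, 3) or patch.ndim != ndim:
        raise ValueError(f"expected a {ndim}D patch, got shape {patch.shape}")
    _check_square(patch)
    z_options = (False, True) if ndim == 3 else (False,)
    descs = [
        (k, fx, fz) for fz in z_options for fx in (False, True) for k in range(4)
    ]
    return [tta_apply(patch, d) for d in descs], descs


def tta_collapse(predictions, descriptors) -> np.ndarray:
    """Invert each prediction's transform and average in probability space."""
    predictions = list(predictions)
    if len(predictions) != len(descriptors):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(descriptors)} descriptors"
        )
    acc = np.zeros_like(np.asarray(predictions[0], dtype=np.float64))
    for pred, desc in zip(predictions, descriptors):
        acc += tta_invert(np.asarray(pred, dtype=np.float64), desc)
    return (acc / len(predictions)).astype(np.float32)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionPolicy:
    """How to turn patch predictions into a full-volume probability map.

    ``mode``: ``per_patch`` (mosaic, no overlap), ``overlap_50`` (50% overlap
    averaging) or ``full_image``.  Spline blending applies only to the
    overlapping modes; the full 3D blend is disabled by default for cost and
    must be forced explicitly.
    """

    mode: str = "overlap_50"
    blending: str = "flat"  # {flat, spline}
    tta: bool = False
    patch_shape: tuple[int, ...] = (256, 256)
    max_full_voxels: int = 8_000_000
    force_3d_blending: bool = False

    def __post_init__(self):
        if self.mode not in ("per_patch", "overlap_50", "full_image"):
            raise ValueError("mode must be per_patch, overlap_50 or full_image")
        if self.blending not in ("flat", "spline"):
            raise ValueError("blending must be 'flat' or 'spline'")
        if self.mode == "full_image" and self.blending == "spline":
            raise ValueError("full_image mode excludes blending")
        self.patch_shape = tuple(int(p) for p in self.patch_shape)


def _model_ndim(model) -> int:
    return model.spec.ndim if hasattr(model, "spec") else model.ndim


def _model_factor(model, ndim: int) -> tuple[int, ...]:
    if hasattr(model, "spec"):
        return model.spec.downsample_factor()
    return getattr(model, "downsample_factor", (1,) * ndim)


def _predict_patch(model, patch: np.ndarray, tta: bool) -> np.ndarray:
    if not tta:
        return np.asarray(model.predict(patch), dtype=np.float32)
    variants, descs = tta_expand(patch)
    preds = [model.predict(v) for v in variants]
    return tta_collapse(preds, descs)


def _predict_single(model, volume: np.ndarray, policy: ReconstructionPolicy) -> np.ndarray:
    ndim = volume.ndim
    if policy.mode == "full_image":
        factor = _model_factor(model, ndim)
        pad = []
        for s, f in zip(volume.shape, factor):
            rem = (-s) % f
            pad.append((0, rem))
        padded = np.pad(volume, pad, mode="reflect") if any(p[1] for p in pad) else volume
        pred = _predict_patch(model, padded, policy.tta)
        return pred[tuple(slice(0, s) for s in volume.shape)].astype(np.float32)
    overlap = 0.5 if policy.mode == "overlap_50" else 0.0
    pad_mode = "reflect" if policy.mode == "overlap_50" else "shift"
    grid = systematic_grid(volume.shape, policy.patch_shape, overlap, pad_mode=pad_mode)
    preds = [_predict_patch(model, p, policy.tta) for p in grid.extract(volume)]
    window = (
        spline_window(policy.patch_shape)
        if policy.blending == "spline"
        else "flat"
    )
    return merge_patches(preds, grid, window)


def predict_volume(model, volume: np.ndarray, policy: ReconstructionPolicy) -> np.ndarray:
    """Run tiled (or full-image) inference over a volume.

    A 2D model applied to a (Z, Y, X) stack predicts slice by slice.  The
    result is deterministic given the model weights.  3D full-image inference
    on a volume above ``policy.max_full_voxels`` raises, advising overlap
    mode (the situation that exhausts accelerator memory on real volumes).
    """
    vol = np.asarray(volume, dtype=np.float32)
    ndim = _model_ndim(model)
    if policy.blending == "spline" and ndim == 3 and not policy.force_3d_blending:
        raise ValueError(
            "spline blending is a 2D technique here (3D cost); pass "
            "force_3d_blending=True to override"
        )
    if ndim == 2 and vol.ndim == 3:
        return np.stack([_predict_single(model, sl, policy) for sl in vol])
    if vol.ndim != ndim:
        raise ValueError(f"volume ndim {vol.ndim} incompatible with model ndim {ndim}")
    if ndim == 3 and policy.mode == "full_image" and vol.size > policy.max_full_voxels:
        raise ValueError(
            f"volume has {vol.size} voxels, above the full-image capacity "
            f"limit ({policy.max_full_voxels}); use mode='overlap_50' instead"
        )
    return _predict_single(model, vol, policy)
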