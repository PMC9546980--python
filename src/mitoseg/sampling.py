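"""Patch extraction, class-balanced sampling, splits and data augmentation.

Training patches are drawn either on a systematic grid or at random, where
random draws use a foreground-weighted probability map so the heavily
imbalanced mitochondria class is seen often enough.  Validation is split off
as 10% of the training slices (random or trailing consecutive block).
Augmentation applies identical geometric transforms to image and label
patches: right-angle rotations, horizontal/vertical flips and (for 3D)
elastic deformation with nearest-neighbour label warping.

Boxes are half-open ``(start, stop)`` pairs per axis, 0-based, lexicographic
(Z, Y, X) order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PatchGrid",
    "SampleConfig",
    "systematic_grid",
    "probability_map",
    "random_patches",
    "split_train_val",
    "augment",
]


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

@dataclass
class PatchGrid:
    """Set of equally sized boxes covering a volume.

    With ``pad_mode='shift'`` the last box per axis is shifted inward so all
    boxes stay full-sized inside the volume.  With ``pad_mode='reflect'`` the
    volume is reflect-padded up to a whole number of strides (inference use,
    so blending windows apply cleanly); boxes then index the padded volume
    and ``pad`` records the per-axis (before, after) amounts.
    """

    volume_shape: tuple[int, ...]
    patch_shape: tuple[int, ...]
    overlap: tuple[float, ...]
    boxes: list[tuple[tuple[int, int], ...]] = field(default_factory=list)
    pad_mode: str = "shift"
    pad: tuple[tuple[int, int], ...] = ()

    @property
    def padded_shape(self) -> tuple[int, ...]:
        if not self.pad:
            return self.volume_shape
        return tuple(s + p[0] + p[1] for s, p in zip(self.volume_shape, self.pad))

    def extract(self, volume: np.ndarray) -> list[np.ndarray]:
        """Cut the grid's patches out of ``volume`` (padding if required)."""
        arr = np.asarray(volume)
        if arr.shape != tuple(self.volume_shape):
            raise ValueError(f"volume shape {arr.shape} != grid shape {self.volume_shape}")
        if self.pad:
            arr = np.pad(arr, self.pad, mode="reflect")
        return [arr[tuple(slice(a, b) for a, b in box)] for box in self.boxes]


def _axis_positions(size: int, patch: int, stride: int) -> list[int]:
    pos = list(range(0, size - patch + 1, stride))
    if pos[-1] != size - patch:
        pos.append(size - patch)
    return pos


def systematic_grid(
    volume_shape,
    patch_shape,
    overlap=0.0,
    pad_mode: str = "shift",
) -> PatchGrid:
    """Build the ordered grid of boxes covering ``volume_shape``.

    ``overlap`` is a fraction in [0, 1) per axis (scalar broadcasts); with
    overlap 0.5 the stride is half the patch shape, so interior voxels are
    covered ``2**ndim`` times.
    """
    vshape = tuple(int(s) for s in volume_shape)
    pshape = tuple(int(p) for p in patch_shape)
    if len(vshape) != len(pshape):
        raise ValueError("volume and patch dimensionality differ")
    ov = np.broadcast_to(np.asarray(overlap, dtype=float), (len(vshape),))
    if np.any(ov < 0) or np.any(ov >= 1):
        raise ValueError("overlap fractions must lie in [0, 1)")
    strides = tuple(max(1, int(round(p * (1.0 - o)))) for p, o in zip(pshape, ov))
    pad: tuple[tuple[int, int], ...] = ()
    if pad_mode == "shift":
        if any(p > s for p, s in zip(pshape, vshape)):
            raise ValueError(f"patch shape {pshape} exceeds volume shape {vshape}")
        axes = [_axis_positions(s, p, st) for s, p, st in zip(vshape, pshape, strides)]
        shape_for_boxes = vshape
    elif pad_mode == "reflect":
        padded, pads = [], []
        for s, p, st in zip(vshape, pshape, strides):
            target = max(s, p)
            rem = (target - p) % st
            if rem:
                target += st - rem
            extra = target - s
            pads.append((extra // 2, extra - extra // 2))
            padded.append(target)
        pad = tuple(pads)
        axes = [
            list(range(0, s - p + 1, st)) for s, p, st in zip(padded, pshape, strides)
        ]
        shape_for_boxes = tuple(padded)
    else:
        raise ValueError("pad_mode must be 'shift' or 'reflect'")
    boxes = []
    for starts in np.ndindex(*(len(a) for a in axes)):
        box = tuple(
            (axes[d][i], axes[d][i] + pshape[d]) for d, i in enumerate(starts)
        )
        boxes.append(box)
    grid = PatchGrid(
        volume_shape=vshape,
        patch_shape=pshape,
        overlap=tuple(ov),
        boxes=boxes,
        pad_mode=pad_mode,
        pad=pad,
    )
    return grid


# ---------------------------------------------------------------------------
# class-balanced random sampling
# ---------------------------------------------------------------------------

def probability_map(labels: np.ndarray) -> np.ndarray:
    """Voxel weights for class-balanced patch-center sampling.

    Foreground voxels get a common weight chosen so total foreground mass is
    0.5 (background weight 1 before normalisation); an all-background volume
    degrades to the uniform map.  Weights are non-negative and sum to 1.
    """
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("empty label volume")
    fg = lab > 0
    n_fg = int(fg.sum())
    n_bg = lab.size - n_fg
    w = np.ones(lab.shape, dtype=np.float64)
    if n_fg and n_bg:
        w[fg] = n_bg / n_fg
    return w / w.sum()


@dataclass
class SampleConfig:
    """Configuration of training-patch selection."""

    patch_shape: tuple[int, ...] = (256, 256)
    mode: str = "random"  # {random, systematic}
    patches_per_image: int = 1
    foreground_min_fraction: float = 0.0  # 0 disables discarding; 0.005 = "low info" rule
    use_probability_map: bool = True
    val_fraction: float = 0.10
    val_mode: str = "random"  # {random, consecutive}
    seed: int = 0

    def __post_init__(self):
        self.patch_shape = tuple(int(p) for p in self.patch_shape)
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patches_per_image < 1:
            raise ValueError("patches_per_image must be >= 1")
        if self.mode not in ("random", "systematic"):
            raise ValueError("mode must be 'random' or 'systematic'")
        if self.val_mode not in ("random", "consecutive"):
            raise ValueError("val_mode must be 'random' or 'consecutive'")


_MAX_RETRIES = 50


def random_patches(
    volume: np.ndarray,
    labels: np.ndarray,
    cfg: SampleConfig,
    n_patches: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray, tuple[tuple[int, int], ...]]]:
    """Draw seeded random patches with centers from the probability map.

    Patches whose foreground fraction falls below
    ``cfg.foreground_min_fraction`` are rejected and redrawn (bounded
    retries).  If the constraint is unattainable (no foreground at all) a
    warning is emitted and sampling proceeds unconstrained.
    """
    if cfg.mode != "random":
        raise ValueError("random_patches requires cfg.mode == 'random'")
    vol = np.asarray(volume)
    lab = np.asarray(labels)
    if vol.shape != lab.shape:
        raise ValueError("volume and labels must share a shape")
    pshape = cfg.patch_shape
    if len(pshape) != vol.ndim:
        raise ValueError(f"patch shape {pshape} does not match volume ndim {vol.ndim}")
    if any(p > s for p, s in zip(pshape, vol.shape)):
        raise ValueError("patch larger than volume")
    n = cfg.patches_per_image if n_patches is None else int(n_patches)
    rng = np.random.default_rng(cfg.seed)
    pmap = probability_map(lab) if cfg.use_probability_map else None
    flat_p = None if pmap is None else pmap.ravel()
    min_frac = cfg.foreground_min_fraction
    if min_frac > 0.0 and not (lab > 0).any():
        warnings.warn(
            "foreground_min_fraction unattainable (no foreground); sampling "
            "unconstrained", stacklevel=2,
        )
        min_frac = 0.0
    out = []
    psize = int(np.prod(pshape))
    for _ in range(n):
        chosen = None
        for _attempt in range(_MAX_RETRIES):
            if flat_p is not None:
                idx = rng.choice(lab.size, p=flat_p)
            else:
                idx = rng.integers(lab.size)
            center = np.unravel_index(idx, lab.shape)
            start = tuple(
                int(np.clip(c - p // 2, 0, s - p))
                for c, p, s in zip(center, pshape, lab.shape)
            )
            box = tuple((st, st + p) for st, p in zip(start, pshape))
            sl = tuple(slice(a, b) for a, b in box)
            if min_frac > 0.0 and (lab[sl] > 0).sum() < min_frac * psize:
                continue
            chosen = (vol[sl].copy(), lab[sl].copy(), box)
            break
        if chosen is None:
            warnings.warn(
                "foreground_min_fraction not met after "
                f"{_MAX_RETRIES} retries; keeping last draw", stacklevel=2,
            )
            chosen = (vol[sl].copy(), lab[sl].copy(), box)
        out.append(chosen)
    return out


def split_train_val(slices, cfg: SampleConfig) -> tuple[np.ndarray, np.ndarray]:
    """Split slice indices into train/validation sets.

    ``slices`` may be an integer count or a sequence.  The validation size is
    ``round_half_up(val_fraction * n)`` with a minimum of 1; consecutive mode
    takes the trailing block, random mode is seeded by ``cfg.seed``.
    """
    n = int(slices) if np.isscalar(slices) else len(slices)
    if n < 2:
        raise ValueError("need at least 2 slices to split")
    k = max(1, int(np.floor(cfg.val_fraction * n + 0.5)))
    idx = np.arange(n)
    if cfg.val_mode == "consecutive":
        return idx[: n - k], idx[n - k :]
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    val = np.sort(perm[:k])
    train = np.sort(perm[k:])
    return train, val


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _elastic_fields(shape_yx, alpha, sigma, rng):
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, shape_yx), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, shape_yx), sigma) * alpha
    return dy, dx


def augment(
    image: np.ndarray,
    label: np.ndarray,
    ops: tuple[str, ...] = ("rot90", "flip"),
    seed: int | np.random.Generator = 0,
    elastic_alpha: float = 10.0,
    elastic_sigma: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform set to an (image, label) pair.

    ``ops`` may contain ``rot90`` (random in-plane right-angle rotation),
    ``flip`` (random vertical/horizontal flips) and ``elastic`` (smooth
    random in-plane displacement, amplitude ``elastic_alpha`` voxels,
    correlation length ``elastic_sigma``).  The identical transform is
    applied to both patches; labels are warped nearest-neighbour so they stay
    strictly binary.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(image)
    lab = np.asarray(label)
    if img.shape != lab.shape:
        raise ValueError("image and label shapes differ")
    axes = (-2, -1)
    if "rot90" in ops:
        k = int(rng.integers(0, 4))
        if img.shape[-1] != img.shape[-2] and k % 2:
            k = 0  # non-square in-plane patches only admit 180-degree turns
        img = np.rot90(img, k, axes=axes)
        lab = np.rot90(lab, k, axes=axes)
    if "flip" in ops:
        for ax in axes:
            if rng.random() < 0.5:
                img = np.flip(img, axis=ax)
                lab = np.flip(lab, axis=ax)
    if "elastic" in ops and elastic_alpha > 0.0:
        shape_yx = img.shape[-2:]
        dy, dx = _elastic_fields(shape_yx, elastic_alpha, elastic_sigma, rng)
        yy, xx = np.meshgrid(
            np.arange(shape_yx[0]), np.arange(shape_yx[1]), indexing="ij"
        )
        coords = np.stack([yy + dy, xx + dx])

        def warp(plane, order):
            return ndimage.map_coordinates(plane, coords, order=order, mode="reflect")

        if img.ndim == 2:
            img = warp(img, 1)
            lab = warp(lab, 0)
        else:  # same in-plane field on every slice preserves Z coherence
            img = np.stack([warp(img[z], 1) for z in range(img.shape[0])])
            lab = np.stack([warp(lab[z], 0) for z in range(lab.shape[0])])
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)
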