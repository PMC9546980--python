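"""Synthetic EM-like fixture volumes with paired binary labels.

The generator emulates the appearance that matters to this pipeline: dark
ellipsoidal organelles with a bright 1-2 voxel rim (the membrane analogue)
on a noisy mid-grey background, optionally squeezed across fewer Z slices to
mimic anisotropic serial-section acquisition.  Labels are the exact voxelised
ellipsoid interiors.  It does not attempt photorealism — no cristae, no
membrane contacts, no imaging artefacts — so a green test on fixtures
establishes that the machinery is correct, not that real EM volumes would
reach any particular score.

``corrupt_labels`` turns clean labels into a plausible imperfect probability
map (soft borders, salt-and-pepper flips, spurious blobs) so post-processing
and metrics are testable without training a model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FixtureSpec", "make_volume", "corrupt_labels"]


@dataclass
class FixtureSpec:
    """Stated world for one synthetic EM fixture volume.

    Semi-axes are in voxels (in-plane major axis sampled from
    ``size_range``); ``anisotropy`` divides the Z semi-axis, emulating
    coarser Z sampling.  Intensities are float in [0, 1]; writers rescale to
    8-bit on disk.
    """

    shape: tuple[int, int, int] = (16, 128, 128)
    n_organelles: int = 10
    size_range: tuple[float, float] = (5.0, 12.0)
    background_mean: float = 0.55
    background_sigma: float = 0.06
    interior_mean: float = 0.22
    interior_sigma: float = 0.05
    rim_mean: float = 0.80
    rim_sigma: float = 0.05
    rim_width: int = 2
    anisotropy: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(
            s < m for s, m in zip(self.shape, (8, 32, 32))
        ):
            raise ValueError("fixture shape must be 3D and at least (8, 32, 32)")
        if self.n_organelles < 0:
            raise ValueError("n_organelles must be >= 0")
        if self.anisotropy < 1.0:
            raise ValueError("anisotropy factor must be >= 1")


def _ellipsoid_mask(shape, center, semi, angle) -> np.ndarray:
    """Voxelised rotated ellipsoid (rotation in the Y-X plane)."""
    zc, yc, xc = center
    cz, cy, cx = semi
    zmax = int(np.ceil(cz)) + 1
    rmax = int(np.ceil(max(cy, cx))) + 1
    z0, z1 = max(0, int(zc) - zmax), min(shape[0], int(zc) + zmax + 1)
    y0, y1 = max(0, int(yc) - rmax), min(shape[1], int(yc) + rmax + 1)
    x0, x1 = max(0, int(xc) - rmax), min(shape[2], int(xc) + rmax + 1)
    z, y, x = np.ogrid[z0:z1, y0:y1, x0:x1]
    dz, dy, dx = z - zc, y - yc, x - xc
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dy + sa * dx
    v = -sa * dy + ca * dx
    inside = (dz / cz) ** 2 + (u / cy) ** 2 + (v / cx) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[z0:z1, y0:y1, x0:x1] = inside
    return mask


def make_volume(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (volume, labels) pair.

    Organelles are placed fully inside the bounds; a candidate overlapping
    existing foreground by more than 50% of its own volume is re-drawn.  If
    placement keeps failing, fewer organelles are placed and a warning is
    emitted.  The same seed always yields the same pair.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    placed = 0
    attempts = 0
    max_attempts = max(20, 20 * spec.n_organelles)
    while placed < spec.n_organelles and attempts < max_attempts:
        attempts += 1
        a = rng.uniform(*spec.size_range)  # in-plane major semi-axis
        b = a * rng.uniform(0.45, 0.85)
        cz = max(1.5, a * rng.uniform(0.45, 0.85) / spec.anisotropy)
        angle = rng.uniform(0, np.pi)
        margin_z, margin_p = cz + 1, a + 1
        if (
            2 * margin_z >= spec.shape[0]
            or 2 * margin_p >= min(spec.shape[1], spec.shape[2])
        ):
            continue
        center = (
            rng.uniform(margin_z, spec.shape[0] - margin_z),
            rng.uniform(margin_p, spec.shape[1] - margin_p),
            rng.uniform(margin_p, spec.shape[2] - margin_p),
        )
        mask = _ellipsoid_mask(spec.shape, center, (cz, b, a), angle)
        n_new = int(mask.sum())
        if n_new == 0:
            continue
        if int((mask & (labels > 0)).sum()) > 0.5 * n_new:
            continue
        labels[mask] = 1
        placed += 1
    if placed < spec.n_organelles:
        warnings.warn(
            f"placed only {placed}/{spec.n_organelles} organelles without "
            "excessive overlap", stacklevel=2,
        )
    volume = rng.normal(spec.background_mean, spec.background_sigma, spec.shape)
    interior = labels > 0
    volume[interior] = rng.normal(spec.interior_mean, spec.interior_sigma, int(interior.sum()))
    struct = np.zeros((3, 3, 3), dtype=bool)
    struct[1] = True  # in-plane rim, matching per-slice membrane appearance
    rim = ndimage.binary_dilation(interior, struct, iterations=spec.rim_width) & ~interior
    volume[rim] = rng.normal(spec.rim_mean, spec.rim_sigma, int(rim.sum()))
    # slight in-plane smoothing so edges are not one-voxel sharp
    volume = ndimage.gaussian_filter(volume, sigma=(0.0, 0.6, 0.6))
    return np.clip(volume, 0.0, 1.0).astype(np.float32), labels


def corrupt_labels(
    labels: np.ndarray,
    flip_rate: float = 0.0,
    border_jitter: float = 0.0,
    spurious_blobs: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate an imperfect network prediction from clean labels.

    ``border_jitter`` flips voxels in the 1-voxel boundary band with the
    given probability; ``flip_rate`` flips voxels anywhere; ``spurious_blobs``
    adds that many small high-probability blobs on background.  Flipped
    voxels land on the wrong side of 0.5 with random confidence.  With all
    rates zero the output equals the labels exactly (as float probabilities).
    """
    if not (0.0 <= flip_rate < 1.0 and 0.0 <= border_jitter < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels)
    prob = lab.astype(np.float32).copy()

    def _flip(sel: np.ndarray) -> None:
        conf = rng.uniform(0.55, 0.95, int(sel.sum())).astype(np.float32)
        prob[sel] = np.abs(lab[sel].astype(np.float32) - conf)

    if border_jitter > 0.0:
        struct = ndimage.generate_binary_structure(lab.ndim, 1)
        band = ndimage.binary_dilation(lab > 0, struct) ^ ndimage.binary_erosion(
            lab > 0, struct
        )
        _flip(band & (rng.random(lab.shape) < border_jitter))
    if flip_rate > 0.0:
        _flip(rng.random(lab.shape) < flip_rate)
    if spurious_blobs > 0:
        bg = lab == 0
        if lab.ndim == 3:
            nz, ny, nx = lab.shape
        else:
            nz, (ny, nx) = 1, lab.shape
        for _ in range(spurious_blobs):
            r = int(rng.integers(1, 4))
            z = int(rng.integers(0, nz))
            y = int(rng.integers(r, max(r + 1, ny - r)))
            x = int(rng.integers(r, max(r + 1, nx - r)))
            yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
            disk = yy**2 + xx**2 <= r**2
            sl = (slice(y - r, y + r + 1), slice(x - r, x + r + 1))
            if lab.ndim == 3:
                sl = (z,) + sl
            region = prob[sl]
            region[disk & (bg[sl])] = rng.uniform(0.7, 0.95)
    return np.clip(prob, 0.0, 1.0)
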