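"""Volume I/O: multipage TIFF stacks, directories of 2D slices, HDF5.

Axis order is (Z, Y, X) everywhere; coordinates are 0-based with half-open
ranges.  Float volumes are stored as 32-bit TIFF; binary masks and 8-bit
images as uint8.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["read_volume", "write_volume", "write_slice_dir", "write_fixture_layout"]

_SLICE_EXTS = (".tif", ".tiff", ".png")


def read_volume(path, dataset: str = "raw") -> np.ndarray:
    """Read a volume from a TIFF stack, a directory of 2D slices, or HDF5."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTS
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG slices found in {path}")
        slices = [iio.imread(f) for f in files]
        return np.stack(slices, axis=0)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            return fh[dataset][()]
    return tifffile.imread(path)


def write_volume(path, volume: np.ndarray, dataset: str = "raw") -> None:
    """Write a (Z,Y,X) volume (or 2D image) as TIFF or into an HDF5 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(volume)
    if path.suffix.lower() in (".h5", ".hdf5"):
        mode = "a" if path.exists() else "w"
        with h5py.File(path, mode) as fh:
            if dataset in fh:
                del fh[dataset]
            fh.create_dataset(dataset, data=arr, compression="gzip")
        return
    tifffile.imwrite(path, arr)


def write_slice_dir(path, volume: np.ndarray, fmt: str = ".tif") -> None:
    """Write each Z slice of a volume as a numbered 2D image in a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for z in range(volume.shape[0]):
        target = path / f"{z:04d}{fmt}"
        if fmt in (".tif", ".tiff"):
            tifffile.imwrite(target, volume[z])
        else:
            iio.imwrite(target, volume[z])


def _to_uint8(vol: np.ndarray) -> np.ndarray:
    if vol.dtype == np.uint8:
        return vol
    if np.issubdtype(vol.dtype, np.floating):
        return np.clip(np.round(vol * 255), 0, 255).astype(np.uint8)
    return vol.astype(np.uint8)


def write_fixture_layout(root, train, train_labels, test, test_labels) -> dict[str, str]:
    """Write a ready-to-train dataset layout mirroring the public EM datasets.

    Layout: ``train/x``, ``train/y``, ``test/x``, ``test/y``, each a
    multipage TIFF stack (8-bit images, 0/255 masks).
    """
    root = Path(root)
    out = {}
    for split, vol, lab in (("train", train, train_labels), ("test", test, test_labels)):
        lab8 = _to_uint8(lab) * np.uint8(255) if arr_is_binary(lab) else _to_uint8(lab)
        for sub, arr in (("x", _to_uint8(vol)), ("y", lab8)):
            d = root / split / sub
            d.mkdir(parents=True, exist_ok=True)
            target = d / f"{split}_{sub}.tif"
            tifffile.imwrite(target, arr)
            out[f"{split}/{sub}"] = os.fspath(target)
    return out


def arr_is_binary(arr: np.ndarray) -> bool:
    return bool(np.isin(np.unique(arr), (0, 1)).all())
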