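"""Readers and writers for volumes and checkpoints.

Volumes: multi-page TIFF (page axis = z), HDF5 ("/raw" float32 intensity,
"/labels" uint8 labels, group attribute "anisotropy"), and PNG for single
2-D images.  Axis order is (z, y, x) everywhere.  Checkpoints: HDF5 with
one dataset per parameter, the family map as group attributes, and the
config snapshots as JSON attributes; round trips are bit-exact.
"""

from __future__ import annotations

import json
import os
from typing import Dict, Optional, Tuple

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .train import Checkpoint

TIFF_EXT = (".tif", ".tiff")
HDF5_EXT = (".h5", ".hdf5")


class FormatError(ValueError):
    pass


def write_volume(array: np.ndarray, path: str,
                 anisotropy: float = 1.0, key: str = "/raw") -> None:
    """Write a 2-D/3-D array; format chosen by extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext in TIFF_EXT:
        tifffile.imwrite(path, array)
    elif ext in HDF5_EXT:
        with h5py.File(path, "a") as f:
            if key in f:
                del f[key]
            f.create_dataset(key, data=array)
            f.attrs["anisotropy"] = float(anisotropy)
    elif ext == ".png":
        if array.ndim != 2:
            raise FormatError("PNG supports 2-D images only")
        if array.dtype != np.uint8:
            array = np.clip(np.round(array * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(path, array)
    else:
        raise FormatError(f"unsupported volume extension {ext!r} ({path})")


def read_volume(path: str, key: str = "/raw") -> Tuple[np.ndarray, dict]:
    """Read a volume and its metadata (axis order, anisotropy)."""
    ext = os.path.splitext(path)[1].lower()
    meta = {"axis_order": "zyx", "anisotropy": 1.0}
    if ext in TIFF_EXT:
        return tifffile.imread(path), meta
    if ext in HDF5_EXT:
        with h5py.File(path, "r") as f:
            if key not in f:
                raise FormatError(
                    f"HDF5 file {path} has no dataset {key!r}; "
                    f"available: {sorted(f.keys())}")
            meta["anisotropy"] = float(f.attrs.get("anisotropy", 1.0))
            return f[key][()], meta
    if ext == ".png":
        img = np.asarray(iio.imread(path))
        if img.ndim == 3:
            img = img[..., 0]
        return img, meta
    raise FormatError(f"unsupported volume extension {ext!r} ({path})")


def write_corpus(images, directory: str, fmt: str = "tiff") -> list:
    """Write a corpus of 2-D grayscale patches as numbered files."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        if fmt == "png":
            p = os.path.join(directory, f"patch_{i:05d}.png")
        else:
            p = os.path.join(directory, f"patch_{i:05d}.tiff")
        write_volume(np.asarray(img, dtype=np.float32 if fmt != "png" else img.dtype), p)
        paths.append(p)
    return paths


def read_corpus(directory: str) -> list:
    """Read every PNG/TIFF patch in a directory, sorted by name.

    8-bit images are rescaled to float32 in [0,1]."""
    names = sorted(n for n in os.listdir(directory)
                   if os.path.splitext(n)[1].lower() in TIFF_EXT + (".png",))
    if not names:
        raise FormatError(f"no PNG/TIFF patches found in {directory}")
    images = []
    for n in names:
        arr, _ = read_volume(os.path.join(directory, n))
        if arr.dtype == np.uint8:
            arr = arr.astype(np.float32) / 255.0
        images.append(arr.astype(np.float32))
    return images


def save_checkpoint(ckpt: Checkpoint, path: str) -> None:
    """Write a checkpoint to HDF5 (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("params")
        for name, arr in ckpt.arrays.items():
            grp.create_dataset(name, data=arr)
        f.attrs["families"] = json.dumps(ckpt.families)
        f.attrs["model_config"] = json.dumps(ckpt.model_config)
        f.attrs["train_config"] = json.dumps(ckpt.train_config)
        f.attrs["iteration"] = ckpt.iteration
        f.create_dataset("loss_history",
                         data=np.asarray(ckpt.loss_history, dtype=np.float64))


def load_checkpoint(path: str) -> Checkpoint:
    with h5py.File(path, "r") as f:
        if "families" not in f.attrs:
            raise FormatError(f"corrupt checkpoint {path}: family map missing")
        arrays = {name: f["params"][name][()] for name in f["params"]}
        return Checkpoint(
            arrays=arrays,
            families=json.loads(f.attrs["families"]),
            model_config=json.loads(f.attrs["model_config"]),
            train_config=json.loads(f.attrs["train_config"]),
            iteration=int(f.attrs["iteration"]),
            loss_history=list(f["loss_history"][()]),
        )
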