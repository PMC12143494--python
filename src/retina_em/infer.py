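"""Volumetric inference with a 2-D segmentation model.

A 3-D volume, axis order (z, y, x), is sliced along one of three planes:
xy slices index z, xz slices index y, yz slices index x.  Each slice is
tiled with non-overlapping tiles of the model input size (border tiles are
reflection-padded; slices smaller than a tile are padded up), the tiles are
segmented, and the per-class probabilities are stitched back.  For
isotropic volumes, orthoplane inference averages the xy, xz and yz
probability volumes voxel-wise; for anisotropic volumes only the xy plane
is reliable and should be used alone.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Tuple

import numpy as np

from . import nn
from .model import SegModel
from .synthetic import LabelVolume

PLANES = ("xy", "xz", "yz")

# plane -> (indexing axis, in-plane axes) in (z, y, x) order
_PLANE_AXES: Dict[str, Tuple[int, Tuple[int, int]]] = {
    "xy": (0, (1, 2)),
    "xz": (1, (0, 2)),
    "yz": (2, (0, 1)),
}


def slice_volume(volume: np.ndarray, plane: str) -> Tuple[List[np.ndarray], int]:
    """Cut a (z, y, x) volume into ordered 2-D slices along ``plane``.

    Returns the slices and the axis index they were taken along, so that
    ``reassemble_slices`` restores the volume bit-exactly.
    """
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}, got {plane!r}")
    if volume.ndim == 2:
        if plane != "xy":
            raise ValueError("2-D input only supports the xy plane")
        return [volume], 0
    if volume.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D volume, got ndim={volume.ndim}")
    axis = _PLANE_AXES[plane][0]
    moved = np.moveaxis(volume, axis, 0)
    return [np.ascontiguousarray(moved[i]) for i in range(moved.shape[0])], axis


def reassemble_slices(slices: List[np.ndarray], axis: int) -> np.ndarray:
    """Inverse of ``slice_volume``."""
    return np.moveaxis(np.stack(slices, axis=0), 0, axis)


def _pad_to(img: np.ndarray, target: Tuple[int, int]) -> np.ndarray:
    """Reflection-pad ``img`` up to ``target``, repeating reflection when the
    image is smaller than the padding it needs."""
    out = img
    while out.shape[0] < target[0] or out.shape[1] < target[1]:
        pad0 = min(max(target[0] - out.shape[0], 0), out.shape[0] - 1) \
            if out.shape[0] > 1 else max(target[0] - out.shape[0], 0)
        pad1 = min(max(target[1] - out.shape[1], 0), out.shape[1] - 1) \
            if out.shape[1] > 1 else max(target[1] - out.shape[1], 0)
        mode = "reflect" if min(out.shape) > 1 else "edge"
        out = np.pad(out, ((0, pad0), (0, pad1)), mode=mode)
    return out


def predict_slice(model: SegModel, image: np.ndarray,
                  batch_tiles: int = 8) -> np.ndarray:
    """Segment one 2-D slice of arbitrary size.

    The slice is covered by a grid of non-overlapping ``input_size`` tiles
    (padded at the borders) and the per-class probabilities are stitched.
    Returns float32 probabilities shaped (n_classes, H, W).
    """
    s = model.config.input_size
    H, W = image.shape
    padded = _pad_to(image.astype(np.float32), (max(H, s), max(W, s)))
    nh = int(np.ceil(H / s))
    nw = int(np.ceil(W / s))
    padded = _pad_to(padded, (nh * s, nw * s))
    tiles, coords = [], []
    for i in range(nh):
        for j in range(nw):
            tiles.append(padded[i * s:(i + 1) * s, j * s:(j + 1) * s])
            coords.append((i, j))
    out = np.zeros((model.config.n_classes, nh * s, nw * s), dtype=np.float32)
    for k in range(0, len(tiles), batch_tiles):
        chunk = np.stack(tiles[k:k + batch_tiles])[:, None, :, :]
        probs = model.segment(nn.Tensor(chunk)).data
        for (i, j), p in zip(coords[k:k + batch_tiles], probs):
            out[:, i * s:(i + 1) * s, j * s:(j + 1) * s] = p
    return out[:, :H, :W]


def predict_plane(model: SegModel, volume: np.ndarray, plane: str,
                  batch_tiles: int = 8) -> np.ndarray:
    """Slice-wise prediction along one plane.

    Returns a probability volume shaped (n_classes, z, y, x) aligned with
    the input volume; every voxel's class probabilities sum to 1.
    """
    slices, axis = slice_volume(volume, plane)
    pred_slices = [predict_slice(model, sl, batch_tiles) for sl in slices]
    # each pred slice is (C, h, w); stack along the slicing axis (+1 for C)
    stacked = np.stack(pred_slices, axis=axis + 1)
    if volume.ndim == 2:
        return pred_slices[0]
    return stacked


def orthoplane_predict(model: SegModel, volume: np.ndarray,
                       anisotropy_factor: float = 1.0,
                       batch_tiles: int = 8) -> np.ndarray:
    """Average the xy, xz and yz probability volumes voxel-wise.

    Intended for isotropic volumes; a warning is issued when the stated
    anisotropy factor exceeds 1 (non-xy slices are then distorted).
    """
    if anisotropy_factor > 1.0:
        warnings.warn(
            f"orthoplane prediction on an anisotropic volume "
            f"(factor {anisotropy_factor}); consider xy-only prediction",
            stacklevel=2)
    acc = None
    for plane in PLANES:
        p = predict_plane(model, volume, plane, batch_tiles)
        acc = p if acc is None else acc + p
    return acc / 3.0


def labels_from_probs(probs: np.ndarray,
                      anisotropy_factor: float = 1.0) -> LabelVolume:
    """Voxel-wise argmax over the class axis (axis 0).

    Ties break toward the smaller class ID (numpy argmax convention).
    """
    if probs.ndim not in (3, 4):
        raise ValueError(
            f"expected (n_classes, H, W) or (n_classes, z, y, x), "
            f"got shape {probs.shape}")
    labels = np.argmax(probs, axis=0).astype(np.uint8)
    return LabelVolume(labels, anisotropy_factor=anisotropy_factor)
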