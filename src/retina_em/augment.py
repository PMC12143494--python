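"""Paired augmentation for reconstruction pre-training.

Each training example is built from one clean image: a geometric transform
(flips + right-angle rotation, exactly invertible) is applied to get the
reconstruction target ImageB, and a stack of corruptions (brightness /
contrast, Gaussian noise, Gaussian blur, rectangular patch masking) is
applied on top of ImageB to get the network input ImageA.  Because the
target carries the same geometric transform as the input, the
reconstruction loss compares geometrically aligned images.

Two operation sets: the geometric set applies to both images of the pair;
the corruption set applies only to the network input.  Flips and rotation
are each applied with probability 0.5; the number of masked patches is
uniform on a configurable integer range (default 1..32).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import numpy as np
from scipy import ndimage


class AugmentationConfigError(ValueError):
    pass


@dataclass
class GeometricRecord:
    """Exactly invertible transform: horizontal/vertical flips then a
    counter-clockwise rotation by ``rot90_k`` quarter turns."""

    flip_h: bool = False
    flip_v: bool = False
    rot90_k: int = 0

    def __post_init__(self) -> None:
        if self.rot90_k not in (0, 1, 2, 3):
            raise ValueError("rot90_k must be in {0,1,2,3}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeometricRecord":
        return cls(**d)


@dataclass
class CorruptionRecord:
    """Photometric and occlusion corruptions applied to the network input.

    Applied in fixed order: brightness/contrast -> noise -> blur -> clip to
    [0,1] -> patch masking.  ``mask_patches`` holds (row, col, size)
    top-left corners; patches may overlap and must lie inside the image.
    """

    brightness_delta: float = 0.0
    contrast_gain: float = 1.0
    noise_sd: float = 0.0
    blur_sd: float = 0.0
    mask_patches: List[Tuple[int, int, int]] = field(default_factory=list)
    fill_value: float = 0.0
    noise_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mask_patches"] = [list(p) for p in self.mask_patches]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CorruptionRecord":
        d = dict(d)
        d["mask_patches"] = [tuple(p) for p in d.get("mask_patches", [])]
        return cls(**d)


@dataclass
class AugmentedPair:
    """Corrupted input, aligned clean target, and the records that made them."""

    input_image: np.ndarray
    target_image: np.ndarray
    geometric: GeometricRecord
    corruption: CorruptionRecord


@dataclass
class AugmentationConfig:
    """Sampling distributions for the two augmentation sets.

    Probabilities are per-operation; ranges are uniform.  The default
    parameter values are artifact choices documented in the methods note.
    """

    p_flip: float = 0.5
    p_rotate: float = 0.5
    p_brightness_contrast: float = 0.5
    p_noise: float = 0.5
    p_blur: float = 0.5
    p_mask: float = 1.0
    brightness_range: Tuple[float, float] = (-0.2, 0.2)
    contrast_range: Tuple[float, float] = (0.8, 1.2)
    noise_sd_range: Tuple[float, float] = (0.0, 0.05)
    blur_sd_range: Tuple[float, float] = (0.0, 1.5)
    mask_count_range: Tuple[int, int] = (1, 32)
    mask_patch_size: int = 16
    mask_fill_value: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_flip", "p_rotate", "p_brightness_contrast", "p_noise",
                     "p_blur", "p_mask"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise AugmentationConfigError(f"{name}={v} not in [0,1]")
        for name in ("brightness_range", "contrast_range", "noise_sd_range",
                     "blur_sd_range", "mask_count_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise AugmentationConfigError(f"{name} range empty: ({lo},{hi})")
        if self.mask_count_range[0] < 0:
            raise AugmentationConfigError("mask count must be >= 0")
        if self.mask_patch_size < 1:
            raise AugmentationConfigError("mask_patch_size must be >= 1")


def sample_records(rng: np.random.Generator, config: AugmentationConfig,
                   image_shape: Tuple[int, int]) -> Tuple[GeometricRecord,
                                                          CorruptionRecord]:
    """Draw one (geometric, corruption) record pair from the config."""
    flip_h = bool(rng.random() < config.p_flip)
    flip_v = bool(rng.random() < config.p_flip)
    if rng.random() < config.p_rotate:
        k = int(rng.integers(1, 4))
    else:
        k = 0
    geo = GeometricRecord(flip_h=flip_h, flip_v=flip_v, rot90_k=k)

    delta, gain = 0.0, 1.0
    if rng.random() < config.p_brightness_contrast:
        delta = float(rng.uniform(*config.brightness_range))
        gain = float(rng.uniform(*config.contrast_range))
    noise_sd = (float(rng.uniform(*config.noise_sd_range))
                if rng.random() < config.p_noise else 0.0)
    blur_sd = (float(rng.uniform(*config.blur_sd_range))
               if rng.random() < config.p_blur else 0.0)
    patches: List[Tuple[int, int, int]] = []
    if rng.random() < config.p_mask:
        count = int(rng.integers(config.mask_count_range[0],
                                 config.mask_count_range[1] + 1))
        h, w = image_shape
        size = min(config.mask_patch_size, h, w)
        for _ in range(count):
            r = int(rng.integers(0, h - size + 1))
            c = int(rng.integers(0, w - size + 1))
            patches.append((r, c, size))
    corr = CorruptionRecord(
        brightness_delta=delta, contrast_gain=gain, noise_sd=noise_sd,
        blur_sd=blur_sd, mask_patches=patches,
        fill_value=config.mask_fill_value,
        noise_seed=int(rng.integers(0, 2 ** 31 - 1)))
    return geo, corr


def apply_geometric(image: np.ndarray, record: GeometricRecord) -> np.ndarray:
    """Apply flips (horizontal then vertical) then a CCW quarter-turn
    rotation.  Exactly invertible; shape-preserving on square images."""
    if image.ndim != 2:
        raise ValueError(f"expected 2-D image, got ndim={image.ndim}")
    out = image
    if record.flip_h:
        out = out[:, ::-1]
    if record.flip_v:
        out = out[::-1, :]
    if record.rot90_k:
        out = np.rot90(out, k=record.rot90_k)
    return np.ascontiguousarray(out)


def invert_geometric(image: np.ndarray, record: GeometricRecord) -> np.ndarray:
    """Undo ``apply_geometric`` exactly."""
    if image.ndim != 2:
        raise ValueError(f"expected 2-D image, got ndim={image.ndim}")
    out = image
    if record.rot90_k:
        out = np.rot90(out, k=-record.rot90_k)
    if record.flip_v:
        out = out[::-1, :]
    if record.flip_h:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def corrupt(image: np.ndarray, record: CorruptionRecord) -> np.ndarray:
    """Apply photometric corruptions then patch masking.

    Order is brightness/contrast -> noise -> blur; the result is clipped to
    [0,1] before the masked patches are written with ``fill_value``, so the
    fill value survives exactly.
    """
    h, w = image.shape
    for (r, c, s) in record.mask_patches:
        if r < 0 or c < 0 or r + s > h or c + s > w:
            raise ValueError(f"mask patch ({r},{c},{s}) outside {h}x{w} image")
    out = image.astype(np.float32, copy=True)
    if record.contrast_gain != 1.0 or record.brightness_delta != 0.0:
        out = (out - 0.5) * record.contrast_gain + 0.5 + record.brightness_delta
    if record.noise_sd > 0:
        noise_rng = np.random.default_rng(record.noise_seed)
        out = out + noise_rng.normal(0.0, record.noise_sd,
                                     size=out.shape).astype(np.float32)
    if record.blur_sd > 0:
        out = ndimage.gaussian_filter(out, sigma=record.blur_sd)
    out = np.clip(out, 0.0, 1.0)
    for (r, c, s) in record.mask_patches:
        out[r:r + s, c:c + s] = record.fill_value
    return out.astype(np.float32)


def make_pair(image: np.ndarray, rng: np.random.Generator,
              config: AugmentationConfig) -> AugmentedPair:
    """Sample records and build an aligned (input, target) pair."""
    if image.ndim != 2:
        raise ValueError(f"expected 2-D grayscale image, got ndim={image.ndim}")
    if image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square image, got {image.shape}")
    geo, corr = sample_records(rng, config, image.shape)
    target = apply_geometric(image, geo)
    inp = corrupt(target, corr)
    return AugmentedPair(input_image=inp, target_image=target,
                         geometric=geo, corruption=corr)


def replay_pair(image: np.ndarray, geo: GeometricRecord,
                corr: CorruptionRecord) -> AugmentedPair:
    """Rebuild a pair from stored records, bit-exactly."""
    target = apply_geometric(image, geo)
    inp = corrupt(target, corr)
    return AugmentedPair(input_image=inp, target_image=target,
                         geometric=geo, corruption=corr)
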