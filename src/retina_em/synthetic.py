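"""Synthetic EM-like image and volume generation.

Desk-scale stand-in for an unlabeled electron-microscopy patch corpus and
for labeled benchmark volumes: background texture is Gaussian-blurred white
noise rescaled to a mid-grey band, and "organelles" are soft-edged ellipses
(2-D) or ellipsoids (3-D) that raise or lower local intensity, so that a
segmentation model has real contrast to learn from.  Everything is driven
by a single integer seed; identical specs give bit-identical outputs.

This emulates the geometry and value range of EM patch data (grayscale,
224x224 by default, intensities in [0,1]) — not the content statistics of
real micrographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage


@dataclass
class LabelVolume:
    """Integer class-ID array (2-D or 3-D) with axis-order metadata.

    ``data`` uses axis order (z, y, x) for 3-D and (y, x) for 2-D;
    ``anisotropy_factor`` is the ratio of z spacing to in-plane spacing
    (1.0 = isotropic).
    """

    data: np.ndarray
    anisotropy_factor: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be an integer array")
        if self.anisotropy_factor < 1.0:
            raise ValueError("anisotropy_factor must be >= 1")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def spacing(self) -> Tuple[float, ...]:
        """Voxel spacing in (z, y, x) units of the in-plane spacing."""
        if self.data.ndim == 3:
            return (self.anisotropy_factor, 1.0, 1.0)
        return (1.0, 1.0)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic generator.

    image_size: side length of 2-D corpus patches in pixels.
    volume_shape: (depth, height, width) of generated volumes in voxels.
    n_classes: number of foreground classes (1-8); labels are {0..n_classes}.
    objects_per_class: inclusive range of object counts per class.
    object_scale: inclusive range of ellipsoid semi-axes in voxels.
    texture_noise_sd: standard deviation of the blurred background noise
        before rescaling, in intensity units.
    anisotropy_factor: z spacing over xy spacing; 1 means isotropic.
    seed: generator seed; fixes all randomness.
    """

    image_size: int = 224
    volume_shape: Tuple[int, int, int] = (32, 64, 64)
    n_classes: int = 2
    objects_per_class: Tuple[int, int] = (2, 4)
    object_scale: Tuple[float, float] = (4.0, 10.0)
    texture_noise_sd: float = 0.1
    anisotropy_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_classes > 8:
            raise ValueError("n_classes must be in 1..8")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape entries must be positive")
        lo, hi = self.objects_per_class
        if lo > hi or lo < 0:
            raise ValueError("objects_per_class range is empty or negative")
        lo, hi = self.object_scale
        if lo > hi or lo <= 0:
            raise ValueError("object_scale range is empty or non-positive")
        if self.anisotropy_factor < 1.0:
            raise ValueError("anisotropy_factor must be >= 1")


def _background(rng: np.random.Generator, shape: Tuple[int, ...],
                noise_sd: float, blur: float = 2.0) -> np.ndarray:
    """Blurred white noise rescaled to [0.3, 0.7] (mid-grey EM-ish texture)."""
    noise = rng.normal(0.0, max(noise_sd, 1e-8), size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=blur)
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5, dtype=np.float32)
    return (0.3 + 0.4 * (smooth - lo) / (hi - lo)).astype(np.float32)


def _soft_ellipsoid(shape: Tuple[int, ...], center: np.ndarray,
                    axes: np.ndarray, edge: float = 1.5) -> np.ndarray:
    """Soft-edged indicator of an axis-aligned ellipsoid, values in [0,1]."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    r = np.sqrt(r2)
    # 1 inside, smooth ramp of width ~edge/min(axes) around the boundary
    ramp = np.clip((1.0 - r) * (min(axes) / edge) + 0.5, 0.0, 1.0)
    return ramp.astype(np.float32)


def _draw_objects(rng: np.random.Generator, intensity: np.ndarray,
                  labels: np.ndarray, spec: SyntheticSpec,
                  anisotropic_z: bool) -> None:
    """Add soft ellipsoidal objects per class; later classes overwrite labels."""
    shape = intensity.shape
    for cls in range(1, spec.n_classes + 1):
        n_obj = int(rng.integers(spec.objects_per_class[0],
                                 spec.objects_per_class[1] + 1))
        # alternate bright/dark per class so classes are distinguishable
        sign = 1.0 if cls % 2 == 1 else -1.0
        for _ in range(n_obj):
            center = np.array([rng.uniform(0, s - 1) for s in shape])
            axes = rng.uniform(spec.object_scale[0], spec.object_scale[1],
                               size=len(shape))
            if anisotropic_z and len(shape) == 3:
                # objects span fewer z slices when z sampling is coarser
                axes[0] = max(axes[0] / spec.anisotropy_factor, 1.0)
            mask = _soft_ellipsoid(shape, center, axes)
            offset = sign * rng.uniform(0.15, 0.30)
            intensity += offset * mask
            labels[mask > 0.5] = cls
    np.clip(intensity, 0.0, 1.0, out=intensity)


def generate_pretrain_corpus(n: int, spec: SyntheticSpec) -> List[np.ndarray]:
    """Generate ``n`` grayscale patches emulating an unlabeled EM corpus.

    Each image is ``image_size`` square, float32 in [0,1], and contains
    smoothed texture plus dark/bright blob structures.
    """
    if n < 0:
        raise ValueError(f"corpus size must be >= 0, got {n}")
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_size, spec.image_size)
    images = []
    for _ in range(n):
        img = _background(rng, shape, spec.texture_noise_sd)
        labels = np.zeros(shape, dtype=np.uint8)
        _draw_objects(rng, img, labels, spec, anisotropic_z=False)
        images.append(img)
    return images


def generate_labeled_volume(spec: SyntheticSpec) -> Tuple[np.ndarray, LabelVolume]:
    """Generate an (intensity volume, label volume) pair.

    The intensity volume is float32 in [0,1] with shape ``volume_shape``;
    labels are uint8 in {0..n_classes} on the same grid, with the
    anisotropy factor recorded as metadata.
    """
    if spec.object_scale[1] > max(spec.volume_shape):
        raise ValueError(
            f"object_scale {spec.object_scale} exceeds volume_shape "
            f"{spec.volume_shape}")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.volume_shape)
    intensity = _background(rng, shape, spec.texture_noise_sd)
    labels = np.zeros(shape, dtype=np.uint8)
    _draw_objects(rng, intensity, labels, spec,
                  anisotropic_z=spec.anisotropy_factor > 1)
    return intensity, LabelVolume(labels, anisotropy_factor=spec.anisotropy_factor)


def split_dataset(pair: Tuple[np.ndarray, LabelVolume], train_fraction: float,
                  seed: int = 0) -> Tuple[Tuple[np.ndarray, LabelVolume],
                                          Tuple[np.ndarray, LabelVolume]]:
    """Split a volume into contiguous train/test blocks along the z axis.

    The split mirrors benchmark practice of holding out whole sub-volumes
    rather than interleaved slices; both blocks are non-empty.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    intensity, labels = pair
    depth = intensity.shape[0]
    if depth < 2:
        raise ValueError("volume must have at least 2 slices to split")
    n_train = int(round(depth * train_fraction))
    n_train = min(max(n_train, 1), depth - 1)
    train = (intensity[:n_train].copy(),
             LabelVolume(labels.data[:n_train].copy(), labels.anisotropy_factor))
    test = (intensity[n_train:].copy(),
            LabelVolume(labels.data[n_train:].copy(), labels.anisotropy_factor))
    return train, test
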