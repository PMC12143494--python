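"""Training: reconstruction pre-training, parameter transfer, freezing, and
segmentation fine-tuning.

Pre-training minimises mean squared error between the reconstruction of the
corrupted input and the geometrically aligned clean target.  Fine-tuning
transfers the pre-trained transformer family into a fresh model, freezes it
(the convolutional encoder, decoder and head stay trainable, letting the
local feature extractor adapt to the labeled dataset while the globally
pre-trained attention layers are preserved), and minimises a pixel-wise
cross-entropy plus soft-Dice loss.

The optimizer is SGD with momentum 0.9 and polynomial per-iteration
learning-rate decay; every iteration is one batch-level update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import augment, nn
from .model import FAMILY_NAMES, ModelConfig, SegModel

LOSSES = ("mse", "ce", "ce_dice")
OPTIMIZERS = ("sgd",)
SCHEDULES = ("poly", "constant")


@dataclass
class TrainConfig:
    """Hyperparameters of one training run (pre-training or fine-tuning)."""

    iterations: int = 100
    batch_size: int = 4
    learning_rate: float = 0.05
    lr_schedule: str = "poly"
    optimizer: str = "sgd"
    seed: int = 0
    loss: str = "ce_dice"
    freeze: Tuple[str, ...] = ()
    momentum: float = 0.9
    poly_power: float = 0.9
    augment_finetune: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}; choose from {LOSSES}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in SCHEDULES:
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        self.freeze = tuple(self.freeze)
        for fam in self.freeze:
            if fam not in FAMILY_NAMES:
                raise ValueError(
                    f"unknown parameter family {fam!r}; "
                    f"valid families: {FAMILY_NAMES}")

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations, "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "lr_schedule": self.lr_schedule, "optimizer": self.optimizer,
            "seed": self.seed, "loss": self.loss,
            "freeze": list(self.freeze), "momentum": self.momentum,
            "poly_power": self.poly_power,
            "augment_finetune": self.augment_finetune,
        }


@dataclass
class Checkpoint:
    """Snapshot of a trained model: arrays, family map, config, history."""

    arrays: Dict[str, np.ndarray]
    families: Dict[str, List[str]]
    model_config: dict
    train_config: dict
    iteration: int
    loss_history: List[float] = field(default_factory=list)


def _make_optimizer(model: SegModel, config: TrainConfig) -> nn.SGD:
    total = config.iterations if config.lr_schedule == "poly" else None
    return nn.SGD(model.params, lr=config.learning_rate,
                  momentum=config.momentum, total_iters=total,
                  poly_power=config.poly_power)


def _checkpoint_from(model: SegModel, config: TrainConfig,
                     history: List[float]) -> Checkpoint:
    fams = {k: sorted(v) for k, v in model.parameter_families().items()}
    return Checkpoint(arrays=model.state_arrays(), families=fams,
                      model_config=model.config.to_dict(),
                      train_config=config.to_dict(),
                      iteration=len(history), loss_history=list(history))


# ---------------------------------------------------------------------------
# pre-training
# ---------------------------------------------------------------------------

def mse_loss(pred: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    """Mean over batch and pixels of the squared reconstruction error."""
    diff = nn.add(pred, -np.asarray(target, dtype=np.float32))
    return nn.mean(nn.square(diff))


def pretrain_step(model: SegModel, batch: Sequence[augment.AugmentedPair],
                  optimizer: nn.SGD) -> float:
    """One reconstruction update on a batch of augmented pairs."""
    if len(batch) == 0:
        raise ValueError("pretrain_step requires a non-empty batch")
    x = np.stack([p.input_image for p in batch])[:, None, :, :]
    y = np.stack([p.target_image for p in batch])[:, None, :, :]
    optimizer.zero_grad()
    recon = model.reconstruct(nn.Tensor(x))
    loss = mse_loss(recon, y)
    loss.backward()
    optimizer.step()
    return float(loss.data)


def run_pretraining(corpus: Sequence[np.ndarray], model: SegModel,
                    config: TrainConfig,
                    aug_config: Optional[augment.AugmentationConfig] = None,
                    log_fn=None) -> Checkpoint:
    """Self-supervised reconstruction pre-training over an image corpus.

    Each iteration samples a batch of images (with replacement), builds
    fresh augmented pairs, and applies one optimizer update.  Returns a
    checkpoint whose loss history has one entry per iteration.
    """
    if len(corpus) == 0:
        raise ValueError("pre-training corpus is empty")
    aug_config = aug_config or augment.AugmentationConfig()
    rng = np.random.default_rng(config.seed)
    optimizer = _make_optimizer(model, config)
    history: List[float] = []
    for it in range(config.iterations):
        idx = rng.integers(0, len(corpus), size=config.batch_size)
        batch = [augment.make_pair(corpus[i], rng, aug_config) for i in idx]
        loss = pretrain_step(model, batch, optimizer)
        history.append(loss)
        if log_fn is not None:
            log_fn(it, loss, optimizer.current_lr())
    return _checkpoint_from(model, config, history)


# ---------------------------------------------------------------------------
# transfer and freezing
# ---------------------------------------------------------------------------

def transfer_transformer_params(source: Checkpoint, model: SegModel) -> SegModel:
    """Copy the transformer family from a checkpoint into ``model``.

    Bit-exact for every transformer array; all other families are left
    untouched.  Shape mismatches raise with the offending parameter name.
    """
    names = source.families.get("transformer", [])
    if not names:
        raise ValueError("source checkpoint has no transformer family")
    target_fams = model.parameter_families()["transformer"]
    for name in names:
        if name not in target_fams:
            raise ValueError(f"transformer parameter {name!r} missing in target")
        src = source.arrays[name]
        dst = model.params[name]
        if dst.data.shape != src.shape:
            raise ValueError(
                f"shape mismatch for {name!r}: source {src.shape}, "
                f"target {dst.data.shape}")
    for name in names:
        model.params[name].data = source.arrays[name].astype(np.float32).copy()
    return model


def set_trainable(model: SegModel, freeze: Sequence[str]) -> SegModel:
    """Freeze the named families; frozen parameters are excluded from
    optimizer updates and stay bit-identical across any number of steps."""
    freeze = set(freeze)
    unknown = freeze - set(FAMILY_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter families: {sorted(unknown)}")
    for name, p in model.params.items():
        p.trainable = model.family_of(name) not in freeze
    return model


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def ce_loss(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    """Mean pixel-wise cross-entropy; ``labels`` are integer class IDs."""
    B, C, H, W = logits.shape
    lp = nn.log_softmax(nn.transpose(logits, (0, 2, 3, 1)))
    onehot = np.eye(C, dtype=np.float32)[labels]          # (B,H,W,C)
    picked = nn.mul(lp, onehot)
    return nn.mul(nn.sum_all(picked), -1.0 / (B * H * W))


def dice_loss(logits: nn.Tensor, labels: np.ndarray,
              eps: float = 1e-6) -> nn.Tensor:
    """Soft Dice loss over all classes: 1 - 2|P∩Y| / (|P| + |Y|)."""
    B, C, H, W = logits.shape
    probs = nn.softmax(nn.transpose(logits, (0, 2, 3, 1)))   # (B,H,W,C)
    onehot = np.eye(C, dtype=np.float32)[labels]
    inter = nn.sum_all(nn.mul(probs, onehot))
    denom = nn.add(nn.sum_all(probs), float(onehot.sum()) + eps)
    dice = nn.mul(nn.mul(inter, 2.0), nn.reciprocal(denom))
    return nn.add(nn.mul(dice, -1.0), 1.0)


def segmentation_loss(logits: nn.Tensor, labels: np.ndarray,
                      kind: str) -> nn.Tensor:
    if kind == "ce":
        return ce_loss(logits, labels)
    if kind == "ce_dice":
        return nn.add(ce_loss(logits, labels), dice_loss(logits, labels))
    raise ValueError(f"unsupported segmentation loss {kind!r}")


def finetune_step(model: SegModel, images: np.ndarray, labels: np.ndarray,
                  optimizer: nn.SGD, loss_kind: str) -> float:
    optimizer.zero_grad()
    logits = model.segment_logits(nn.Tensor(images))
    loss = segmentation_loss(logits, labels, loss_kind)
    loss.backward()
    optimizer.step()
    return float(loss.data)


def _geometric_label_aug(rng: np.random.Generator, image: np.ndarray,
                         label: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Flips + right-angle rotation applied identically to image and label."""
    square = image.shape[0] == image.shape[1]
    rec = augment.GeometricRecord(
        flip_h=bool(rng.random() < 0.5), flip_v=bool(rng.random() < 0.5),
        rot90_k=int(rng.integers(0, 4)) if square
        else 2 * int(rng.integers(0, 2)))
    return (augment.apply_geometric(image, rec),
            augment.apply_geometric(label, rec))


def run_finetuning(dataset: Sequence[Tuple[np.ndarray, np.ndarray]],
                   model: SegModel, config: TrainConfig,
                   source: Optional[Checkpoint] = None,
                   log_fn=None) -> Checkpoint:
    """Supervised segmentation fine-tuning on labeled 2-D slices.

    ``dataset`` is a sequence of (image, label) pairs of equal spatial
    shape, labels integer in [0, n_classes).  If ``source`` is given its
    transformer family is transferred first; the families named in
    ``config.freeze`` are then frozen for the whole run.
    """
    if len(dataset) == 0:
        raise ValueError("fine-tuning dataset is empty")
    n_classes = model.config.n_classes
    for i, (img, lab) in enumerate(dataset):
        if img.shape != lab.shape:
            raise ValueError(
                f"slice {i}: image shape {img.shape} != label shape {lab.shape}")
        if lab.min() < 0 or lab.max() >= n_classes:
            raise ValueError(
                f"slice {i}: labels outside [0, {n_classes}): "
                f"range [{lab.min()}, {lab.max()}]")
    if source is not None:
        transfer_transformer_params(source, model)
    set_trainable(model, config.freeze)
    loss_kind = config.loss if config.loss != "mse" else "ce_dice"
    rng = np.random.default_rng(config.seed)
    optimizer = _make_optimizer(model, config)
    history: List[float] = []
    for it in range(config.iterations):
        idx = rng.integers(0, len(dataset), size=config.batch_size)
        imgs, labs = [], []
        for i in idx:
            img, lab = dataset[i]
            if config.augment_finetune:
                img, lab = _geometric_label_aug(rng, img, lab)
            imgs.append(img)
            labs.append(lab)
        x = np.stack(imgs)[:, None, :, :].astype(np.float32)
        y = np.stack(labs).astype(np.int64)
        loss = finetune_step(model, x, y, optimizer, loss_kind)
        history.append(loss)
        if log_fn is not None:
            log_fn(it, loss, optimizer.current_lr())
    set_trainable(model, ())
    return _checkpoint_from(model, config, history)
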