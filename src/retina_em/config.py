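"""YAML run configuration with strict validation.

A run config has per-stage blocks (``synthetic``, ``augmentation``,
``model``, ``train``, ``inference``, ``paths``) plus a global ``seed``.
Unknown keys are rejected so typos fail loudly; every command writes its
resolved config next to its outputs for reproducibility.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Any, Dict, Optional

import yaml

from .augment import AugmentationConfig
from .model import ModelConfig
from .synthetic import SyntheticSpec
from .train import TrainConfig


class RunConfigError(ValueError):
    pass


def _build(cls, block: Dict[str, Any], name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise RunConfigError(
            f"unknown keys in {name!r} block: {sorted(unknown)}; "
            f"valid keys: {sorted(fields)}")
    coerced = {}
    for k, v in block.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as e:
        raise RunConfigError(f"invalid {name!r} block: {e}") from e


_TOP_KEYS = {"seed", "synthetic", "augmentation", "model", "train",
             "inference", "paths"}
_INFER_KEYS = {"plane", "orthoplane", "batch_tiles"}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    synthetic: SyntheticSpec = dataclasses.field(default_factory=SyntheticSpec)
    augmentation: AugmentationConfig = dataclasses.field(
        default_factory=AugmentationConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    inference: Dict[str, Any] = dataclasses.field(
        default_factory=lambda: {"plane": "xy", "orthoplane": False,
                                 "batch_tiles": 8})
    paths: Dict[str, str] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "RunConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise RunConfigError(
                f"unknown top-level keys: {sorted(unknown)}; "
                f"valid keys: {sorted(_TOP_KEYS)}")
        seed = int(d.get("seed", 0))
        synth = dict(d.get("synthetic", {}))
        synth.setdefault("seed", seed)
        model = dict(d.get("model", {}))
        model.setdefault("seed", seed)
        train = dict(d.get("train", {}))
        train.setdefault("seed", seed)
        infer = dict(d.get("inference", {}))
        bad = set(infer) - _INFER_KEYS
        if bad:
            raise RunConfigError(
                f"unknown keys in 'inference' block: {sorted(bad)}")
        base = {"plane": "xy", "orthoplane": False, "batch_tiles": 8}
        base.update(infer)
        paths = d.get("paths", {})
        if not all(isinstance(v, str) for v in paths.values()):
            raise RunConfigError("'paths' values must be strings")
        return cls(
            seed=seed,
            synthetic=_build(SyntheticSpec, synth, "synthetic"),
            augmentation=_build(AugmentationConfig,
                                dict(d.get("augmentation", {})), "augmentation"),
            model=_build(ModelConfig, model, "model"),
            train=_build(TrainConfig, train, "train"),
            inference=base,
            paths=dict(paths),
        )

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        if not isinstance(d, dict):
            raise RunConfigError(f"config root must be a mapping ({path})")
        return cls.from_dict(d)

    def to_dict(self) -> Dict[str, Any]:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: plain(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        return {"seed": self.seed, "synthetic": plain(self.synthetic),
                "augmentation": plain(self.augmentation),
                "model": plain(self.model), "train": plain(self.train),
                "inference": plain(self.inference), "paths": plain(self.paths)}

    def write_resolved(self, out_dir: str, stem: str = "resolved_config") -> str:
        os.makedirs(out_dir, exist_ok=True)
        path = os.path.join(out_dir, f"{stem}.yaml")
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)
        return path
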