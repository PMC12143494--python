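"""Hybrid CNN-transformer encoder-decoder for 2-D EM segmentation.

The network follows the TransUNet layout: a stack of stride-2 convolutional
stages extracts a feature map from the input image; the feature map is
tokenised by a patch embedding; pre-norm transformer blocks (multi-head
self-attention + MLP) refine the tokens; the tokens are reshaped back to a
spatial grid and progressively upsampled, concatenating the convolutional
skip features at matching resolutions.  Two interchangeable heads sit on
top of the decoder: a single-channel reconstruction head (self-supervised
pre-training) and an ``n_classes``-channel segmentation head.

Every parameter belongs to exactly one named family — ``conv_encoder``,
``transformer``, ``decoder`` or ``head`` — which is the unit of transfer
and freezing between pre-training and fine-tuning.  The ``transformer``
family includes the patch embedding, the positional embedding, all block
weights and the final norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np

from . import nn
from .nn import Parameter, Tensor

FAMILY_NAMES = ("conv_encoder", "transformer", "decoder", "head")


class ConfigError(ValueError):
    """Raised when a model configuration violates a structural invariant."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by ``2**len(conv_channels) * patch_size``
    so the token grid is integral, and ``embed_dim`` by ``n_heads``.
    ``patch_size`` must be a power of two so the decoder's repeated 2x
    upsampling recovers the input resolution; ``decoder_channels`` must have
    one entry per upsampling stage, i.e. ``len(conv_channels) +
    log2(patch_size)`` entries.
    """

    input_size: int = 224
    conv_channels: Tuple[int, ...] = (64, 128, 256)
    patch_size: int = 2
    embed_dim: int = 384
    n_layers: int = 6
    n_heads: int = 6
    mlp_dim: int = 1536
    decoder_channels: Tuple[int, ...] = (256, 128, 64, 32)
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        self.decoder_channels = tuple(int(c) for c in self.decoder_channels)
        down = 2 ** len(self.conv_channels) * self.patch_size
        if self.input_size <= 0:
            raise ConfigError("input_size must be positive")
        if self.patch_size < 1 or (self.patch_size & (self.patch_size - 1)):
            raise ConfigError("patch_size must be a power of two")
        if self.input_size % down != 0:
            raise ConfigError(
                f"input_size={self.input_size} not divisible by "
                f"2**len(conv_channels) * patch_size = {down}")
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError(
                f"embed_dim={self.embed_dim} not divisible by n_heads={self.n_heads}")
        if self.n_classes < 1:
            raise ConfigError("n_classes must be >= 1")
        n_up = len(self.conv_channels) + int(np.log2(self.patch_size))
        if len(self.decoder_channels) != n_up:
            raise ConfigError(
                f"decoder_channels must have {n_up} entries "
                f"(len(conv_channels) + log2(patch_size)), got "
                f"{len(self.decoder_channels)}")

    @property
    def grid_size(self) -> int:
        """Token grid side length."""
        return self.input_size // (2 ** len(self.conv_channels) * self.patch_size)

    @property
    def n_tokens(self) -> int:
        return self.grid_size ** 2

    @property
    def n_up_stages(self) -> int:
        return len(self.conv_channels) + int(np.log2(self.patch_size))

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "conv_channels": list(self.conv_channels),
            "patch_size": self.patch_size,
            "embed_dim": self.embed_dim,
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "mlp_dim": self.mlp_dim,
            "decoder_channels": list(self.decoder_channels),
            "n_classes": self.n_classes,
            "seed": self.seed,
        }

    @classmethod
    def tiny(cls, n_classes: int = 2, seed: int = 0) -> "ModelConfig":
        """A 64-pixel configuration that trains in seconds on one CPU core."""
        return cls(input_size=64, conv_channels=(16, 32), patch_size=2,
                   embed_dim=32, n_layers=2, n_heads=2, mlp_dim=64,
                   decoder_channels=(32, 16, 16), n_classes=n_classes,
                   seed=seed)


class SegModel:
    """The built network: parameter store plus forward functions."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: Dict[str, Parameter] = {}
        rng = np.random.default_rng(config.seed)
        self._build(rng)

    # -- construction --------------------------------------------------------
    def _add(self, name: str, p: Parameter) -> Parameter:
        self.params[name] = p
        return p

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        c_in = 1
        for i, c_out in enumerate(cfg.conv_channels):
            pre = f"conv_encoder.stage{i}"
            self._add(f"{pre}.conv.w", nn.kaiming_conv(rng, c_out, c_in, 3))
            self._add(f"{pre}.conv.b", nn.zeros(c_out))
            self._add(f"{pre}.norm.w", nn.ones(c_out))
            self._add(f"{pre}.norm.b", nn.zeros(c_out))
            c_in = c_out

        d = cfg.embed_dim
        self._add("transformer.patch_embed.w",
                  nn.kaiming_conv(rng, d, c_in, cfg.patch_size))
        self._add("transformer.patch_embed.b", nn.zeros(d))
        self._add("transformer.pos_embed",
                  Parameter(rng.normal(0.0, 0.02, size=(1, cfg.n_tokens, d))))
        for i in range(cfg.n_layers):
            pre = f"transformer.block{i}"
            self._add(f"{pre}.ln1.w", nn.ones(d))
            self._add(f"{pre}.ln1.b", nn.zeros(d))
            for proj in ("q", "k", "v"):
                self._add(f"{pre}.attn.{proj}.w", nn.xavier_linear(rng, d, d))
                self._add(f"{pre}.attn.{proj}.b", nn.zeros(d))
            self._add(f"{pre}.attn.proj.w", nn.xavier_linear(rng, d, d))
            self._add(f"{pre}.attn.proj.b", nn.zeros(d))
            self._add(f"{pre}.ln2.w", nn.ones(d))
            self._add(f"{pre}.ln2.b", nn.zeros(d))
            self._add(f"{pre}.mlp.fc1.w", nn.xavier_linear(rng, d, cfg.mlp_dim))
            self._add(f"{pre}.mlp.fc1.b", nn.zeros(cfg.mlp_dim))
            self._add(f"{pre}.mlp.fc2.w", nn.xavier_linear(rng, cfg.mlp_dim, d))
            self._add(f"{pre}.mlp.fc2.b", nn.zeros(d))
        self._add("transformer.final_norm.w", nn.ones(d))
        self._add("transformer.final_norm.b", nn.zeros(d))

        dec = cfg.decoder_channels
        self._add("decoder.proj.conv.w", nn.kaiming_conv(rng, dec[0], d, 3))
        self._add("decoder.proj.conv.b", nn.zeros(dec[0]))
        skip_at = self._skip_resolutions()
        c_cur = dec[0]
        res = cfg.grid_size
        for j, c_out in enumerate(dec):
            res *= 2
            c_skip = skip_at.get(res, (None, 0))[1]
            pre = f"decoder.stage{j}"
            self._add(f"{pre}.conv.w", nn.kaiming_conv(rng, c_out, c_cur + c_skip, 3))
            self._add(f"{pre}.conv.b", nn.zeros(c_out))
            self._add(f"{pre}.norm.w", nn.ones(c_out))
            self._add(f"{pre}.norm.b", nn.zeros(c_out))
            c_cur = c_out

        self._add("head.recon.w", nn.kaiming_conv(rng, 1, c_cur, 3))
        self._add("head.recon.b", nn.zeros(1))
        self._add("head.seg.w", nn.kaiming_conv(rng, cfg.n_classes, c_cur, 1))
        self._add("head.seg.b", nn.zeros(cfg.n_classes))

    def _skip_resolutions(self) -> Dict[int, Tuple[int, int]]:
        """Map spatial resolution -> (conv stage index, channel count)."""
        cfg = self.config
        out = {}
        for i, c in enumerate(cfg.conv_channels):
            out[cfg.input_size // 2 ** (i + 1)] = (i, c)
        return out

    # -- families ------------------------------------------------------------
    def parameter_families(self) -> Dict[str, Set[str]]:
        """Partition of all parameter names into the four named families."""
        fams: Dict[str, Set[str]] = {f: set() for f in FAMILY_NAMES}
        for name in self.params:
            fams[name.split(".", 1)[0]].add(name)
        return fams

    def family_of(self, name: str) -> str:
        return name.split(".", 1)[0]

    # -- forward helpers -----------------------------------------------------
    def _check_input(self, x: Tensor) -> None:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (batch, 1, H, W) input, got {x.shape}")
        s = self.config.input_size
        if x.shape[2] != s or x.shape[3] != s:
            raise ValueError(
                f"input spatial size {x.shape[2]}x{x.shape[3]} != "
                f"configured input_size {s}")

    def _conv_block(self, x: Tensor, prefix: str, stride: int) -> Tensor:
        p = self.params
        x = nn.conv2d(x, p[f"{prefix}.conv.w"], p[f"{prefix}.conv.b"],
                      stride=stride, padding=1)
        x = nn.instance_norm(x, p[f"{prefix}.norm.w"], p[f"{prefix}.norm.b"])
        return nn.relu(x)

    def _linear(self, x: Tensor, prefix: str) -> Tensor:
        return nn.add(nn.matmul(x, self.params[f"{prefix}.w"]),
                      self.params[f"{prefix}.b"])

    def _attention(self, x: Tensor, prefix: str) -> Tensor:
        cfg = self.config
        B, N, D = x.shape
        h, dh = cfg.n_heads, D // cfg.n_heads
        q = self._linear(x, f"{prefix}.q")
        k = self._linear(x, f"{prefix}.k")
        v = self._linear(x, f"{prefix}.v")

        def heads(t: Tensor) -> Tensor:
            return nn.transpose(nn.reshape(t, (B, N, h, dh)), (0, 2, 1, 3))

        q, k, v = heads(q), heads(k), heads(v)
        scores = nn.mul(nn.matmul(q, nn.transpose(k, (0, 1, 3, 2))),
                        1.0 / np.sqrt(dh))
        attn = nn.softmax(scores)
        out = nn.matmul(attn, v)
        out = nn.reshape(nn.transpose(out, (0, 2, 1, 3)), (B, N, D))
        return self._linear(out, f"{prefix}.proj")

    def _mlp(self, x: Tensor, prefix: str) -> Tensor:
        x = nn.gelu(self._linear(x, f"{prefix}.fc1"))
        return self._linear(x, f"{prefix}.fc2")

    # -- public forward API --------------------------------------------------
    def encode(self, x: Tensor) -> Tuple[Tensor, List[Tensor]]:
        """Run the hybrid encoder.

        Returns the refined token sequence, shaped
        ``(batch, n_tokens, embed_dim)``, and one skip feature per
        convolutional stage at its native resolution.
        """
        self._check_input(x)
        cfg = self.config
        p = self.params
        skips: List[Tensor] = []
        for i in range(len(cfg.conv_channels)):
            x = self._conv_block(x, f"conv_encoder.stage{i}", stride=2)
            skips.append(x)
        x = nn.conv2d(x, p["transformer.patch_embed.w"],
                      p["transformer.patch_embed.b"],
                      stride=cfg.patch_size, padding=0)
        B = x.shape[0]
        g = cfg.grid_size
        tokens = nn.reshape(nn.transpose(x, (0, 2, 3, 1)),
                            (B, cfg.n_tokens, cfg.embed_dim))
        tokens = nn.add(tokens, p["transformer.pos_embed"])
        for i in range(cfg.n_layers):
            pre = f"transformer.block{i}"
            h = nn.layer_norm(tokens, p[f"{pre}.ln1.w"], p[f"{pre}.ln1.b"])
            tokens = nn.add(tokens, self._attention(h, f"{pre}.attn"))
            h = nn.layer_norm(tokens, p[f"{pre}.ln2.w"], p[f"{pre}.ln2.b"])
            tokens = nn.add(tokens, self._mlp(h, f"{pre}.mlp"))
        tokens = nn.layer_norm(tokens, p["transformer.final_norm.w"],
                               p["transformer.final_norm.b"])
        return tokens, skips

    def decode(self, tokens: Tensor, skips: List[Tensor]) -> Tensor:
        """Reshape tokens to a grid and upsample back to input resolution."""
        cfg = self.config
        p = self.params
        B, N, D = tokens.shape
        if N != cfg.n_tokens:
            raise ValueError(f"token count {N} != expected {cfg.n_tokens}")
        g = cfg.grid_size
        x = nn.transpose(nn.reshape(tokens, (B, g, g, D)), (0, 3, 1, 2))
        x = nn.relu(nn.conv2d(x, p["decoder.proj.conv.w"],
                              p["decoder.proj.conv.b"], stride=1, padding=1))
        skip_at = self._skip_resolutions()
        res = g
        for j in range(cfg.n_up_stages):
            x = nn.upsample2(x)
            res *= 2
            if res in skip_at:
                x = nn.concat([x, skips[skip_at[res][0]]], axis=1)
            x = self._conv_block(x, f"decoder.stage{j}", stride=1)
        return x

    def reconstruct(self, x: Tensor) -> Tensor:
        """Reconstruction head: single-channel image, same size as input."""
        feat = self.decode(*self.encode(x))
        return nn.conv2d(feat, self.params["head.recon.w"],
                         self.params["head.recon.b"], stride=1, padding=1)

    def segment_logits(self, x: Tensor) -> Tensor:
        """Per-pixel class logits, shaped (batch, n_classes, H, W)."""
        feat = self.decode(*self.encode(x))
        return nn.conv2d(feat, self.params["head.seg.w"],
                         self.params["head.seg.b"], stride=1, padding=0)

    def segment(self, x: Tensor) -> Tensor:
        """Per-pixel class probabilities (softmax over the class axis)."""
        logits = self.segment_logits(x)
        B, C, H, W = logits.shape
        probs = nn.softmax(nn.transpose(logits, (0, 2, 3, 1)))
        return nn.transpose(probs, (0, 3, 1, 2))

    # -- parameter access ----------------------------------------------------
    def state_arrays(self) -> Dict[str, np.ndarray]:
        """Copies of every parameter array, keyed by name."""
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_arrays(self, arrays: Dict[str, np.ndarray],
                    families: Set[str] | None = None) -> None:
        """Load parameter arrays (optionally restricted to named families)."""
        for name, arr in arrays.items():
            if families is not None and self.family_of(name) not in families:
                continue
            if name not in self.params:
                raise KeyError(f"unknown parameter {name!r}")
            if self.params[name].data.shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: model "
                    f"{self.params[name].data.shape}, source {arr.shape}")
            self.params[name].data = arr.astype(np.float32).copy()


def build_model(config: ModelConfig) -> SegModel:
    """Construct a seeded, deterministically initialised network."""
    return SegModel(config)
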