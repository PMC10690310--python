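"""The slice-tiled volumetric network.

A volume's N standardized slices are tiled vertically into one elongated
image of size (N*side) x side x 3. A ConvNeXt backbone with total spatial
downsampling ``side/8`` maps it to an (N*8) x 8 grid of F-channel features,
which is split into N per-slice 8x8xF maps. Each map is flattened and sent
through one shared affine tokenizer to a 768-wide (or reduced-width) token;
a trainable positional vector initialized to the constant slice index is
added, a class token is prepended, and a 5-layer pre-norm transformer
encoder integrates the sequence. The encoded class token feeds a task head:
one logit (binary), one real (regression), or k logits (multiclass).

Two presets are provided: ``convnext_tiny_config`` (the full 256-px,
(3,3,9,3)/(96,192,384,768) tiny variant) and ``compact_config`` (a 64-px,
reduced-width variant with the same 8x8 feature geometry, sized for CPU
training).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .preprocess import ElongatedImage, standardize_volume, tile_volume
from .volume_data import Volume


# ---------------------------------------------------------------------------
# Configs

@dataclass
class BackboneConfig:
    input_side: int = 256
    stem_kernel: int = 4
    stage_depths: tuple = (3, 3, 9, 3)
    stage_widths: tuple = (96, 192, 384, 768)
    layer_scale_init: float = 1e-6

    def __post_init__(self):
        self.stage_depths = tuple(self.stage_depths)
        self.stage_widths = tuple(self.stage_widths)
        if len(self.stage_depths) != len(self.stage_widths):
            raise ValueError("stage_depths and stage_widths must align")
        if self.feature_side != 8:
            raise ValueError(
                f"input_side {self.input_side} / downsample {self.downsample_factor} "
                f"must give an 8x8 per-slice grid")

    @property
    def downsample_factor(self) -> int:
        return self.stem_kernel * 2 ** (len(self.stage_depths) - 1)

    @property
    def feature_side(self) -> int:
        return self.input_side // self.downsample_factor

    @property
    def feature_dim(self) -> int:
        return self.stage_widths[-1]


@dataclass
class IntegratorConfig:
    token_dim: int = 768
    depth: int = 5
    heads: int = 12
    mlp_ratio: int = 4
    max_n: int = 64

    def __post_init__(self):
        if self.token_dim % self.heads != 0:
            raise ValueError("token_dim must be divisible by heads")


@dataclass
class SlivitConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    head: str = "binary"  # binary | regression | multiclass_k

    @property
    def out_dim(self) -> int:
        if self.head in ("binary", "regression"):
            return 1
        if self.head.startswith("multiclass_"):
            return int(self.head.split("_")[1])
        raise ValueError(f"unknown head kind {self.head!r}")

    def to_dict(self):
        return {"backbone": asdict(self.backbone),
                "integrator": asdict(self.integrator),
                "head": self.head}

    @classmethod
    def from_dict(cls, d):
        return cls(backbone=BackboneConfig(**d["backbone"]),
                   integrator=IntegratorConfig(**d["integrator"]),
                   head=d["head"])


def convnext_tiny_config() -> BackboneConfig:
    """The full tiny-variant backbone at 256-px input (F = 768)."""
    return BackboneConfig()


def compact_config() -> BackboneConfig:
    """Reduced-width backbone: 64-px slices, two stages, downsample 8.

    Blocks sit in the low-resolution stage only; at a few hundred training
    volumes, narrower widths regularize markedly better than wider ones.
    """
    return BackboneConfig(input_side=64, stage_depths=(0, 2), stage_widths=(12, 24))


def stem_only_config(base: BackboneConfig | None = None) -> BackboneConfig:
    """Backbone with zero blocks: every spatial kernel equals its stride.

    With no 7x7 depthwise kernels, per-slice receptive fields never cross
    tile boundaries, so tiled processing must agree block-for-block with
    per-slice processing; used as an exactness oracle.
    """
    base = base or BackboneConfig()
    return BackboneConfig(input_side=base.input_side,
                          stage_depths=tuple(0 for _ in base.stage_depths),
                          stage_widths=base.stage_widths)


def compact_integrator_config(max_n: int = 64) -> IntegratorConfig:
    return IntegratorConfig(token_dim=32, depth=5, heads=4, mlp_ratio=4, max_n=max_n)


# ---------------------------------------------------------------------------
# Layers

class PatchConv(nn.Module):
    """k x k convolution with stride k, as patch-reshape + matmul."""

    def __init__(self, k, in_ch, out_ch, rng):
        self.k = k
        self.in_ch = in_ch
        self.proj = nn.Linear(k * k * in_ch, out_ch, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        k = self.k
        if H % k or W % k:
            raise ValueError(f"spatial dims {H}x{W} not divisible by stride {k}")
        x = x.reshape(B, H // k, k, W // k, k, C)
        x = x.transpose((0, 1, 3, 2, 4, 5))
        x = x.reshape(B, H // k, W // k, k * k * C)
        return self.proj(x)


class ConvNeXtBlock(nn.Module):
    """7x7 depthwise -> LN -> 1x1 expand x4 -> GELU -> 1x1 project, residual.

    A learnable per-channel layer scale (init 1e-6) multiplies the branch.
    """

    def __init__(self, dim, rng, layer_scale_init=1e-6):
        self.dw_weight = Tensor(nn.trunc_normal(rng, (7, 7, dim)), requires_grad=True)
        self.dw_bias = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.norm = nn.LayerNorm(dim)
        self.pw1 = nn.Linear(dim, 4 * dim, rng)
        self.pw2 = nn.Linear(4 * dim, dim, rng)
        self.gamma = Tensor(np.full(dim, layer_scale_init, dtype=np.float32),
                            requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        y = nn.depthwise_conv2d(x, self.dw_weight, self.dw_bias)
        y = self.norm(y)
        y = nn.gelu(self.pw1(y))
        y = self.pw2(y)
        return x + y * self.gamma


class ConvNeXtBackbone(nn.Module):
    """Stem (4x4 stride 4 + LN), stages of blocks, LN + 2x2 stride-2
    transitions between stages. Maps (B, h, w, 3) -> (B, h/f, w/f, F)."""

    def __init__(self, config: BackboneConfig, rng):
        self.config = config
        widths = config.stage_widths
        self.stem = PatchConv(config.stem_kernel, 3, widths[0], rng)
        self.stem_norm = nn.LayerNorm(widths[0])
        self.stages = []
        self.transitions = []
        for i, depth in enumerate(config.stage_depths):
            if i > 0:
                self.transitions.append(
                    (nn.LayerNorm(widths[i - 1]), PatchConv(2, widths[i - 1], widths[i], rng)))
            self.stages.append([ConvNeXtBlock(widths[i], rng, config.layer_scale_init)
                                for _ in range(depth)])

    def named_parameters(self, prefix=""):
        yield from self.stem.named_parameters(prefix + "stem.")
        yield from self.stem_norm.named_parameters(prefix + "stem_norm.")
        for i, (norm, conv) in enumerate(self.transitions):
            yield from norm.named_parameters(f"{prefix}transitions.{i}.norm.")
            yield from conv.named_parameters(f"{prefix}transitions.{i}.conv.")
        for i, stage in enumerate(self.stages):
            for j, block in enumerate(stage):
                yield from block.named_parameters(f"{prefix}stages.{i}.{j}.")

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem_norm(self.stem(x))
        for i, stage in enumerate(self.stages):
            if i > 0:
                norm, conv = self.transitions[i - 1]
                x = conv(norm(x))
            for block in stage:
                x = block(x)
        return x


class MultiHeadAttention(nn.Module):
    def __init__(self, dim, heads, rng):
        self.heads = heads
        self.dim = dim
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.scale = 1.0 / np.sqrt(dim // heads)

    def forward(self, x: Tensor) -> Tensor:
        B, S, D = x.shape
        h = self.heads
        dh = D // h
        qkv = self.qkv(x).reshape(B, S, 3, h, dh).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, h, S, dh)
        attn = nn.softmax(q.matmul(k.transpose((0, 1, 3, 2))) * self.scale)
        out = attn.matmul(v)  # (B, h, S, dh)
        out = out.transpose((0, 2, 1, 3)).reshape(B, S, D)
        return self.proj(out)


class TransformerBlock(nn.Module):
    """Pre-norm encoder block with GELU MLP."""

    def __init__(self, dim, heads, mlp_ratio, rng):
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = nn.Linear(mlp_ratio * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.fc2(nn.gelu(self.fc1(self.norm2(x))))
        return x


# ---------------------------------------------------------------------------
# The full model

class SlivitModel(nn.Module):
    """Backbone + shared tokenizer + positional embeddings + transformer + head."""

    def __init__(self, config: SlivitConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        bb, integ = config.backbone, config.integrator
        self.backbone = ConvNeXtBackbone(bb, rng)
        flat_dim = bb.feature_side * bb.feature_side * bb.feature_dim
        self.tokenizer = nn.Linear(flat_dim, integ.token_dim, rng)
        # one trainable vector per slice position, initialized to the
        # (0-based) slice index so each token starts out carrying its depth
        pos = np.repeat(np.arange(integ.max_n, dtype=np.float32)[:, None],
                        integ.token_dim, axis=1)
        self.pos_embed = Tensor(pos, requires_grad=True)
        self.cls_token = Tensor(nn.trunc_normal(rng, (integ.token_dim,)), requires_grad=True)
        self.blocks = [TransformerBlock(integ.token_dim, integ.heads, integ.mlp_ratio, rng)
                       for _ in range(integ.depth)]
        self.final_norm = nn.LayerNorm(integ.token_dim)
        self.head = nn.Linear(integ.token_dim, config.out_dim, rng)

    # -- pieces ------------------------------------------------------------

    def feature_maps(self, x: Tensor) -> Tensor:
        """(B, N*side, side, 3) -> (B, N*8, 8, F)."""
        return self.backbone(x)

    def tokens_from_features(self, feats: Tensor) -> Tensor:
        """Split, flatten, tokenize, add positions, prepend class token."""
        B, rows, cols, F = feats.shape
        s = self.config.backbone.feature_side
        n = rows // s
        if n > self.config.integrator.max_n:
            raise ValueError(f"volume has {n} slices; integrator allows up to "
                             f"{self.config.integrator.max_n}")
        flat = feats.reshape(B, n, s * s * F)
        tok = self.tokenizer(flat) + self.pos_embed[:n]
        cls = self.cls_token.reshape(1, 1, -1) + Tensor(
            np.zeros((B, 1, self.config.integrator.token_dim), dtype=np.float32))
        return nn.concat([cls, tok], axis=1)

    def integrate(self, tokens: Tensor) -> Tensor:
        for block in self.blocks:
            tokens = block(tokens)
        return self.final_norm(tokens)

    def forward(self, x) -> Tensor:
        """x: (B, N*side, side, 3) array or Tensor -> (B, out_dim) head output."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        feats = self.feature_maps(x)
        tokens = self.tokens_from_features(feats)
        encoded = self.integrate(tokens)
        return self.head(encoded[:, 0, :])


class PretrainClassifier(nn.Module):
    """Backbone + global average pool + affine map to k class logits."""

    def __init__(self, backbone: ConvNeXtBackbone, n_classes: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.backbone = backbone
        dim = backbone.config.feature_dim
        self.norm = nn.LayerNorm(dim)
        self.head = nn.Linear(dim, n_classes, rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        feats = self.backbone(x)  # (B, 8, 8, F)
        pooled = feats.mean(axis=1).mean(axis=1)
        return self.head(self.norm(pooled))


# ---------------------------------------------------------------------------
# Spec-level operations

def build_backbone(config: BackboneConfig, init: str = "random",
                   weights: dict | None = None, seed: int = 0) -> ConvNeXtBackbone:
    """Construct a backbone; ``init='transferred'`` loads supplied weights."""
    backbone = ConvNeXtBackbone(config, np.random.default_rng(seed))
    if init == "transferred":
        if weights is None:
            raise ValueError("init='transferred' requires weights")
        backbone.load_state_dict(weights, strict=True)
    elif init != "random":
        raise ValueError(f"unknown init {init!r}")
    return backbone


def extract_feature_maps(backbone: ConvNeXtBackbone, elongated: ElongatedImage) -> np.ndarray:
    """Run the backbone on a tiled image and split into N 8x8xF maps."""
    side = backbone.config.input_side
    h = elongated.pixels.shape[0]
    if h % side:
        raise ValueError(f"elongated height {h} is not a multiple of {side}")
    with nn.no_grad():
        feats = backbone(Tensor(elongated.pixels[None])).data[0]
    s = backbone.config.feature_side
    n = feats.shape[0] // s
    return feats.reshape(n, s, s, feats.shape[-1])


def tokenize_and_embed(model: SlivitModel, stack: np.ndarray) -> np.ndarray:
    """(N, 8, 8, F) feature maps -> (N+1, token_dim) sequence (class token first)."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 4:
        raise ValueError("expected an (N, s, s, F) stack")
    n, s, _, F = stack.shape
    with nn.no_grad():
        feats = Tensor(stack.reshape(1, n * s, s, F))
        tokens = model.tokens_from_features(feats)
    return tokens.data[0]


def integrate_and_predict(model: SlivitModel, tokens: np.ndarray) -> np.ndarray:
    """(N+1, token_dim) sequence -> head output for the class token."""
    tokens = np.asarray(tokens, dtype=np.float32)
    if tokens.ndim != 2 or tokens.shape[0] < 2:
        raise ValueError("expected an (N+1, token_dim) sequence with N >= 1")
    if tokens.shape[1] != model.config.integrator.token_dim:
        raise ValueError("token dimension mismatch")
    with nn.no_grad():
        encoded = model.integrate(Tensor(tokens[None]))
        out = model.head(encoded[:, 0, :])
    return out.data[0]


def forward_volume(model: SlivitModel, volume: Volume, stretch: bool = True) -> np.ndarray:
    """Standardize -> tile -> extract -> tokenize -> integrate -> head."""
    side = model.config.backbone.input_side
    slices = standardize_volume(volume, side=side, stretch=stretch)
    elongated = tile_volume(slices)
    with nn.no_grad():
        out = model(elongated.pixels[None])
    return out.data[0]


def build_pretrain_model(backbone: ConvNeXtBackbone, n_classes: int = 4,
                         seed: int = 0) -> PretrainClassifier:
    return PretrainClassifier(backbone, n_classes=n_classes, seed=seed)


# ---------------------------------------------------------------------------
# Checkpoints

def save_checkpoint(model: nn.Module, path, config: SlivitConfig | None = None,
                    extra: dict | None = None) -> None:
    """Single-file npz archive: weight groups + a JSON manifest."""
    state = model.state_dict()
    manifest = {
        "format": "slivit-checkpoint-v1",
        "config": config.to_dict() if config is not None else None,
        "shapes": {k: list(v.shape) for k, v in state.items()},
        "extra": extra or {},
    }
    np.savez(path, __manifest__=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    """Return (state_dict, manifest)."""
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        state = {k: data[k] for k in data.files if k != "__manifest__"}
    return state, manifest


def backbone_state(state: dict, prefix: str = "backbone.") -> dict:
    """Extract the standalone backbone weight group from a model state dict."""
    return {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)}
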