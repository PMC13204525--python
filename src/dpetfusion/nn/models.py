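"""Compact 3D classifiers: a small residual CNN and a small vision transformer.

Both consume standardized 64^3 tumor crops and emit a single logit. The
ResNet keeps the reference topology — stem convolution, eight residual
blocks (4 stages x 2), global average pooling, two fully connected layers —
but is width-reduced for CPU training, and its stem begins with an average
pooling so the residual stages run at a coarse spatial scale. The ViT
splits the crop into non-overlapping patches, embeds them in a
64-dimensional latent space and applies 3 transformer layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dpetfusion.nn import autograd as ag
from dpetfusion.nn.autograd import Tensor
from dpetfusion.nn.layers import BatchNorm3d, Conv3d, LayerNorm, Linear, Module

INPUT_SHAPE = (64, 64, 64)


@dataclass
class ModelConfig:
    """Architecture + training settings for one deep-branch candidate."""

    arch: str = "resnet3d_small"  # or "vit3d"
    width: int = 8  # CNN base width
    input_pool: int = 4  # stem average-pool factor (CNN)
    patch_size: int = 16  # ViT
    embed_dim: int = 64
    depth: int = 3
    heads: int = 4
    mlp_ratio: float = 2.0
    lr: float = 1e-3
    weight_decay: float = 1e-3
    proj_lr_mult: float = 10.0  # faster learning for the zero-init fusion projection
    epochs: int = 12
    batch_size: int = 16
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.arch == "vit3d" and INPUT_SHAPE[0] % self.patch_size != 0:
            raise ValueError(f"patch size {self.patch_size} must divide {INPUT_SHAPE[0]}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not self.name:
            self.name = self.arch


class ResidualBlock(Module):
    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv3d(c_in, c_out, rng, stride=stride)
        self.bn1 = BatchNorm3d(c_out)
        self.conv2 = Conv3d(c_out, c_out, rng)
        self.bn2 = BatchNorm3d(c_out)
        if stride != 1 or c_in != c_out:
            self.shortcut = Conv3d(c_in, c_out, rng, kernel=1, stride=stride, padding=0)
        else:
            self.shortcut = None

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        skip = x if self.shortcut is None else self.shortcut(x)
        return ag.relu(out + skip)


class ResNet3DSmall(Module):
    """Stem conv + 8 residual blocks + GAP + two fully connected layers."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        w = config.width
        self.config = config
        self.input_pool = config.input_pool
        self.stem = Conv3d(1, w, rng, stride=2)
        self.stem_bn = BatchNorm3d(w)
        widths = [w, 2 * w, 4 * w, 4 * w]
        strides = [1, 2, 2, 2]
        blocks = []
        c_prev = w
        for c, s in zip(widths, strides):
            blocks.append(ResidualBlock(c_prev, c, s, rng))
            blocks.append(ResidualBlock(c, c, 1, rng))
            c_prev = c
        self.blocks = blocks
        self.feature_dim = widths[-1]
        self.fc1 = Linear(self.feature_dim, 2 * w, rng)
        self.fc2 = Linear(2 * w, 1, rng)
        self._stage_activations: list[Tensor] = []

    def features(self, x: Tensor, keep_cam: bool = False) -> Tensor:
        """Pooled representation (N, feature_dim) of 64^3 (or pre-pooled) input."""
        if x.shape[-1] == INPUT_SHAPE[0] and self.input_pool > 1:
            x = ag.avgpool3d(x, self.input_pool)
        out = ag.relu(self.stem_bn(self.stem(x)))
        if keep_cam:
            self._stage_activations = []
        for i, block in enumerate(self.blocks):
            out = block(out)
            if keep_cam and i % 2 == 1:  # end of each stage
                self._stage_activations.append(out)
        return out.mean(axis=(2, 3, 4))

    def head(self, pooled: Tensor) -> Tensor:
        return self.fc2(ag.relu(self.fc1(pooled)))

    def __call__(self, x: Tensor, keep_cam: bool = False) -> Tensor:
        return self.head(self.features(x, keep_cam=keep_cam))


class TransformerBlock(Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.mlp1 = Linear(dim, hidden, rng)
        self.mlp2 = Linear(hidden, dim, rng)
        self.heads = heads
        self.dim = dim

    def _attend(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h = self.heads
        dh = d // h
        q = self.wq(x).reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        k = self.wk(x).reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        v = self.wv(x).reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        att = ag.softmax(ag.mul_const(q @ k.transpose(0, 1, 3, 2), 1.0 / np.sqrt(dh)), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.wo(out)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self._attend(self.norm1(x))
        return x + self.mlp2(ag.gelu(self.mlp1(self.norm2(x))))


class ViT3D(Module):
    """Non-overlapping 3D patches -> 64-dim embedding -> 3 transformer layers."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        p = config.patch_size
        self.patch = p
        self.n_tokens = (INPUT_SHAPE[0] // p) ** 3
        dim = config.embed_dim
        self.embed = Linear(p**3, dim, rng)
        self.pos = Tensor(rng.normal(0, 0.02, size=(1, self.n_tokens, dim)), requires_grad=True)
        self.layers = [
            TransformerBlock(dim, config.heads, config.mlp_ratio, rng)
            for _ in range(config.depth)
        ]
        self.norm = LayerNorm(dim)
        self.head_fc = Linear(dim, 1, rng)
        self.feature_dim = dim

    def _patchify(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        g = INPUT_SHAPE[0] // self.patch
        p = self.patch
        x = x.reshape(n, g, p, g, p, g, p)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6)
        return x.reshape(n, g**3, p**3)

    def features(self, x: Tensor) -> Tensor:
        tokens = self.embed(self._patchify(x)) + self.pos
        for layer in self.layers:
            tokens = layer(tokens)
        return self.norm(tokens).mean(axis=1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head_fc(self.features(x))


class FeatureFusionNet(Module):
    """Feature-level fusion: radiomics vector injected at the pooling layer.

    The selected radiomics features (z-scored with training statistics) pass
    through a learnable linear projection to the CNN's pooled-representation
    width and are added element-wise (residual) before the classification
    head. The projection is zero-initialized, so at initialization the
    network is exactly the image-only pathway.
    """

    def __init__(self, config: ModelConfig, n_radiomics: int):
        rng = np.random.default_rng(config.seed)
        self.backbone = ResNet3DSmall(config)
        self.n_radiomics = n_radiomics
        # bias-free so zeroed radiomics input reduces exactly to the image path
        self.projection = Linear(n_radiomics, self.backbone.feature_dim, rng,
                                 zero_init=True, bias=False)
        self.config = config

    def __call__(self, x: Tensor, r: Tensor) -> Tensor:
        if r.shape[-1] != self.n_radiomics:
            raise ValueError(
                f"expected {self.n_radiomics} radiomics features, got {r.shape[-1]}"
            )
        pooled = self.backbone.features(x)
        fused = pooled + self.projection(r)
        return self.backbone.head(fused)


def build_model(config: ModelConfig) -> Module:
    if config.arch == "resnet3d_small":
        return ResNet3DSmall(config)
    if config.arch == "vit3d":
        return ViT3D(config)
    raise ValueError(f"unknown architecture {config.arch!r}")
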