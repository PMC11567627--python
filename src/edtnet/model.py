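"""EDTNet assembly: U-shaped transformer encoder-decoder for binary masks.

Layout (grid sizes for a 256-px image, embed stride 4):

    embed (+PE)        64x64 x C
    encoder stage 1    esla_depth x ESLA          -> skip 1
    downsample         32x32 x 2C
    encoder stage 2    esla_depth x ESLA          -> skip 2
    bottleneck down    16x16 x 4C
    esga_depth x ESGA (global attention)
    bottleneck up      32x32 x 2C
    (+PE_dec) skip attention 2, esla_depth x ESLA
    upsample           64x64 x C
    (+PE_dec) skip attention 1, esla_depth x ESLA
    patch-expand head  256x256 x 1 logits

Downsampling is either a stride-2 convolution over the token grid or Swin
style patch merging; upsampling is a stride-2 transposed convolution; the
head is a stride-``embed_stride`` transposed convolution to one channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .attention import (AttentionConfig, ESGABlock, ESLABlock, PositionalEncoding,
                        SkipAttentionFuse, TokenGrid, conv_patch_embed)
from .autodiff import Tensor
from . import autodiff as ad

__all__ = ["ModelConfig", "ConfigurationError", "EDTNet", "ConvDownsample",
           "PatchMerge", "DeconvUpsample", "PatchExpandHead", "build_edtnet",
           "count_parameters"]


class ConfigurationError(ValueError):
    """Raised when a ModelConfig violates an architectural constraint."""


@dataclass(frozen=True)
class ModelConfig:
    """Every architecture hyperparameter, pinned in one place.

    Stage dims are ``[C, 2C, 4C]`` with ``C = base_dim``; head counts per
    stage are ``stage_dim // head_dim``.
    """

    image_size: int = 256
    in_channels: int = 3
    embed_stride: int = 4
    base_dim: int = 96
    esla_depth: int = 2
    esga_depth: int = 3
    head_dim: int = 32
    window_size: int = 8
    downsample_kind: str = "conv"        # "conv" | "patch_merge"
    embedding_kind: str = "conv"         # "conv" | "linear_patch"
    skip_attention: bool = True
    alpha: float = 0.5
    seed: int = 0

    @property
    def stage_dims(self) -> tuple[int, int, int]:
        c = self.base_dim
        return (c, 2 * c, 4 * c)

    @property
    def grid_sizes(self) -> tuple[int, int, int]:
        g = self.image_size // self.embed_stride
        return (g, g // 2, g // 4)

    def validate(self) -> None:
        problems = []
        if self.image_size % (self.embed_stride * 4):
            problems.append(
                f"image_size {self.image_size} must be divisible by "
                f"embed_stride*4 = {self.embed_stride * 4} (two downsamples)")
        for dim in self.stage_dims:
            if dim % self.head_dim:
                problems.append(f"head_dim {self.head_dim} must divide stage dim {dim}")
        if self.esga_depth < 0:
            problems.append(f"esga_depth must be >= 0, got {self.esga_depth}")
        if self.esla_depth < 1:
            problems.append(f"esla_depth must be >= 1, got {self.esla_depth}")
        if self.downsample_kind not in ("conv", "patch_merge"):
            problems.append(f"unknown downsample_kind {self.downsample_kind!r}")
        if self.embedding_kind not in ("conv", "linear_patch"):
            problems.append(f"unknown embedding_kind {self.embedding_kind!r}")
        if not 0.0 <= self.alpha <= 1.0:
            problems.append(f"alpha must lie in [0,1], got {self.alpha}")
        for g in self.grid_sizes[:2]:
            m = min(self.window_size, g)
            if g % m:
                problems.append(f"window_size {self.window_size} does not tile grid {g}")
        if problems:
            raise ConfigurationError("; ".join(problems))

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale preset: 64-px images, C=16, ~260k parameters."""
        base = dict(image_size=64, base_dim=16, head_dim=8, window_size=8)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def full_scale(cls, **overrides) -> "ModelConfig":
        """Full-scale profile: 256-px images, C=96, heads (3, 6, 12)."""
        return cls(**overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))


# -- resolution-changing modules ---------------------------------------


def _to_map(grid: TokenGrid) -> Tensor:
    """(B, N, d) tokens -> (B, d, h, w) feature map."""
    return grid.values.transpose(0, 2, 1).reshape(
        grid.batch, grid.d, grid.h, grid.w)


def _to_grid(x: Tensor) -> TokenGrid:
    b, d, h, w = x.shape
    return TokenGrid(x.reshape(b, d, h * w).transpose(0, 2, 1), h, w)


class ConvDownsample(nn.Module):
    """Stride-2 convolution over the grid: h, w halved, dim doubled."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(dim, 2 * dim, kernel=2, stride=2, rng=rng)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        if grid.h % 2 or grid.w % 2:
            raise ValueError(f"cannot downsample odd grid {grid.h}x{grid.w}")
        return _to_grid(self.conv(_to_map(grid)))


class PatchMerge(nn.Module):
    """Concatenate 2x2 token neighbourhoods (4C) and reduce linearly to 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.reduce = nn.Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        if grid.h % 2 or grid.w % 2:
            raise ValueError(f"cannot merge odd grid {grid.h}x{grid.w}")
        b, d = grid.batch, grid.d
        h2, w2 = grid.h // 2, grid.w // 2
        x = grid.values.reshape(b, h2, 2, w2, 2, d)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h2 * w2, 4 * d)
        return TokenGrid(self.reduce(x), h2, w2)


class DeconvUpsample(nn.Module):
    """Stride-2 transposed convolution: h, w doubled, dim halved."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.deconv = nn.ConvTranspose2d(dim, dim // 2, kernel=2, stride=2, rng=rng)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        return _to_grid(self.deconv(_to_map(grid)))


class PatchExpandHead(nn.Module):
    """Patch-expanding output head: tokens -> full-resolution 1-ch logits.

    A stride-``embed_stride`` transposed convolution expands the grid to
    full resolution at a small channel width, and a 5x5 refinement
    convolution (receptive field on the order of a small nodule) produces
    the single-channel logit map with sharper boundaries than the bare
    deconvolution alone.
    """

    REFINE_CHANNELS = 8

    def __init__(self, dim: int, stride: int, rng: np.random.Generator):
        self.stride = stride
        self.deconv = nn.ConvTranspose2d(dim, self.REFINE_CHANNELS,
                                         kernel=stride, stride=stride, rng=rng)
        self.refine = nn.Conv2d(self.REFINE_CHANNELS, 1, kernel=5, stride=1,
                                padding=2, rng=rng)

    def forward(self, grid: TokenGrid, image_size: int) -> Tensor:
        if grid.h * self.stride != image_size:
            raise ValueError(
                f"head expects a 1/{self.stride} resolution grid: "
                f"{grid.h}x{grid.w} tokens cannot expand to {image_size} px")
        return self.refine(nn.gelu(self.deconv(_to_map(grid))))


class LinearPatchEmbed(nn.Module):
    """Non-overlapping patch flattening followed by a linear map."""

    def __init__(self, in_ch: int, dim: int, stride: int, rng: np.random.Generator):
        self.stride = stride
        self.proj = nn.Linear(in_ch * stride * stride, dim, rng)

    def forward(self, image: Tensor) -> TokenGrid:
        b, c, hh, ww = image.shape
        s = self.stride
        if hh % s or ww % s:
            raise ValueError(f"image dims {(hh, ww)} not divisible by patch {s}")
        h, w = hh // s, ww // s
        x = image.reshape(b, c, h, s, w, s)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(b, h * w, c * s * s)
        return TokenGrid(self.proj(x), h, w)


class ConvPatchEmbed(nn.Module):
    """Convolutional patch embedding (kernel = stride by default)."""

    def __init__(self, in_ch: int, dim: int, stride: int, rng: np.random.Generator,
                 kernel: int | None = None):
        k = stride if kernel is None else kernel
        fan_in = in_ch * k * k
        self.stride = stride
        self.weight = nn.Parameter(rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                              (dim, in_ch, k, k)))
        self.bias = nn.Parameter(np.zeros(dim))

    def forward(self, image: Tensor) -> TokenGrid:
        return conv_patch_embed(image, self.weight, self.bias, self.stride)


# -- the network --------------------------------------------------------


class EDTNet(nn.Module):
    """The full segmentation network. Forward: (B, 3, H, W) -> (B, 1, H, W)."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2, c3 = config.stage_dims
        g0, g1, g2 = config.grid_sizes
        cfg1 = AttentionConfig(c1 // config.head_dim, config.head_dim, config.window_size)
        cfg2 = AttentionConfig(c2 // config.head_dim, config.head_dim, config.window_size)
        cfg3 = AttentionConfig(c3 // config.head_dim, config.head_dim, None)

        if config.embedding_kind == "conv":
            self.embed = ConvPatchEmbed(config.in_channels, c1, config.embed_stride, rng)
        else:
            self.embed = LinearPatchEmbed(config.in_channels, c1, config.embed_stride, rng)
        self.pos_enc = PositionalEncoding(g0, g0, c1)

        down = ConvDownsample if config.downsample_kind == "conv" else PatchMerge
        self.enc_stage1 = [ESLABlock(c1, (g0, g0), cfg1, rng)
                           for _ in range(config.esla_depth)]
        self.down1 = down(c1, rng)
        self.enc_stage2 = [ESLABlock(c2, (g1, g1), cfg2, rng)
                           for _ in range(config.esla_depth)]
        self.bottleneck_down = down(c2, rng)
        self.bottleneck = [ESGABlock(c3, (g2, g2), cfg3, rng)
                           for _ in range(config.esga_depth)]
        self.bottleneck_up = DeconvUpsample(c3, rng)

        self.dec_pos2 = PositionalEncoding(g1, g1, c2)
        self.skip2 = (SkipAttentionFuse(c2, c2, cfg2, rng)
                      if config.skip_attention else None)
        self.dec_stage2 = [ESLABlock(c2, (g1, g1), cfg2, rng)
                           for _ in range(config.esla_depth)]
        self.up2 = DeconvUpsample(c2, rng)
        self.dec_pos1 = PositionalEncoding(g0, g0, c1)
        self.skip1 = (SkipAttentionFuse(c1, c1, cfg1, rng)
                      if config.skip_attention else None)
        self.dec_stage1 = [ESLABlock(c1, (g0, g0), cfg1, rng)
                           for _ in range(config.esla_depth)]
        self.head = PatchExpandHead(c1, config.embed_stride, rng)

    # -----------------------------------------------------------------
    def forward(self, images) -> Tensor:
        """``images``: (B, 3, H, W) array or tensor, intensities in [0, 1]."""
        x = ad.as_tensor(images)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (B, {self.config.in_channels}, H, W) "
                             f"input, got {x.shape}")
        if x.shape[2] != self.config.image_size or x.shape[3] != self.config.image_size:
            raise ValueError(f"model built for {self.config.image_size}px images, "
                             f"got {x.shape[2]}x{x.shape[3]}")
        grid = self.pos_enc(self.embed(x))
        for blk in self.enc_stage1:
            grid = blk(grid)
        enc1 = grid
        grid = self.down1(grid)
        for blk in self.enc_stage2:
            grid = blk(grid)
        enc2 = grid
        grid = self.bottleneck_down(grid)
        for blk in self.bottleneck:
            grid = blk(grid)
        grid = self.bottleneck_up(grid)

        grid = self.dec_pos2(grid)
        if self.skip2 is not None:
            grid = self.skip2(grid, enc2)
        for blk in self.dec_stage2:
            grid = blk(grid)
        grid = self.up2(grid)
        grid = self.dec_pos1(grid)
        if self.skip1 is not None:
            grid = self.skip1(grid, enc1)
        for blk in self.dec_stage1:
            grid = blk(grid)
        return self.head(grid, self.config.image_size)

    #: test-time-averaging transforms: the invariances the augmentation set
    #: trains (identity, both flips, 90 and 180 degree rotations), as
    #: (forward on (B,C,H,W), inverse on (B,H,W)) pairs
    _TTA_TRANSFORMS = (
        (lambda a: a, lambda p: p),
        (lambda a: a[:, :, :, ::-1], lambda p: p[:, :, ::-1]),
        (lambda a: a[:, :, ::-1, :], lambda p: p[:, ::-1, :]),
        (lambda a: np.rot90(a, 1, axes=(2, 3)), lambda p: np.rot90(p, -1, axes=(1, 2))),
        (lambda a: np.rot90(a, 2, axes=(2, 3)), lambda p: np.rot90(p, -2, axes=(1, 2))),
    )

    def predict_proba(self, images, tta: bool = False) -> np.ndarray:
        """Sigmoid probabilities, (B, H, W), no gradient tape kept.

        With ``tta`` the prediction is averaged over the flip/rotation
        transforms the training augmentation enforces invariance to.
        """
        images = np.asarray(images, dtype=np.float64)
        transforms = self._TTA_TRANSFORMS if tta else self._TTA_TRANSFORMS[:1]
        acc = None
        for fwd, inv in transforms:
            logits = self.forward(np.ascontiguousarray(fwd(images)))
            p = inv(ad.sigmoid(logits.detach()).data[:, 0])
            acc = p if acc is None else acc + p
        return acc / len(transforms)

    def predict_mask(self, images, threshold: float = 0.5,
                     tta: bool = False) -> np.ndarray:
        """Thresholded binary masks, (B, H, W) uint8."""
        return (self.predict_proba(images, tta=tta) > threshold).astype(np.uint8)


def build_edtnet(config: ModelConfig) -> EDTNet:
    """Build the network; initialization is deterministic under ``config.seed``."""
    return EDTNet(config)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalars."""
    return model.num_parameters()
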