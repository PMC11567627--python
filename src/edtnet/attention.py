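"""Spatially-biased attention: the building blocks of the encoder-decoder.

Tokens live on an ``h x w`` grid (:class:`TokenGrid`, row-major). The
attention score between tokens ``i`` and ``j`` is the usual scaled dot
product plus a learnable *relative spatial bias* ``S_ij`` that depends only
on the offset ``P_i - P_j`` between their grid positions:

    A = softmax(Q K^T / sqrt(d_head) + S) V

The bias is stored as a per-head lookup table over the ``(2m_h-1)(2m_w-1)``
realizable offsets of the attention scope, so it is translation invariant
and its size is independent of the image. Two scopes are used:

* ESLA — spatially aware *local* attention: the grid is tiled into
  non-overlapping square windows and biased attention runs per window.
* ESGA — spatially aware *global* attention: one scope covering the whole
  (bottleneck) grid. ESLA with a full-grid window is exactly ESGA.

Cross attention lets decoder queries attend to encoder keys/values; skip
attention is cross attention between same-resolution encoder and decoder
streams plus a residual, replacing concatenation skips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = ["TokenGrid", "AttentionConfig", "AttentionProjections",
           "PositionalEncoding", "SpatialBiasTable", "relative_position_index",
           "relative_spatial_bias", "conv_patch_embed", "add_positional_encoding",
           "biased_attention", "window_partition", "window_reverse",
           "ESLABlock", "ESGABlock", "CrossAttention", "SkipAttentionFuse"]


@dataclass
class TokenGrid:
    """``h*w`` tokens of dim ``d`` on a spatial grid, row-major."""

    values: Tensor  # (B, h*w, d)
    h: int
    w: int

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[1] != self.h * self.w:
            raise ValueError(f"token tensor {self.values.shape} does not match "
                             f"an {self.h}x{self.w} grid")

    @property
    def d(self) -> int:
        return self.values.shape[2]

    @property
    def batch(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AttentionConfig:
    heads: int
    head_dim: int
    window_size: int | None = None  # side length m for local scope

    @property
    def d_attn(self) -> int:
        return self.heads * self.head_dim

    @property
    def scale(self) -> float:
        return math.sqrt(self.head_dim)


class AttentionProjections(nn.Module):
    """Q/K/V/output projections, optionally with the decoder query map W'.

    ``in_dim`` is the query-side token dim, ``kv_dim`` the key/value-side
    dim (they differ in cross attention). When ``w_prime`` is set the
    query projection is the decoder pre-attention map of the cross
    attention module; it is a distinct matrix, never shared with W_Q.
    """

    def __init__(self, in_dim: int, cfg: AttentionConfig,
                 rng: np.random.Generator, kv_dim: int | None = None,
                 w_prime: bool = False):
        kv_dim = in_dim if kv_dim is None else kv_dim
        d_attn = cfg.d_attn
        if w_prime:
            self.w_prime = nn.Linear(in_dim, d_attn, rng, bias=False)
            self.w_q = None
        else:
            self.w_prime = None
            self.w_q = nn.Linear(in_dim, d_attn, rng, bias=False)
        self.w_k = nn.Linear(kv_dim, d_attn, rng, bias=False)
        self.w_v = nn.Linear(kv_dim, d_attn, rng, bias=False)
        self.w_out = nn.Linear(d_attn, in_dim, rng)

    def query(self, x: Tensor) -> Tensor:
        proj = self.w_q if self.w_prime is None else self.w_prime
        return proj(x)


class PositionalEncoding(nn.Module):
    """One learnable vector per grid cell, zero-initialized."""

    def __init__(self, h: int, w: int, dim: int):
        self.h, self.w = h, w
        self.pe = nn.Parameter(np.zeros((h * w, dim)))

    def forward(self, grid: TokenGrid) -> TokenGrid:
        return add_positional_encoding(grid, self.pe)


def add_positional_encoding(grid: TokenGrid, pe: Tensor) -> TokenGrid:
    """Elementwise sum E' = E + PE with a strict shape check."""
    pe = ad.as_tensor(pe)
    if pe.shape != grid.values.shape[1:]:
        raise ValueError(f"positional encoding shape {pe.shape} does not match "
                         f"tokens {grid.values.shape[1:]}")
    return TokenGrid(grid.values + pe, grid.h, grid.w)


def relative_position_index(h: int, w: int) -> np.ndarray:
    """(N, N) integer map from token pair (i, j) to flattened offset P_i - P_j.

    Offsets range over ``[-(h-1), h-1] x [-(w-1), w-1]``; the flat index is
    ``(dr + h - 1) * (2w - 1) + (dc + w - 1)``.
    """
    rows, cols = np.divmod(np.arange(h * w), w)
    dr = rows[:, None] - rows[None, :]
    dc = cols[:, None] - cols[None, :]
    return (dr + h - 1) * (2 * w - 1) + (dc + w - 1)


class SpatialBiasTable(nn.Module):
    """Learnable per-head bias over relative offsets within a scope.

    Realizes ``S_ij = h(P_i, P_j, W_s)`` as a table lookup keyed by
    ``P_i - P_j``: ``(2*scope_h - 1) * (2*scope_w - 1)`` entries per head.
    """

    def __init__(self, heads: int, scope_h: int, scope_w: int):
        self.scope_h, self.scope_w = scope_h, scope_w
        self.table = nn.Parameter(
            np.zeros((heads, (2 * scope_h - 1) * (2 * scope_w - 1))))
        self._index = relative_position_index(scope_h, scope_w)

    def matrix(self) -> Tensor:
        """The (heads, N, N) bias matrix for the full scope."""
        return ad.bias_lookup(self.table, self._index)


def relative_spatial_bias(scope: tuple[int, int], table: SpatialBiasTable) -> Tensor:
    """Bias matrix S for an ``h x w`` scope served by ``table``.

    Raises if the scope realizes offsets the table does not cover.
    """
    h, w = scope
    if h > table.scope_h or w > table.scope_w:
        raise IndexError(f"scope {scope} exceeds bias table scope "
                         f"({table.scope_h}, {table.scope_w})")
    if (h, w) == (table.scope_h, table.scope_w):
        return table.matrix()
    rows, cols = np.divmod(np.arange(h * w), w)
    dr = rows[:, None] - rows[None, :]
    dc = cols[:, None] - cols[None, :]
    idx = (dr + table.scope_h - 1) * (2 * table.scope_w - 1) + (dc + table.scope_w - 1)
    return ad.bias_lookup(table.table, idx)


def conv_patch_embed(image: Tensor, weights: Tensor, bias: Tensor | None,
                     stride: int) -> TokenGrid:
    """Convolutional patch embedding: (B, C, H, W) image -> token grid.

    ``weights`` is a (d, C, k, k) kernel; overlap (k > stride) is padded
    symmetrically so the grid is exactly ``H/stride x W/stride``.
    """
    image = ad.as_tensor(image)
    k = weights.shape[2]
    if k < stride or (k - stride) % 2:
        raise ValueError(f"kernel {k} incompatible with stride {stride}")
    if image.shape[2] % stride or image.shape[3] % stride:
        raise ValueError(f"image dims {image.shape[2:]} not divisible by stride {stride}")
    pad = (k - stride) // 2
    out = ad.conv2d(image, weights, bias, stride=stride, padding=pad)
    b, d, h, w = out.shape
    tokens = out.reshape(b, d, h * w).transpose(0, 2, 1)
    return TokenGrid(tokens, h, w)


def biased_attention(tokens: Tensor, proj: AttentionProjections,
                     bias: Tensor | None, cfg: AttentionConfig,
                     kv_tokens: Tensor | None = None) -> Tensor:
    """Multi-head scaled dot-product attention with additive spatial bias.

    ``tokens``: (B, N, d) queries; ``kv_tokens`` defaults to ``tokens``
    (self attention). ``bias``: (heads, N, M) added to the scores, or
    ``None``. Returns (B, N, d).
    """
    tokens = ad.as_tensor(tokens)
    if not np.isfinite(tokens.data).all():
        raise ValueError("attention received non-finite tokens")
    kv = tokens if kv_tokens is None else ad.as_tensor(kv_tokens)
    b, n, _ = tokens.shape
    m = kv.shape[1]
    hds, hd = cfg.heads, cfg.head_dim

    def split_heads(x: Tensor, length: int) -> Tensor:
        return x.reshape(x.shape[0], length, hds, hd).transpose(0, 2, 1, 3)

    q = split_heads(proj.query(tokens), n)
    k = split_heads(proj.w_k(kv), m)
    v = split_heads(proj.w_v(kv), m)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / cfg.scale)
    if bias is not None:
        scores = scores + ad.as_tensor(bias)
    attn = ad.softmax(scores, axis=-1)
    out = attn @ v  # (B, heads, N, hd)
    merged = out.transpose(0, 2, 1, 3).reshape(b, n, hds * hd)
    return proj.w_out(merged)


def attention_weights(tokens: Tensor, proj: AttentionProjections,
                      bias: Tensor | None, cfg: AttentionConfig,
                      kv_tokens: Tensor | None = None) -> np.ndarray:
    """The softmax attention matrix (B, heads, N, M) — diagnostics only."""
    tokens = ad.as_tensor(tokens)
    kv = tokens if kv_tokens is None else ad.as_tensor(kv_tokens)
    hds, hd = cfg.heads, cfg.head_dim
    q = proj.query(tokens).data.reshape(tokens.shape[0], -1, hds, hd).transpose(0, 2, 1, 3)
    k = proj.w_k(kv).data.reshape(kv.shape[0], -1, hds, hd).transpose(0, 2, 1, 3)
    scores = q @ k.transpose(0, 1, 3, 2) / cfg.scale
    if bias is not None:
        scores = scores + ad.as_tensor(bias).data
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def window_partition(grid: TokenGrid, m_h: int, m_w: int | None = None) -> Tensor:
    """Tile the grid into non-overlapping ``m_h x m_w`` windows.

    Returns (B * n_windows, m_h*m_w, d); window order is row-major over
    window positions, tokens row-major within each window.
    """
    m_w = m_h if m_w is None else m_w
    if grid.h % m_h or grid.w % m_w:
        raise ValueError(f"window {m_h}x{m_w} does not tile grid {grid.h}x{grid.w}")
    b, d = grid.batch, grid.d
    nh, nw = grid.h // m_h, grid.w // m_w
    x = grid.values.reshape(b, nh, m_h, nw, m_w, d)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * nh * nw, m_h * m_w, d)


def window_reverse(windows: Tensor, batch: int, h: int, w: int,
                   m_h: int, m_w: int | None = None) -> TokenGrid:
    """Inverse of :func:`window_partition`."""
    m_w = m_h if m_w is None else m_w
    nh, nw = h // m_h, w // m_w
    d = windows.shape[2]
    x = windows.reshape(batch, nh, nw, m_h, m_w, d)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return TokenGrid(x.reshape(batch, h * w, d), h, w)


class _BiasedTransformerBlock(nn.Module):
    """Pre-norm transformer block with windowed, spatially biased attention.

    ``scope`` is the attention extent: the window side for local blocks or
    the full grid for global ones. Anatomy: LN -> windowed biased MHA ->
    residual -> LN -> MLP (expansion 4, GELU) -> residual.
    """

    def __init__(self, dim: int, grid_hw: tuple[int, int],
                 scope: tuple[int, int], cfg: AttentionConfig,
                 rng: np.random.Generator):
        if cfg.d_attn != dim:
            raise ValueError(f"heads*head_dim = {cfg.d_attn} must equal token dim {dim}")
        h, w = grid_hw
        if h % scope[0] or w % scope[1]:
            raise ValueError(f"attention scope {scope} does not tile grid {grid_hw}")
        self.grid_hw = grid_hw
        self.scope = scope
        self.cfg = cfg
        self.norm1 = nn.LayerNorm(dim)
        self.proj = AttentionProjections(dim, cfg, rng)
        self.bias = SpatialBiasTable(cfg.heads, scope[0], scope[1])
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.Mlp(dim, rng)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        h, w = grid.h, grid.w
        if (h, w) != tuple(self.grid_hw):
            raise ValueError(f"block built for grid {self.grid_hw}, got {(h, w)}")
        x = grid.values
        normed = TokenGrid(self.norm1(x), h, w)
        wins = window_partition(normed, self.scope[0], self.scope[1])
        s = self.bias.matrix()
        attended = biased_attention(wins, self.proj, s, self.cfg)
        y = window_reverse(attended, grid.batch, h, w,
                           self.scope[0], self.scope[1]).values
        x = x + y
        x = x + self.mlp(self.norm2(x))
        return TokenGrid(x, h, w)


class ESLABlock(_BiasedTransformerBlock):
    """Enhanced spatially aware *local* attention block (windowed)."""

    def __init__(self, dim: int, grid_hw: tuple[int, int], cfg: AttentionConfig,
                 rng: np.random.Generator):
        m = cfg.window_size if cfg.window_size is not None else grid_hw[0]
        m_h = min(m, grid_hw[0])
        m_w = min(m, grid_hw[1])
        super().__init__(dim, grid_hw, (m_h, m_w), cfg, rng)


class ESGABlock(_BiasedTransformerBlock):
    """Enhanced spatially aware *global* attention block (full-grid scope)."""

    def __init__(self, dim: int, grid_hw: tuple[int, int], cfg: AttentionConfig,
                 rng: np.random.Generator):
        super().__init__(dim, grid_hw, tuple(grid_hw), cfg, rng)


class CrossAttention(nn.Module):
    """Decoder queries (via the distinct projection W') attend to encoder
    keys/values: ``C = softmax(D'' E_enc^T / sqrt(d_head)) V_enc``."""

    def __init__(self, dec_dim: int, enc_dim: int, cfg: AttentionConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.proj = AttentionProjections(dec_dim, cfg, rng, kv_dim=enc_dim,
                                         w_prime=True)

    def forward(self, dec: TokenGrid, enc: TokenGrid) -> TokenGrid:
        out = biased_attention(dec.values, self.proj, None, self.cfg,
                               kv_tokens=enc.values)
        return TokenGrid(out, dec.h, dec.w)


def cross_attention_fuse(dec: TokenGrid, enc: TokenGrid,
                         module: CrossAttention) -> TokenGrid:
    """Functional form of :class:`CrossAttention`; output has decoder dims."""
    return module(dec, enc)


class SkipAttentionFuse(nn.Module):
    """Attention-based skip fusion at one resolution.

    Decoder tokens query the same-resolution encoder tokens through cross
    attention; the result is residually added to the decoder stream, so a
    zero value projection passes the decoder through unchanged.
    """

    def __init__(self, dec_dim: int, enc_dim: int, cfg: AttentionConfig,
                 rng: np.random.Generator):
        self.cross = CrossAttention(dec_dim, enc_dim, cfg, rng)

    def forward(self, dec: TokenGrid, enc: TokenGrid) -> TokenGrid:
        if (dec.h, dec.w) != (enc.h, enc.w):
            raise ValueError(f"skip attention needs same-resolution grids, got "
                             f"decoder {(dec.h, dec.w)} vs encoder {(enc.h, enc.w)}")
        fused = self.cross(dec, enc)
        return TokenGrid(dec.values + fused.values, dec.h, dec.w)
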