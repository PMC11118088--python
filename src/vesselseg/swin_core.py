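"""Shifted-window transformer backbone primitives.

Tokens live on a channels-last grid (N, H, W, C).  A "stage" is a sequence of
block pairs: a window-attention block followed by a shifted-window block, each
block being pre-norm attention + residual then pre-norm MLP + residual.  The
shifted variant rolls the grid by floor(window/2) with an attention mask that
stops wrapped-around regions from attending to each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigurationError, DimensionError

_F32 = np.float32


@dataclass(frozen=True)
class StageConfig:
    """Hyperparameters of one attention stage.

    depth: number of (W-MSA, SW-MSA) block pairs
    heads: attention heads; must divide the stage channel dim
    window: window side length in tokens
    mlp_ratio: hidden expansion of the per-token MLP
    """

    depth: int = 2
    heads: int = 3
    window: int = 7
    mlp_ratio: float = 4.0

    def validate(self, dim: int) -> list[str]:
        errs = []
        if self.depth < 1:
            errs.append(f"depth must be >= 1, got {self.depth}")
        if self.window < 1:
            errs.append(f"window must be >= 1, got {self.window}")
        if self.heads < 1 or dim % self.heads != 0:
            errs.append(f"heads ({self.heads}) must divide channel dim ({dim})")
        return errs


# -- tokenization -----------------------------------------------------------

def patch_partition(image: np.ndarray, patch: int = 4) -> np.ndarray:
    """Rearrange an (H, W, 3) or (N, H, W, 3) image into non-overlapping
    patch tokens of dim patch*patch*3.  Lossless: no weights involved."""
    arr = np.asarray(image, dtype=_F32)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    if arr.ndim != 4:
        raise DimensionError(f"expected (N,H,W,C) or (H,W,C) image, got shape {arr.shape}")
    N, H, W, C = arr.shape
    if H % patch != 0:
        raise DimensionError(f"height {H} is not divisible by patch size {patch}")
    if W % patch != 0:
        raise DimensionError(f"width {W} is not divisible by patch size {patch}")
    out = (
        arr.reshape(N, H // patch, patch, W // patch, patch, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(N, H // patch, W // patch, patch * patch * C)
    )
    return out[0] if squeeze else out


class LinearEmbedding(nn.Module):
    """Affine per-token projection of raw patch vectors to the model width."""

    def __init__(self, in_dim: int = 48, embed_dim: int = 96):
        super().__init__()
        self.in_dim = in_dim
        self.proj = nn.Linear(in_dim, embed_dim)
        self.norm = nn.LayerNorm(embed_dim)

    def init(self, rng):
        self.proj.init(rng)
        return self

    def forward(self, tokens: Tensor) -> Tensor:
        if tokens.shape[-1] != self.in_dim:
            raise DimensionError(
                f"expected token dim {self.in_dim}, got {tokens.shape[-1]}"
            )
        return self.norm(self.proj(tokens))


# -- windows ----------------------------------------------------------------

def window_partition(x: Tensor, w: int) -> Tensor:
    """(N, H, W, C) -> (N * nWin, w*w, C)."""
    N, H, W, C = x.shape
    return (
        x.reshape(N, H // w, w, W // w, w, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(N * (H // w) * (W // w), w * w, C)
    )


def window_reverse(xw: Tensor, w: int, N: int, H: int, W: int) -> Tensor:
    C = xw.shape[-1]
    return (
        xw.reshape(N, H // w, W // w, w, w, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(N, H, W, C)
    )


def shift_attention_mask(H: int, W: int, w: int, shift: int) -> np.ndarray:
    """(nWin, w*w, w*w) additive mask: -100 between wrapped regions, else 0."""
    region = np.zeros((1, H, W, 1), dtype=_F32)
    cnt = 0
    for hs in (slice(0, H - w), slice(H - w, H - shift), slice(H - shift, H)):
        for ws in (slice(0, W - w), slice(W - w, W - shift), slice(W - shift, W)):
            region[:, hs, ws, :] = cnt
            cnt += 1
    ids = window_partition(Tensor(region), w).data.reshape(-1, w * w)
    mask = (ids[:, :, None] != ids[:, None, :]).astype(_F32) * -100.0
    return mask


def _relative_index(w: int) -> np.ndarray:
    coords = np.stack(np.meshgrid(np.arange(w), np.arange(w), indexing="ij"), axis=0)
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel.transpose(1, 2, 0) + (w - 1)
    return (rel[..., 0] * (2 * w - 1) + rel[..., 1]).reshape(-1)


class WindowAttention(nn.Module):
    """Multi-head self-attention inside fixed windows, with a learned
    relative-position bias per head."""

    def __init__(self, dim: int, heads: int, window: int):
        super().__init__()
        if dim % heads != 0:
            raise ConfigurationError(f"heads ({heads}) must divide dim ({dim})")
        self.dim, self.heads, self.window = dim, heads, window
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.qkv = nn.Linear(dim, 3 * dim)
        self.proj = nn.Linear(dim, dim)
        self.rel_bias = nn.Parameter(np.zeros(((2 * window - 1) ** 2, heads), dtype=_F32))
        self._rel_idx = _relative_index(window)

    def init(self, rng, out_std=None):
        self.qkv.init(rng)
        self.proj.init(rng, out_std if out_std is not None else 0.02)
        nn.trunc_normal_(self.rel_bias, rng)
        return self

    def forward(self, xw: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, T, C = xw.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(xw).reshape(B, T, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = ad.split(qkv, 3, axis=0)
        q = q.reshape(B, h, T, hd)
        k = k.reshape(B, h, T, hd)
        v = v.reshape(B, h, T, hd)
        attn = ad.matmul(q * self.scale, k.transpose(0, 1, 3, 2))
        bias = ad.take_rows(self.rel_bias, self._rel_idx).reshape(T, T, h).transpose(2, 0, 1)
        attn = attn + bias.reshape(1, h, T, T)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(B // nw, nw, h, T, T) + Tensor(mask[None, :, None])
            attn = attn.reshape(B, h, T, T)
        attn = ad.softmax(attn, axis=-1)
        out = ad.matmul(attn, v).transpose(0, 2, 1, 3).reshape(B, T, C)
        return self.proj(out)

    def attention_weights(self, xw: np.ndarray) -> np.ndarray:
        """Softmax attention maps for inspection/tests (no mask)."""
        B, T, C = xw.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(Tensor(xw)).reshape(B, T, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, _ = ad.split(qkv, 3, axis=0)
        q = q.reshape(B, h, T, hd)
        k = k.reshape(B, h, T, hd)
        attn = ad.matmul(q * self.scale, k.transpose(0, 1, 3, 2))
        bias = ad.take_rows(self.rel_bias, self._rel_idx).reshape(T, T, h).transpose(2, 0, 1)
        attn = attn + bias.reshape(1, h, T, T)
        return ad.softmax(attn, axis=-1).data


class SwinBlock(nn.Module):
    """One pre-norm transformer block with (shifted-)window attention."""

    def __init__(self, dim: int, heads: int, window: int, shift: int, mlp_ratio: float = 4.0):
        super().__init__()
        self.dim, self.window, self.shift = dim, window, shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.Mlp(dim, int(dim * mlp_ratio))
        self._mask_cache: dict[tuple, np.ndarray] = {}

    def init(self, rng, residual_std=0.02):
        # small residual-branch output std keeps the trunk near identity at
        # start, which speeds up optimization on short schedules
        self.attn.init(rng, out_std=residual_std)
        self.mlp.init(rng, out_std=residual_std)
        return self

    def forward(self, x: Tensor) -> Tensor:
        N, H, W, C = x.shape
        w = self.window
        if H % w or W % w:
            raise DimensionError(f"token grid {H}x{W} not divisible by window {w}")
        shortcut = x
        x = self.norm1(x)
        mask = None
        if self.shift:
            x = ad.roll(x, (-self.shift, -self.shift), axes=(1, 2))
            key = (H, W)
            if key not in self._mask_cache:
                self._mask_cache[key] = shift_attention_mask(H, W, w, self.shift)
            mask = self._mask_cache[key]
        xw = window_partition(x, w)
        xw = self.attn(xw, mask)
        x = window_reverse(xw, w, N, H, W)
        if self.shift:
            x = ad.roll(x, (self.shift, self.shift), axes=(1, 2))
        x = shortcut + x
        return x + self.mlp(self.norm2(x))


class SwinStage(nn.Module):
    """cfg.depth pairs of (window, shifted-window) blocks; shape preserving."""

    def __init__(self, dim: int, cfg: StageConfig):
        super().__init__()
        errs = cfg.validate(dim)
        if errs:
            raise ConfigurationError("; ".join(errs))
        shift = cfg.window // 2
        blocks = []
        for _ in range(cfg.depth):
            blocks.append(SwinBlock(dim, cfg.heads, cfg.window, 0, cfg.mlp_ratio))
            blocks.append(SwinBlock(dim, cfg.heads, cfg.window, shift, cfg.mlp_ratio))
        self.blocks = blocks

    def init(self, rng, residual_std=0.02):
        for b in self.blocks:
            b.init(rng, residual_std)
        return self

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class PatchMerging(nn.Module):
    """2x2 neighbor concatenation (4*dim) + linear reduction to 2*dim."""

    def __init__(self, dim: int):
        super().__init__()
        self.dim = dim
        self.norm = nn.LayerNorm(4 * dim)
        self.reduce = nn.Linear(4 * dim, 2 * dim, bias=False)

    def init(self, rng):
        self.reduce.init(rng)
        return self

    def forward(self, x: Tensor) -> Tensor:
        N, H, W, C = x.shape
        if H % 2 or W % 2:
            raise DimensionError(f"patch merging needs even spatial dims, got {H}x{W}")
        parts = [x[:, 0::2, 0::2, :], x[:, 1::2, 0::2, :], x[:, 0::2, 1::2, :], x[:, 1::2, 1::2, :]]
        return self.reduce(self.norm(ad.concat(parts, axis=-1)))


class PatchExpanding(nn.Module):
    """Factor-2 expansion: project to 2*dim then rearrange to (2H, 2W, dim/2).
    Factor-4 (final head): project to 16*dim then rearrange to (4H, 4W, dim)."""

    def __init__(self, dim: int, factor: int = 2):
        super().__init__()
        if factor not in (2, 4):
            raise ConfigurationError(f"expand factor must be 2 or 4, got {factor}")
        if factor == 2 and dim % 2 != 0:
            raise DimensionError(f"factor-2 expansion needs even dim, got {dim}")
        self.dim, self.factor = dim, factor
        self.out_dim = dim // 2 if factor == 2 else dim
        proj_out = 2 * dim if factor == 2 else 16 * dim
        self.proj = nn.Linear(dim, proj_out, bias=False)
        self.norm = nn.LayerNorm(self.out_dim)

    def init(self, rng):
        self.proj.init(rng)
        return self

    def forward(self, x: Tensor) -> Tensor:
        N, H, W, _ = x.shape
        f, c = self.factor, self.out_dim
        y = self.proj(x).reshape(N, H, W, f, f, c).transpose(0, 1, 3, 2, 4, 5)
        return self.norm(y.reshape(N, H * f, W * f, c))
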