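"""Pixel-wise texture highlighting and its host decoder block.

The highlighting chain, per feature map Fin (N, H, W, C):

    Z    = Fin + SobelMag(PN(Fin))          boundary-augmented map
    G    = GaussianBlur3x3(Z)               smoothed gate
    V    = G * Fin                          elementwise gating
    Fout = Conv1x1([V ; Fin])               texture blending, C channels out

PN is per-pixel RMS normalization across channels (epsilon 1e-8), SobelMag the
per-channel magnitude of horizontal/vertical 3x3 Sobel responses.  Sobel and
the blur use reflective padding so image borders do not create artificial
edges.  The PT Swin block applies this chain to the token grid and then a
(window, shifted-window) attention pair.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import DimensionError
from .swin_core import StageConfig, SwinStage

_F32 = np.float32

PN_EPS = 1e-8

# 3x3 Sobel taps; response to a unit step is 4 per axis
_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=_F32)
_SOBEL_Y = _SOBEL_X.T.copy()


def _gaussian3(sigma: float = 0.8) -> np.ndarray:
    g = np.exp(-np.arange(-1, 2) ** 2 / (2.0 * sigma * sigma))
    k = np.outer(g, g)
    return (k / k.sum()).astype(_F32)


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        t = x
        was_array = False
    else:
        t = Tensor(np.asarray(x, dtype=_F32))
        was_array = True
    if t.ndim == 3:
        t = t.reshape((1,) + t.shape)
    if t.ndim != 4:
        raise DimensionError(f"expected (N,H,W,C) or (H,W,C) feature map, got {t.shape}")
    return t, was_array


def _depthwise3(x: Tensor, kernel: np.ndarray) -> Tensor:
    """Fixed (non-learned) 3x3 per-channel convolution, reflective padding."""
    N, H, W, C = x.shape
    if H < 3 or W < 3:
        raise DimensionError(f"spatial dims must be >= 3 for a 3x3 kernel, got {H}x{W}")
    xp = ad.pad_reflect(x, 1, 1)
    y = None
    for i in range(3):
        for j in range(3):
            c = float(kernel[i, j])
            if c == 0.0:
                continue
            tap = xp[:, i : i + H, j : j + W, :] * c
            y = tap if y is None else y + tap
    return y


def pixel_normalize(F) -> Tensor:
    """Divide each pixel's channel vector by its RMS (epsilon-guarded)."""
    t, _ = _as_tensor(F)
    ms = (t * t).mean(axis=-1, keepdims=True)
    return t / (ms + PN_EPS).sqrt()


def sobel_magnitude(F) -> Tensor:
    """Per-channel gradient magnitude sqrt(Sx^2 + Sy^2), reflective padding."""
    t, _ = _as_tensor(F)
    sx = _depthwise3(t, _SOBEL_X)
    sy = _depthwise3(t, _SOBEL_Y)
    return ad.hypot(sx, sy)


def gaussian_blur3(F, sigma: float = 0.8) -> Tensor:
    """3x3 Gaussian blur (kernel normalized to sum 1), per channel."""
    t, _ = _as_tensor(F)
    return _depthwise3(t, _gaussian3(sigma))


class PTHM(nn.Module):
    """Pixel-wise Texture Highlighting Module (shape preserving)."""

    def __init__(self, dim: int, sigma: float = 0.8):
        super().__init__()
        self.dim = dim
        self.sigma = float(sigma)
        self.blend = nn.Linear(2 * dim, dim)  # the 1x1 blending convolution

    def init(self, rng):
        self.blend.init(rng)
        return self

    def forward(self, fin: Tensor) -> Tensor:
        z = fin + sobel_magnitude(pixel_normalize(fin))
        gate = gaussian_blur3(z, self.sigma)
        v = gate * fin
        return self.blend(ad.concat([v, fin], axis=-1))


def texture_highlight(module: PTHM, Fin) -> Tensor:
    """Functional alias for :meth:`PTHM.forward` on arrays or tensors."""
    t, _ = _as_tensor(Fin)
    return module(t)


class PTSwinBlock(nn.Module):
    """Texture highlighting composed with an attention stage.

    `position` controls whether highlighting runs before the attention pair
    (default: enrich locally, then mix globally) or after it; `enabled=False`
    reduces the block to a plain attention stage for ablations.
    """

    def __init__(self, dim: int, cfg: StageConfig, enabled: bool = True,
                 position: str = "before", sigma: float = 0.8):
        super().__init__()
        if position not in ("before", "after"):
            raise ValueError(f"position must be 'before' or 'after', got {position!r}")
        self.enabled = bool(enabled)
        self.position = position
        self.pthm = PTHM(dim, sigma)
        self.stage = SwinStage(dim, cfg)

    def init(self, rng, residual_std=0.02):
        self.pthm.init(rng)
        self.stage.init(rng, residual_std)
        return self

    def forward(self, x: Tensor) -> Tensor:
        if self.enabled and self.position == "before":
            x = self.pthm(x)
        x = self.stage(x)
        if self.enabled and self.position == "after":
            x = self.pthm(x)
        return x
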