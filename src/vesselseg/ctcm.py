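"""Cross-level texture complementary fusion.

The encoder emits a three-level pyramid F1 (1/4 scale, C channels),
F2 (1/8, 2C), F3 (1/16, 4C).  Downsampling discards fine boundary texture;
this module recovers it by forming two difference maps at the finest scale,

    Fd1 = P1(F1)        - up4(P3(F3))
    Fd2 = up2(P2(F2))   - up4(P3(F3))

where P* are independent 1x1 projections to 4C channels, then re-compresses
the weighted, concatenated differences back to 1/16 scale through two
conv->ReLU->average-pool blocks and adds the result to F3 residually:

    Fc = F3 + ConvBlocks([alpha * Fd1 ; beta * Fd2])

Average pooling (not max) is used so recovered texture is aggregated rather
than discarded.  The output always matches F3's shape.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import DimensionError

_F32 = np.float32


def _check_pyramid(F1: Tensor, F2: Tensor, F3: Tensor) -> None:
    n1, h1, w1, c1 = F1.shape
    n2, h2, w2, c2 = F2.shape
    n3, h3, w3, c3 = F3.shape
    if not (n1 == n2 == n3):
        raise DimensionError(f"batch sizes differ: {n1}, {n2}, {n3}")
    if (h2, w2) != (h1 // 2, w1 // 2) or (h3, w3) != (h1 // 4, w1 // 4):
        raise DimensionError(
            f"spatial dims must halve per level, got {h1}x{w1}, {h2}x{w2}, {h3}x{w3}"
        )
    if c2 != 2 * c1 or c3 != 4 * c1:
        raise DimensionError(f"channels must double per level, got {c1}, {c2}, {c3}")


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2."""
    N, H, W, C = x.shape
    if H % 2 or W % 2:
        raise DimensionError(f"average pooling needs even spatial dims, got {H}x{W}")
    return x.reshape(N, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))


class ConvBlock(nn.Module):
    """3x3 convolution -> ReLU -> 2x2 average pooling (stride 2)."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, k=3)

    def init(self, rng):
        self.conv.init(rng)
        return self

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2(ad.relu(self.conv(x)))


class CTCM(nn.Module):
    """Cross-level Texture Complementary Module.

    Parameters
    ----------
    embed_dim:
        C, the channel width of the finest level F1.
    alpha, beta:
        Scalar weights on the two difference maps before fusion.
    upsample:
        "bilinear" (default, smooth texture differences) or "nearest".
    """

    def __init__(self, embed_dim: int, alpha: float = 1.0, beta: float = 1.0,
                 upsample: str = "bilinear"):
        super().__init__()
        if upsample not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {upsample!r}")
        if not (np.isfinite(alpha) and np.isfinite(beta)):
            raise ValueError("alpha and beta must be finite")
        C = embed_dim
        self.alpha, self.beta = float(alpha), float(beta)
        self.upsample = upsample
        self.proj1 = nn.Conv2d(C, 4 * C, k=1)
        self.proj2 = nn.Conv2d(2 * C, 4 * C, k=1)
        self.proj3 = nn.Conv2d(4 * C, 4 * C, k=1)
        self.block1 = ConvBlock(8 * C, 4 * C)
        self.block2 = ConvBlock(4 * C, 4 * C)

    def init(self, rng):
        for m in (self.proj1, self.proj2, self.proj3, self.block1, self.block2):
            m.init(rng)
        return self

    def texture_differences(self, F1: Tensor, F2: Tensor, F3: Tensor) -> tuple[Tensor, Tensor]:
        """The two finest-scale difference maps (each 1/4 scale, 4C channels)."""
        _check_pyramid(F1, F2, F3)
        a1 = self.proj1(F1)
        a2 = ad.upsample2d(self.proj2(F2), 2, self.upsample)
        a3 = ad.upsample2d(self.proj3(F3), 4, self.upsample)
        return a1 - a3, a2 - a3

    def forward(self, F1: Tensor, F2: Tensor, F3: Tensor) -> Tensor:
        d1, d2 = self.texture_differences(F1, F2, F3)
        fused = ad.concat([d1 * self.alpha, d2 * self.beta], axis=-1)
        fused = self.block2(self.block1(fused))
        return F3 + fused


def ctcm_forward(module: CTCM, F1, F2, F3) -> Tensor:
    """Functional alias for :meth:`CTCM.forward` on arrays or tensors."""
    as_t = lambda x: x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_F32))
    return module(as_t(F1), as_t(F2), as_t(F3))
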