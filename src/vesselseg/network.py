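"""The full texture-driven shifted-window segmentation network.

U-shaped layout: a three-stage shifted-window transformer encoder with patch
merging between stages, a cross-level texture fusion module (CTCM) bridging
the encoder pyramid into the decoder's deepest input, and a three-stage
decoder of texture-highlighting attention blocks with patch expanding and
skip connections (concatenation + linear reduction).  A final 4x patch
expansion and per-token linear head produce one score per class per pixel.
Logits come out raw; losses and metrics apply their own activation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .ctcm import CTCM
from .errors import CheckpointError, ConfigurationError, DimensionError
from .pt_swin import PTSwinBlock
from .swin_core import (
    LinearEmbedding,
    PatchExpanding,
    PatchMerging,
    StageConfig,
    SwinStage,
    patch_partition,
)

_F32 = np.float32


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The three stages operate at 1/4, 1/8 and 1/16 of the input resolution
    with C, 2C and 4C channels.  `window` must divide the token grid at all
    three scales; for the default 448-pixel input and patch 4 that means the
    grids 112/56/28, which window 7 divides.
    """

    img_size: int = 448
    patch: int = 4
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 2)
    heads: tuple[int, ...] = (3, 6, 12)
    window: int = 7
    mlp_ratio: float = 4.0
    num_classes: int = 2
    alpha: float = 1.0
    beta: float = 1.0
    enable_ctcm: bool = True
    enable_pthm: bool = True
    pthm_position: str = "before"
    upsample: str = "bilinear"
    blur_sigma: float = 0.8
    # init std of residual-branch output projections (attention proj, MLP
    # out); smaller than the 0.02 used elsewhere, keeping blocks near
    # identity at start for faster short-schedule optimization
    residual_init_std: float = 0.005

    def stage_dims(self) -> list[int]:
        return [self.embed_dim * (2 ** i) for i in range(3)]

    def token_sizes(self) -> list[int]:
        s = self.img_size // self.patch
        return [s, s // 2, s // 4]

    def validate(self) -> list[str]:
        errs = []
        if self.num_classes < 2:
            errs.append(f"num_classes must be >= 2, got {self.num_classes}")
        if self.img_size % self.patch != 0:
            errs.append(f"patch size {self.patch} does not divide image size {self.img_size}")
        if len(self.depths) != 3 or len(self.heads) != 3:
            errs.append("depths and heads must each have 3 entries (one per stage)")
        else:
            s = self.img_size // self.patch
            for i, (dim, hd, dp) in enumerate(zip(self.stage_dims(), self.heads, self.depths)):
                if s % self.window != 0:
                    errs.append(
                        f"window {self.window} does not divide the stage-{i + 1} token grid ({s})"
                    )
                if i < 2 and s % 2 != 0:
                    errs.append(f"stage-{i + 1} token grid ({s}) must be even for patch merging")
                if dim % hd != 0:
                    errs.append(f"heads[{i}]={hd} does not divide stage dim {dim}")
                if dp < 1:
                    errs.append(f"depths[{i}] must be >= 1, got {dp}")
                s //= 2
        if self.pthm_position not in ("before", "after"):
            errs.append(f"pthm_position must be 'before' or 'after', got {self.pthm_position!r}")
        if self.upsample not in ("bilinear", "nearest"):
            errs.append(f"upsample must be 'bilinear' or 'nearest', got {self.upsample!r}")
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            errs.append("alpha and beta must be finite")
        return errs

    def stage_cfg(self, i: int) -> StageConfig:
        return StageConfig(self.depths[i], self.heads[i], self.window, self.mlp_ratio)


class TextureSwinUNet(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        errs = cfg.validate()
        if errs:
            raise ConfigurationError("invalid model configuration: " + "; ".join(errs))
        self.cfg = cfg
        C = cfg.embed_dim
        self.embed = LinearEmbedding(cfg.patch * cfg.patch * 3, C)
        self.enc1 = SwinStage(C, cfg.stage_cfg(0))
        self.merge1 = PatchMerging(C)
        self.enc2 = SwinStage(2 * C, cfg.stage_cfg(1))
        self.merge2 = PatchMerging(2 * C)
        self.enc3 = SwinStage(4 * C, cfg.stage_cfg(2))
        self.ctcm = CTCM(C, cfg.alpha, cfg.beta, cfg.upsample)
        pt = lambda dim, i: PTSwinBlock(
            dim, cfg.stage_cfg(i), cfg.enable_pthm, cfg.pthm_position, cfg.blur_sigma
        )
        self.dec3 = pt(4 * C, 2)
        self.expand3 = PatchExpanding(4 * C, 2)
        self.skip2 = nn.Linear(4 * C, 2 * C)
        self.dec2 = pt(2 * C, 1)
        self.expand2 = PatchExpanding(2 * C, 2)
        self.skip1 = nn.Linear(2 * C, C)
        self.dec1 = pt(C, 0)
        self.final_expand = PatchExpanding(C, 4)
        self.head = nn.Linear(C, cfg.num_classes)

    def init(self, rng: np.random.Generator):
        rs = self.cfg.residual_init_std
        self.embed.init(rng)
        for m in (self.enc1, self.enc2, self.enc3, self.dec3, self.dec2, self.dec1):
            m.init(rng, rs)
        for m in (self.merge1, self.merge2, self.ctcm, self.expand3, self.skip2,
                  self.expand2, self.skip1, self.final_expand, self.head):
            m.init(rng)
        return self

    # -- forward -----------------------------------------------------------
    def encode(self, images: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        cfg = self.cfg
        arr = np.asarray(images, dtype=_F32)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[3] != 3:
            raise DimensionError(f"expected (N,H,W,3) input, got {arr.shape}")
        if arr.shape[1] != cfg.img_size or arr.shape[2] != cfg.img_size:
            raise DimensionError(
                f"model expects {cfg.img_size}x{cfg.img_size} input, got {arr.shape[1]}x{arr.shape[2]}"
            )
        x = self.embed(Tensor(patch_partition(arr, cfg.patch)))
        F1 = self.enc1(x)
        F2 = self.enc2(self.merge1(F1))
        F3 = self.enc3(self.merge2(F2))
        return F1, F2, F3

    def forward(self, images: np.ndarray) -> Tensor:
        F1, F2, F3 = self.encode(images)
        fc = self.ctcm(F1, F2, F3) if self.cfg.enable_ctcm else F3
        d = self.dec3(fc)
        x = self.skip2(ad.concat([self.expand3(d), F2], axis=-1))
        d = self.dec2(x)
        x = self.skip1(ad.concat([self.expand2(d), F1], axis=-1))
        d = self.dec1(x)
        return self.head(self.final_expand(d))

    # -- inference helpers -------------------------------------------------
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, (N, H, W, NC)."""
        logits = self.forward(images).data
        logits = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=-1, keepdims=True)

    def predict_mask(self, images: np.ndarray) -> np.ndarray:
        """Argmax class map, (N, H, W); ties resolve to background (class 0)."""
        return np.argmax(self.forward(images).data, axis=-1)


def build_model(cfg: ModelConfig, seed: int = 0) -> TextureSwinUNet:
    """Construct and initialize the network (truncated-normal projections,
    zero biases) from a single integer seed."""
    model = TextureSwinUNet(cfg)
    model.init(np.random.default_rng(seed))
    return model


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(path, model: TextureSwinUNet) -> None:
    """Single-file weights container with the architecture config embedded."""
    state = model.state_dict()
    cfg = asdict(model.cfg)
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **{f"param/{k}": v for k, v in state.items()})


def load_checkpoint(path) -> TextureSwinUNet:
    with np.load(path) as data:
        if "__config__" not in data:
            raise CheckpointError(f"{path} is not a model checkpoint (no embedded config)")
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        for key in ("depths", "heads"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = ModelConfig(**cfg_dict)
        model = TextureSwinUNet(cfg)
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    try:
        model.load_state_dict(state)
    except (KeyError, ValueError) as exc:
        raise CheckpointError(f"checkpoint {path} does not match its config: {exc}") from exc
    return model
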