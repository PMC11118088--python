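"""SGD training with polynomial learning-rate decay, plus prediction helpers.

Optimization follows the segmentation-standard recipe: SGD with momentum 0.9
and weight decay 1e-4, batch size 2, and the per-epoch schedule

    lr(epoch) = initial_lr * (1 - epoch / max_epoch) ** poly_exponent

with initial_lr 0.01, max_epoch 200 and exponent 0.9 by default.  A single
integer seed controls weight initialization, shuffling, augmentation and
phantom generation.  A configurable fraction of the training samples is held
out for best-checkpoint selection by F1 (set 0 to train on everything).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data_pipeline import ImageSample, augment
from .errors import DatasetError, VesselSegError
from .evaluation import Metrics, evaluate_pairs
from .losses import LossConfig, total_loss
from .network import ModelConfig, TextureSwinUNet, build_model, save_checkpoint

logger = logging.getLogger("vesselseg")


@dataclass
class TrainConfig:
    initial_lr: float = 0.01
    max_epoch: int = 200
    poly_exponent: float = 0.9
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 2
    seed: int = 0
    val_fraction: float = 0.2
    # linear ramp of the Hausdorff weight over the first K epochs (0 = off).
    # The term's gradient has magnitude ~eps and is concentrated on worst
    # offenders; on short schedules it needs a coarse segmentation to exist
    # before it is useful.
    haus_warmup_epochs: int = 0
    # optional global gradient-norm clip (None = off); tames the spiky
    # worst-offender gradients of the Hausdorff term on short schedules
    grad_clip: float | None = None
    # start the segmentation head at the empirical class-prior logits so the
    # initial prediction matches base rates instead of 50/50
    init_head_bias_from_prior: bool = True
    # random flip augmentation; disable for pure overfit-capacity runs
    augment: bool = True
    # decay horizon of the polynomial schedule; None = max_epoch.  Setting it
    # beyond max_epoch trains on the early (higher-lr) part of the schedule,
    # useful when a run is a truncated version of a longer protocol.
    schedule_horizon: int | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    out_dir: str = "runs/default"

    def validate(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError(f"initial_lr must be positive, got {self.initial_lr}")
        if self.max_epoch < 1:
            raise ValueError(f"max_epoch must be >= 1, got {self.max_epoch}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError(f"val_fraction must lie in [0, 1), got {self.val_fraction}")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Polynomial decay; strictly decreasing from initial_lr to 0 at the
    schedule horizon (= max_epoch unless overridden)."""
    horizon = cfg.schedule_horizon or cfg.max_epoch
    if not (0 <= epoch <= horizon):
        raise ValueError(f"epoch {epoch} outside [0, {horizon}]")
    return cfg.initial_lr * (1.0 - epoch / horizon) ** cfg.poly_exponent


@dataclass
class TrainResult:
    history: list[dict]
    best_f1: float
    best_epoch: int
    best_checkpoint: str
    last_checkpoint: str
    final_train_metrics: Metrics | None = None


def _batches(n: int, bs: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, bs):
        yield order[i : i + bs]


def _model_f1(model: TextureSwinUNet, samples: list[ImageSample]) -> Metrics:
    preds = [model.predict_mask(s.image[None])[0] for s in samples]
    _, agg = evaluate_pairs([(p, s.mask) for p, s in zip(preds, samples)])
    return agg


def train(samples: list[ImageSample], cfg: TrainConfig,
          log_every: int = 1) -> TrainResult:
    """Train a model on preprocessed samples; returns history + checkpoints.

    Raises on NaN loss, naming the first offending loss term.
    """
    cfg.validate()
    if not samples:
        raise DatasetError("no training samples provided")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.val_fraction * len(samples)))
    order = rng.permutation(len(samples))
    val = [samples[i] for i in order[:n_val]]
    tr = [samples[i] for i in order[n_val:]]
    if not tr:
        raise DatasetError("validation split left no training samples")

    model = build_model(cfg.model, seed=cfg.seed)
    if cfg.init_head_bias_from_prior and model.head.bias is not None:
        prior = float(np.clip(np.mean([s.mask.mean() for s in tr]), 1e-4, 1 - 1e-4))
        model.head.bias.data[:] = np.log(
            [1.0 - prior, prior], dtype=np.float32
        )  # softmax of these equals the empirical foreground rate
    opt = nn.SGD(model.parameters(), lr=cfg.initial_lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)

    history: list[dict] = []
    best_f1, best_epoch = -1.0, -1
    best_path = out_dir / "best.npz"
    last_path = out_dir / "last.npz"
    log_path = out_dir / "train_log.jsonl"
    log_fh = open(log_path, "w")
    try:
        nominal_omega3 = cfg.loss.omega3
        for epoch in range(cfg.max_epoch):
            opt.lr = lr_schedule(epoch, cfg)
            if cfg.haus_warmup_epochs > 0:
                ramp = min(1.0, epoch / cfg.haus_warmup_epochs)
                cfg.loss.omega3 = nominal_omega3 * ramp
            sums = {"total": 0.0, "ce": 0.0, "dice": 0.0, "clip_haus": 0.0}
            n_batches = 0
            for idx in _batches(len(tr), cfg.batch_size, rng):
                batch = [augment(tr[i], rng) if cfg.augment else tr[i] for i in idx]
                images = np.stack([b.image for b in batch])
                labels = np.stack([b.mask for b in batch])
                model.zero_grad()
                loss, parts = total_loss(model(images), labels, cfg.loss, return_parts=True)
                for k in sums:
                    sums[k] += parts[k]
                    if math.isnan(parts[k]):
                        raise VesselSegError(
                            f"NaN loss in term '{k}' at epoch {epoch}; aborting"
                        )
                loss.backward()
                if cfg.grad_clip:
                    nn.clip_grad_norm(model.parameters(), cfg.grad_clip)
                opt.step()
                n_batches += 1
            rec = {"epoch": epoch, "lr": opt.lr,
                   **{k: v / n_batches for k, v in sums.items()}}
            if val:
                vm = _model_f1(model, val)
                rec["val_f1"] = vm.f1
                rec["val_acc"] = vm.acc
                if vm.f1 > best_f1:
                    best_f1, best_epoch = vm.f1, epoch
                    save_checkpoint(best_path, model)
            log_fh.write(json.dumps(rec) + "\n")
            log_fh.flush()
            history.append(rec)
            if log_every and epoch % log_every == 0:
                logger.info("epoch %d lr %.5f total %.4f (ce %.4f dice %.4f haus %.4f)%s",
                            epoch, rec["lr"], rec["total"], rec["ce"], rec["dice"],
                            rec["clip_haus"],
                            f" val_f1 {rec['val_f1']:.4f}" if "val_f1" in rec else "")
    finally:
        log_fh.close()
        cfg.loss.omega3 = nominal_omega3
    save_checkpoint(last_path, model)
    if not val:
        tm = _model_f1(model, tr)
        best_f1, best_epoch = tm.f1, cfg.max_epoch - 1
        save_checkpoint(best_path, model)
        final_metrics = tm
    else:
        final_metrics = _model_f1(model, tr)
    return TrainResult(history=history, best_f1=best_f1, best_epoch=best_epoch,
                       best_checkpoint=str(best_path), last_checkpoint=str(last_path),
                       final_train_metrics=final_metrics)


def predict_dataset(model: TextureSwinUNet, samples: list[ImageSample]) -> list[np.ndarray]:
    return [model.predict_mask(s.image[None])[0].astype(np.uint8) for s in samples]
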