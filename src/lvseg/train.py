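"""Training loop for the segmentation networks.

The learning rate is adjusted linearly from ``lr_initial`` (0.001) to
``lr_final`` (0.0001) over the first ``lr_end_epoch`` (120) epochs and
held constant afterwards.  Loss is per-pixel cross-entropy by default,
with soft-dice and a combined sum selectable.  The checkpoint with the
best validation dice is retained.  Runs are deterministic for a fixed
seed: shuffling, weight init and the numpy backend are all seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import dice
from .model import ImprovedResUNet, normalize_image, predict
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import DTYPE
from .nn.optim import make_optimizer

LOSSES = ("cross_entropy", "dice", "combined")


@dataclass
class TrainConfig:
    lr_initial: float = 1e-3
    lr_final: float = 1e-4
    lr_end_epoch: int = 120
    n_epochs: int = 150
    batch_size: int = 8
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    seed: int = 0
    target: str = "endo"

    def __post_init__(self):
        if not (0 < self.lr_final <= self.lr_initial):
            raise ValueError("need 0 < lr_final <= lr_initial")
        if self.lr_end_epoch > self.n_epochs:
            raise ValueError("lr_end_epoch must not exceed n_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if self.target not in ("endo", "epi"):
            raise ValueError("target must be 'endo' or 'epi'")


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_dice: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Linear decay lr_initial -> lr_final over [0, lr_end_epoch], then constant."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    if epoch >= config.lr_end_epoch:
        return config.lr_final
    frac = epoch / config.lr_end_epoch
    return config.lr_initial + (config.lr_final - config.lr_initial) * frac


def _loss_fn(name: str, logits: Tensor, labels: np.ndarray) -> Tensor:
    if name == "cross_entropy":
        return ag.softmax_cross_entropy(logits, labels)
    if name == "dice":
        return ag.soft_dice_loss(logits, labels)
    ce = ag.softmax_cross_entropy(logits, labels)
    dl = ag.soft_dice_loss(logits, labels)
    return ag.add(ce, dl)


def _prepare(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Normalize images and stack (N,1,H,W) inputs / (N,H,W) int labels."""
    imgs = np.stack([normalize_image(img) for img, _ in pairs]).astype(DTYPE)[:, None]
    labels = np.stack([np.asarray(m) > 0 for _, m in pairs]).astype(np.int64)
    return imgs, labels


def _snapshot(model: ImprovedResUNet) -> dict:
    return {
        "params": {k: v.data.copy() for k, v in model.named_parameters().items()},
        "buffers": {k: v.copy() for k, v in model.buffers().items()},
    }


def _restore(model: ImprovedResUNet, snap: dict) -> None:
    for k, v in model.named_parameters().items():
        v.data = snap["params"][k].copy()
    for k, v in model.buffers().items():
        v[...] = snap["buffers"][k]


def validation_dice(model: ImprovedResUNet, val_set) -> float:
    """Mean foreground dice over a held-out set (empty/empty pairs score 1)."""
    scores = []
    for img, gt in val_set:
        _, pred = predict(model, np.asarray(img))
        gt = np.asarray(gt) > 0
        if not pred.any() and not gt.any():
            scores.append(1.0)
        elif not pred.any() or not gt.any():
            scores.append(0.0)
        else:
            scores.append(dice(pred, gt))
    return float(np.mean(scores))


def train(
    model: ImprovedResUNet,
    train_set,
    val_set,
    config: TrainConfig,
    verbose: bool = False,
) -> tuple[ImprovedResUNet, TrainHistory]:
    """Fit ``model`` on (image, mask) pairs; returns the best-validation model.

    ``train_set`` / ``val_set`` are sequences of (image, binary mask)
    arrays matching the model's input size.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    size = model.config.input_size
    for img, m in list(train_set) + list(val_set):
        if np.asarray(img).shape != (size, size):
            raise ValueError(f"sample shape {np.asarray(img).shape} != model input {size}")
        if not np.all(np.isin(np.unique(m), (0, 1, True, False))):
            raise ValueError("masks must be binary")

    x_all, y_all = _prepare(train_set)
    rng = np.random.default_rng(config.seed)
    opt = make_optimizer(config.optimizer, model.parameters(), config.lr_initial)

    history = TrainHistory()
    best = {"dice": -1.0, "snap": None}
    n = len(train_set)
    for epoch in range(config.n_epochs):
        lr = lr_schedule(epoch, config)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(Tensor(x_all[idx]))
            loss = _loss_fn(config.loss, logits, y_all[idx])
            lv = loss.item()
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite training loss {lv} at epoch {epoch} (lr={lr:g})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lv)
        vd = validation_dice(model, val_set)
        history.records.append(EpochRecord(epoch, lr, float(np.mean(losses)), vd))
        if vd > best["dice"]:
            best = {"dice": vd, "snap": _snapshot(model)}
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.6f}  loss {np.mean(losses):.4f}  "
                  f"val dice {vd:.4f}")
    if best["snap"] is not None:
        _restore(model, best["snap"])
    return model, history
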