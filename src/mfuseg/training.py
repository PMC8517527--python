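"""Training: seeded 80/20 split, Adagrad optimisation, best-validation-Dice
checkpointing.

The default configuration follows the full-scale recipe: Adagrad with
learning rate 1e-3, 50 epochs, batch size 16, an 80/20 train/validation
split, and the weights of the epoch with the highest validation Dice
(earliest epoch on ties) kept as the checkpoint.  Validation Dice is the
unweighted mean of liver and tumor Dice over validation slices, with an
empty-empty slice scoring 1.  The loss is selectable: cross-entropy, soft
Dice over the foreground classes, or their sum (default).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .nn.losses import compute_loss  # re-exported: scalar loss on prob maps
from .mfu_net import MFUNet

__all__ = ["TrainConfig", "TrainHistory", "split_dataset", "compute_loss",
           "slice_dice", "evaluate_dice", "train"]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adagrad"
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 16
    val_fraction: float = 0.2
    seed: int = 0
    loss: str = "ce+dice"
    checkpoint_metric: str = "dice"

    def __post_init__(self):
        if not (0 < self.val_fraction < 1):
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adagrad":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.checkpoint_metric != "dice":
            raise ValueError(f"unsupported checkpoint metric {self.checkpoint_metric!r}")


@dataclass
class TrainHistory:
    """Per-epoch records plus the untrained baseline.

    ``rows`` has one entry per epoch: (epoch, loss, dice_liver, dice_tumor,
    dice_mean); ``baseline_dice`` is the validation Dice of the untrained
    network; ``best_epoch`` indexes into rows (1-based epoch number).
    """

    rows: list[dict] = field(default_factory=list)
    baseline_dice: float = float("nan")
    best_epoch: int = -1
    best_dice: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["epoch", "loss", "dice_liver",
                                                "dice_tumor", "dice_mean"])

    def __len__(self) -> int:
        return len(self.rows)


def split_dataset(items, val_fraction: float, seed: int):
    """Random disjoint, exhaustive train/validation partition.

    The validation size is the fraction rounded to the nearest item
    (clamped so both parts are non-empty); the split is deterministic under
    the seed.
    """
    items = list(items)
    n = len(items)
    if n < 2:
        raise ValueError(f"need at least 2 items to split, got {n}")
    n_val = int(round(n * val_fraction))
    n_val = min(max(n_val, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    val_idx = set(perm[:n_val].tolist())
    train = [items[i] for i in range(n) if i not in val_idx]
    val = [items[i] for i in range(n) if i in val_idx]
    return train, val


def slice_dice(pred_labels: np.ndarray, gt_labels: np.ndarray) -> tuple[float, float]:
    """(liver, tumor) Dice on one label plane; empty-empty scores 1.

    Liver merges labels {1, 2} (tumor lies inside the liver).
    """
    out = []
    for cls_mask_p, cls_mask_g in (
        (pred_labels >= 1, gt_labels >= 1),
        (pred_labels == 2, gt_labels == 2),
    ):
        s = int(cls_mask_p.sum()) + int(cls_mask_g.sum())
        if s == 0:
            out.append(1.0)
        else:
            out.append(2.0 * int((cls_mask_p & cls_mask_g).sum()) / s)
    return out[0], out[1]


def _forward_batch(net: MFUNet, images: np.ndarray) -> nn.Var:
    return net(nn.Var(images[:, None, :, :]))


def evaluate_dice(net: MFUNet, pairs, batch_size: int = 16) -> tuple[float, float, float]:
    """Mean (liver, tumor, mean) Dice of ``net`` over (image, label) pairs."""
    net.eval()
    livers, tumors = [], []
    with nn.no_grad():
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start : start + batch_size]
            images = np.stack([np.asarray(im, dtype=float) for im, _ in chunk])
            logits = _forward_batch(net, images).data
            preds = logits.argmax(axis=1)
            for (_, lab), pred in zip(chunk, preds):
                dl, dt = slice_dice(pred, np.asarray(lab))
                livers.append(dl)
                tumors.append(dt)
    dl, dt = float(np.mean(livers)), float(np.mean(tumors))
    return dl, dt, (dl + dt) / 2.0


def train(net: MFUNet, data, cfg: TrainConfig):
    """Train ``net`` on (image, label) slice pairs.

    Splits the data with ``cfg.val_fraction``/``cfg.seed``, runs
    ``cfg.epochs`` epochs of Adagrad, records per-epoch train loss and
    validation Dice, and returns ``(best_weights, history)`` where
    ``best_weights`` is the state dict of the epoch with maximal validation
    Dice (earliest on ties).  The network is left loaded with the best
    weights.  The whole trajectory is deterministic under
    (cfg.seed, data order, single device).
    """
    data = list(data)
    train_set, val_set = split_dataset(data, cfg.val_fraction, cfg.seed)
    if not train_set or not val_set:
        raise ValueError("empty train or validation set")
    for _, lab in data:
        bad = set(np.unique(lab)) - {0, 1, 2}
        if bad:
            raise ValueError(f"labels outside {{0,1,2}}: {sorted(bad)}")

    rng = np.random.default_rng(cfg.seed + 1)  # batch shuffling stream
    opt = nn.Adagrad(net.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    history.baseline_dice = evaluate_dice(net, val_set, cfg.batch_size)[2]

    best_state, best_dice, best_epoch = None, -np.inf, -1
    for epoch in range(1, cfg.epochs + 1):
        net.train()
        order = rng.permutation(len(train_set))
        losses = []
        for bi, start in enumerate(range(0, len(order), cfg.batch_size)):
            idx = order[start : start + cfg.batch_size]
            images = np.stack([np.asarray(train_set[i][0], dtype=float) for i in idx])
            labels = np.stack([np.asarray(train_set[i][1]) for i in idx])
            opt.zero_grad()
            logits = _forward_batch(net, images)
            loss = nn.segmentation_loss(logits, labels, kind=cfg.loss)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {bi}")
            nn.backward(loss)
            opt.step()
            losses.append(lval)
        dl, dt, dmean = evaluate_dice(net, val_set, cfg.batch_size)
        history.rows.append({
            "epoch": epoch, "loss": float(np.mean(losses)),
            "dice_liver": dl, "dice_tumor": dt, "dice_mean": dmean,
        })
        if dmean > best_dice:
            best_dice, best_epoch = dmean, epoch
            best_state = net.state_dict()

    history.best_epoch = best_epoch
    history.best_dice = float(best_dice)
    net.load_state_dict(best_state)
    return best_state, history
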