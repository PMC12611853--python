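"""Training objective, data splits, training loop and overlap metrics.

The loss is the convex combination of binary cross-entropy and Dice loss

    L = w_bce * BCE(p, g) + w_dice * (1 - (2 sum(pg) + s) / (sum(p) + sum(g) + s))

with smoothing s.  Evaluation binarizes the probability map at a threshold
and reports precision, recall, accuracy, DSC and IoU; DSC and IoU obey
DSC = 2 IoU / (1 + IoU) exactly when computed from the same counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import Tensor
from .autograd.nn import Module
from .autograd.optim import Adam

_CLIP = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 1e-5
    weight_decay: float = 1e-4
    w_bce: float = 0.5
    w_dice: float = 0.5
    dice_smooth: float = 1.0
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.learning_rate, self.dice_smooth) <= 0:
            raise ValueError("batch_size, learning_rate and dice_smooth must be positive")
        if self.epochs < 0 or self.weight_decay < 0:
            raise ValueError("epochs and weight_decay must be non-negative")
        if abs(self.w_bce + self.w_dice - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to 1")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    precision: float
    recall: float
    accuracy: float
    dsc: float
    iou: float
    counts: ConfusionCounts | None = None
    degenerate: list[str] = field(default_factory=list)
    per_image: list["MetricsReport"] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "dsc": self.dsc,
            "iou": self.iou,
            "degenerate": list(self.degenerate),
        }


def bce_dice_loss(pred: Tensor, target: np.ndarray,
                  config: TrainConfig | None = None) -> Tensor:
    """Differentiable BCE + Dice loss on a probability map in (0, 1)."""
    config = config or TrainConfig()
    t = np.asarray(target, dtype=np.float32)
    if pred.shape != t.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {t.shape}")
    p = pred.clip(_CLIP, 1.0 - _CLIP)
    tt = Tensor(t)
    bce = -(tt * p.log() + (1.0 - tt) * (1.0 - p).log()).mean()
    s = config.dice_smooth
    inter = (p * tt).sum()
    dice = 1.0 - (2.0 * inter + s) / (p.sum() + tt.sum() + s)
    return config.w_bce * bce + config.w_dice * dice


def confusion_counts(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    p = np.asarray(pred_mask)
    g = np.asarray(true_mask)
    if p.shape != g.shape:
        raise ValueError("masks must have the same shape")
    for name, m in (("pred_mask", p), ("true_mask", g)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    p = p.astype(bool)
    g = g.astype(bool)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, tn, fn)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Precision, recall, accuracy, DSC and IoU from pixel counts.

    Zero-denominator conventions: a metric whose denominator is empty is
    reported as 1.0 (perfect agreement on absence) and flagged in
    ``degenerate``.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 1.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    accuracy = ratio(tp + tn, counts.total, "accuracy")
    dsc = ratio(2 * tp, 2 * tp + fp + fn, "dsc")
    iou = ratio(tp, tp + fp + fn, "iou")
    return MetricsReport(precision, recall, accuracy, dsc, iou, counts, degenerate)


def split_dataset(items: Sequence | int, fractions=(0.8, 0.1, 0.1),
                  seed: int = 0) -> tuple[list[int], list[int], list[int]]:
    """Seeded disjoint train/val/test index partition.

    Partition sizes are the rounded fractions of n (largest-remainder
    rounding); every partition must receive at least one item.
    """
    n = items if isinstance(items, int) else len(items)
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    rema = sorted(range(3), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in range(n - sum(sizes)):
        sizes[rema[i % 3]] += 1
    if min(sizes) < 1:
        raise ValueError(
            f"n={n} is too small for fractions {fractions}: "
            f"every partition needs at least one sample"
        )
    order = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return (sorted(order[:a].tolist()), sorted(order[a:b].tolist()),
            sorted(order[b:].tolist()))


def _stack(samples) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([np.asarray(s.image, dtype=np.float32)[None] for s in samples])
    masks = np.stack([np.asarray(s.nodule_mask, dtype=np.float32)[None] for s in samples])
    return imgs, masks


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_dsc: float
    val_iou: float


def train_model(model: Module, train_samples: Sequence, val_samples: Sequence,
                config: TrainConfig | None = None,
                verbose: bool = False) -> tuple[Module, list[EpochRecord]]:
    """Adam training with per-epoch validation and best-DSC weight retention.

    Fully seeded: batch order derives from ``config.seed``.  Aborts on a
    non-finite loss.  ``epochs=0`` returns the model unchanged with an empty
    history.
    """
    config = config or TrainConfig()
    if len(train_samples) == 0 or len(val_samples) == 0:
        raise ValueError("train and validation partitions must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    history: list[EpochRecord] = []
    best_dsc = -1.0
    best_state = None
    n = len(train_samples)
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = [train_samples[i] for i in order[start : start + config.batch_size]]
            imgs, masks = _stack(batch)
            opt.zero_grad()
            loss = bce_dice_loss(model(Tensor(imgs)), masks, config)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            losses.append(value)
        val_loss, val_dsc, val_iou = _validate(model, val_samples, config)
        rec = EpochRecord(epoch, float(np.mean(losses)), val_loss, val_dsc, val_iou)
        history.append(rec)
        if verbose:
            print(f"epoch {epoch}: train_loss={rec.train_loss:.4f} "
                  f"val_loss={rec.val_loss:.4f} val_dsc={rec.val_dsc:.4f}")
        if val_dsc > best_dsc:
            best_dsc = val_dsc
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def _validate(model: Module, samples: Sequence,
              config: TrainConfig) -> tuple[float, float, float]:
    """One forward pass over the validation set: loss plus mean DSC/IoU."""
    model.eval()
    imgs, masks = _stack(samples)
    pred = model(Tensor(imgs))
    loss = float(bce_dice_loss(pred, masks, config).data)
    dscs, ious = [], []
    for prob, mask in zip(pred.data[:, 0], masks[:, 0]):
        m = compute_metrics(confusion_counts(
            (prob > config.threshold).astype(np.uint8), mask.astype(np.uint8)))
        dscs.append(m.dsc)
        ious.append(m.iou)
    return loss, float(np.mean(dscs)), float(np.mean(ious))


def predict_mask(model: Module, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarized single-image prediction."""
    model.eval()
    prob = model(Tensor(np.asarray(image, dtype=np.float32)[None, None])).data[0, 0]
    return (prob > threshold).astype(np.uint8)


def evaluate_model(model: Module, samples: Sequence, threshold: float = 0.5,
                   aggregation: str = "mean") -> MetricsReport:
    """Per-image metrics averaged over the evaluation set.

    ``aggregation='mean'`` (default) averages per-image metrics;
    ``'pooled'`` sums pixel counts over all images first.
    """
    if len(samples) == 0:
        raise ValueError("evaluation set is empty")
    if aggregation not in ("mean", "pooled"):
        raise ValueError("aggregation must be 'mean' or 'pooled'")
    model.eval()
    per_image = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for s in samples:
        imgs, masks = _stack([s])
        prob = model(Tensor(imgs)).data[0, 0]
        pred = (prob > threshold).astype(np.uint8)
        counts = confusion_counts(pred, np.asarray(s.nodule_mask, dtype=np.uint8))
        per_image.append(compute_metrics(counts))
        pooled = ConfusionCounts(pooled.tp + counts.tp, pooled.fp + counts.fp,
                                 pooled.tn + counts.tn, pooled.fn + counts.fn)
    if aggregation == "pooled":
        report = compute_metrics(pooled)
    else:
        report = MetricsReport(
            precision=float(np.mean([m.precision for m in per_image])),
            recall=float(np.mean([m.recall for m in per_image])),
            accuracy=float(np.mean([m.accuracy for m in per_image])),
            dsc=float(np.mean([m.dsc for m in per_image])),
            iou=float(np.mean([m.iou for m in per_image])),
            counts=pooled,
        )
    report.per_image = per_image
    return report


def write_history(history: list[EpochRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "val_loss", "val_dsc", "val_iou"])
        for rec in history:
            writer.writerow([rec.epoch, rec.train_loss, rec.val_loss,
                             rec.val_dsc, rec.val_iou])
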