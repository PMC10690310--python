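"""Training protocol: learning-rate discovery, one-cycle fitting with early
stopping and best-checkpoint selection, 2D backbone pretraining, and
end-to-end 3D fine-tuning.

Defaults mirror the protocol used throughout: four volumes per batch,
early stopping after five epochs without validation-loss improvement, the
weights with the lowest validation loss retained, binary cross entropy for
classification and the L1 norm for regression, and a decoupled-weight-decay
adaptive-moment optimizer (betas 0.9/0.99, eps 1e-5, weight decay 0.01)
driven by a one-cycle schedule: cosine warmup from base_lr/25 to base_lr
over the first 25% of steps, cosine annealing to base_lr/1e4, with the
first-moment factor cycling 0.95 -> 0.85 -> 0.95 inversely.
"""

from __future__ import annotations

import copy
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .model import (SlivitModel, SlivitConfig, BackboneConfig,
                    build_backbone, build_pretrain_model)
from .preprocess import (standardize_volume, standardize_slice,
                         tile_volume, contrast_stretch)
from .volume_data import LabeledDataset


# ---------------------------------------------------------------------------
# Config and record types

@dataclass
class TrainConfig:
    batch_size: int = 4
    patience: int = 5
    max_epochs: int = 50
    loss: str = "bce_logits"  # bce_logits | l1 | cross_entropy
    base_lr: float | str = "auto"
    seed: int = 0
    betas: tuple = (0.9, 0.99)
    eps: float = 1e-5
    weight_decay: float = 0.01
    warmup_frac: float = 0.25
    div_start: float = 25.0
    div_final: float = 1e4
    momentum_range: tuple = (0.95, 0.85)

    def __post_init__(self):
        if self.batch_size < 1 or self.patience < 1:
            raise ValueError("batch_size and patience must be >= 1")


@dataclass
class TrainRecord:
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    best_val_loss: float = math.inf
    stopped_early: bool = False
    base_lr: float = 0.0
    checkpoint_path: str | None = None
    seconds: float = 0.0


# ---------------------------------------------------------------------------
# Schedules and losses

def one_cycle_lr(step: int, total_steps: int, base_lr: float,
                 warmup_frac: float = 0.25, div_start: float = 25.0,
                 div_final: float = 1e4) -> float:
    """Cosine warmup to base_lr over warmup_frac of steps, cosine anneal after."""
    w = max(1, int(round(warmup_frac * total_steps)))
    start, final = base_lr / div_start, base_lr / div_final
    if step <= w:
        return start + (base_lr - start) * 0.5 * (1 - math.cos(math.pi * step / w))
    t = (step - w) / max(1, total_steps - w)
    return final + (base_lr - final) * 0.5 * (1 + math.cos(math.pi * min(t, 1.0)))


def one_cycle_momentum(step: int, total_steps: int, warmup_frac: float = 0.25,
                       mom_range: tuple = (0.95, 0.85)) -> float:
    """First-moment factor annealing inversely to the learning rate."""
    hi, lo = mom_range
    w = max(1, int(round(warmup_frac * total_steps)))
    if step <= w:
        return hi + (lo - hi) * 0.5 * (1 - math.cos(math.pi * step / w))
    t = (step - w) / max(1, total_steps - w)
    return lo + (hi - lo) * 0.5 * (1 - math.cos(math.pi * min(t, 1.0)))


_LOSSES = {
    "bce_logits": nn.bce_with_logits,
    "l1": nn.l1_loss,
    "cross_entropy": nn.cross_entropy,
}


def _check_batch_shapes(xs):
    shapes = {x.shape for x in xs}
    if len(shapes) != 1:
        raise ValueError(f"volumes in one batch must share N and frame size; got {shapes}")


def _batches(xs, ys, batch_size, rng=None):
    order = np.arange(len(xs))
    if rng is not None:
        rng.shuffle(order)
    for i in range(0, len(order), batch_size):
        sel = order[i:i + batch_size]
        bx = [xs[j] for j in sel]
        _check_batch_shapes(bx)
        yield np.stack(bx), np.asarray([ys[j] for j in sel])


def _loss_on(model, xs, ys, loss_name, batch_size):
    fn = _LOSSES[loss_name]
    total, count = 0.0, 0
    with nn.no_grad():
        for bx, by in _batches(xs, ys, batch_size):
            out = model(bx)
            if loss_name != "cross_entropy":
                out = out.reshape(len(bx))
            total += float(fn(out, by).data) * len(bx)
            count += len(bx)
    return total / count


# ---------------------------------------------------------------------------
# Learning-rate finder

def find_learning_rate(model, xs, ys, config: TrainConfig, n_iters: int = 100,
                       lr_bounds: tuple = (1e-7, 10.0)) -> float:
    """Exponential lr sweep; suggest from the steepest descent of smoothed loss.

    The sweep runs ~n_iters minibatch steps from 1e-7 to 10, smoothing the
    loss exponentially (factor 0.98) and aborting once the smoothed loss
    exceeds four times its running minimum. The suggestion is the lr at the
    steepest negative slope of the smoothed curve, divided by 10 and clipped
    to [1e-6, 1e-1].
    """
    if len(xs) < 1:
        raise ValueError("empty training data")
    state = copy.deepcopy(model.state_dict())
    loss_fn = _LOSSES[config.loss]
    opt = nn.AdamW(model.parameters(), lr=lr_bounds[0], betas=config.betas,
                   eps=config.eps, weight_decay=config.weight_decay)
    lrs = np.geomspace(lr_bounds[0], lr_bounds[1], n_iters)
    rng = np.random.default_rng(config.seed)
    batch_iter = None
    smoothed, raw_min = [], math.inf
    avg, beta = 0.0, 0.98
    used_lrs = []
    for it, lr in enumerate(lrs):
        if batch_iter is None:
            batch_iter = _batches(xs, ys, config.batch_size,
                                  np.random.default_rng(rng.integers(2 ** 31)))
        try:
            bx, by = next(batch_iter)
        except StopIteration:
            batch_iter = _batches(xs, ys, config.batch_size,
                                  np.random.default_rng(rng.integers(2 ** 31)))
            bx, by = next(batch_iter)
        opt.lr = float(lr)
        opt.zero_grad()
        out = model(bx)
        if config.loss != "cross_entropy":
            out = out.reshape(len(bx))
        loss = loss_fn(out, by)
        lv = float(loss.data)
        if it == 0 and not math.isfinite(lv):
            model.load_state_dict(state)
            raise RuntimeError("non-finite loss at the first lr-finder step")
        if not math.isfinite(lv):
            break
        avg = beta * avg + (1 - beta) * lv
        debiased = avg / (1 - beta ** (it + 1))
        smoothed.append(debiased)
        used_lrs.append(float(lr))
        raw_min = min(raw_min, debiased)
        if debiased > 4.0 * raw_min:
            break
        loss.backward()
        opt.step()
    model.load_state_dict(state)
    if len(smoothed) < 3:
        return 1e-3
    sm = np.asarray(smoothed)
    loglr = np.log(np.asarray(used_lrs))
    # windowed slope is robust to batch noise; skip the burn-in where the
    # debiased running average is still settling
    d = max(1, min(8, len(sm) - 1))
    burn = min(10, len(sm) - d - 1)
    slopes = (sm[d:] - sm[:-d]) / (loglr[d:] - loglr[:-d])
    i = burn + int(np.argmin(slopes[burn:]))
    steepest = used_lrs[i + d // 2]
    return float(np.clip(steepest / 10.0, 1e-6, 1e-1))


# ---------------------------------------------------------------------------
# One-cycle training with early stopping

def train_one_cycle(model, train_xs, train_ys, val_xs, val_ys,
                    config: TrainConfig, checkpoint_path=None,
                    log_path=None, flip_augment: bool = False) -> TrainRecord:
    """Fit with the one-cycle policy; early-stop on validation loss.

    Training stops once the validation loss has failed to improve for
    ``config.patience`` consecutive epochs (or at max_epochs); the weights
    from the best-validation epoch are restored into ``model``.
    ``flip_augment`` applies a per-volume horizontal flip re-drawn each epoch.
    """
    if len(train_xs) == 0 or len(val_xs) == 0:
        raise ValueError("training and validation data must be non-empty")
    loss_fn = _LOSSES[config.loss]
    base_lr = config.base_lr
    if base_lr == "auto":
        base_lr = find_learning_rate(model, train_xs, train_ys, config)
    n_batches = math.ceil(len(train_xs) / config.batch_size)
    total_steps = config.max_epochs * n_batches
    opt = nn.AdamW(model.parameters(), lr=base_lr, betas=config.betas,
                   eps=config.eps, weight_decay=config.weight_decay)
    record = TrainRecord(base_lr=float(base_lr))
    best_state = None
    bad_epochs = 0
    step = 0
    t0 = time.time()
    log_rows = []
    for epoch in range(1, config.max_epochs + 1):
        rng = np.random.default_rng((config.seed * 100003 + epoch) % (2 ** 31))
        ep_loss, ep_n = 0.0, 0
        lr_peak = 0.0
        for bx, by in _batches(train_xs, train_ys, config.batch_size, rng):
            if flip_augment:
                flips = rng.random(len(bx)) < 0.5
                if flips.any():
                    bx = bx.copy()
                    bx[flips] = bx[flips][:, :, ::-1, :]
            step += 1
            opt.lr = one_cycle_lr(step, total_steps, base_lr, config.warmup_frac,
                                  config.div_start, config.div_final)
            opt.beta1 = one_cycle_momentum(step, total_steps, config.warmup_frac,
                                           config.momentum_range)
            lr_peak = max(lr_peak, opt.lr)
            opt.zero_grad()
            out = model(bx)
            if config.loss != "cross_entropy":
                out = out.reshape(len(bx))
            loss = loss_fn(out, by)
            if not math.isfinite(float(loss.data)):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(bx)
            ep_n += len(bx)
        train_loss = ep_loss / ep_n
        val_loss = _loss_on(model, val_xs, val_ys, config.loss, config.batch_size)
        record.train_losses.append(train_loss)
        record.val_losses.append(val_loss)
        log_rows.append((epoch, train_loss, val_loss, lr_peak, time.time() - t0))
        if val_loss < record.best_val_loss:
            record.best_val_loss = val_loss
            record.best_epoch = epoch
            best_state = copy.deepcopy(model.state_dict())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                record.stopped_early = True
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    record.seconds = time.time() - t0
    if checkpoint_path is not None:
        from .model import save_checkpoint
        cfg = getattr(model, "config", None)
        save_checkpoint(model, checkpoint_path,
                        cfg if isinstance(cfg, SlivitConfig) else None,
                        extra={"best_epoch": record.best_epoch,
                               "best_val_loss": record.best_val_loss})
        record.checkpoint_path = str(checkpoint_path)
    if log_path is not None:
        import csv
        with open(log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_loss", "lr_peak", "seconds"])
            writer.writerows(log_rows)
    return record


# ---------------------------------------------------------------------------
# 2D pretraining

def prepare_images_2d(images: np.ndarray, side: int, stretch: bool = True) -> list:
    """Grayscale images -> standardized (side, side, 3) slices."""
    out = []
    for img in images:
        f = contrast_stretch(img) if stretch else np.asarray(img, dtype=np.float32)
        out.append(standardize_slice(f, side=side))
    return out


def pretrain_2d(images: np.ndarray, labels: np.ndarray, config: TrainConfig,
                backbone_config: BackboneConfig | None = None,
                n_classes: int = 4, val_frac: float = 0.2, seed: int | None = None):
    """Train the backbone + 4-way head on labeled 2D images.

    Returns ``(backbone_weights, record, val_accuracy)``; the weight dict
    loads directly into :func:`build_backbone` with ``init='transferred'``.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < n_classes:
        raise ValueError(f"need {n_classes} distinct classes, "
                         f"got {len(np.unique(labels))}")
    bb_config = backbone_config or BackboneConfig()
    seed = config.seed if seed is None else seed
    backbone = build_backbone(bb_config, "random", seed=seed)
    clf = build_pretrain_model(backbone, n_classes=n_classes, seed=seed + 1)
    xs = prepare_images_2d(images, bb_config.input_side)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(xs))
    n_val = max(1, int(round(val_frac * len(xs))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    cfg = replace(config, loss="cross_entropy")
    record = train_one_cycle(clf,
                             [xs[i] for i in train_idx], labels[train_idx],
                             [xs[i] for i in val_idx], labels[val_idx], cfg)
    # validation accuracy with the restored best weights
    correct = 0
    with nn.no_grad():
        for bx, by in _batches([xs[i] for i in val_idx], labels[val_idx],
                               config.batch_size):
            pred = clf(bx).data.argmax(axis=1)
            correct += int((pred == by).sum())
    acc = correct / len(val_idx)
    return backbone.state_dict(), record, acc


# ---------------------------------------------------------------------------
# 3D fine-tuning

def materialize_volumes(dataset: LabeledDataset, ids, label_column: str,
                        side: int, stretch: bool = True) -> tuple:
    """Standardize and tile each volume once -> (list of arrays, label array)."""
    xs, ys = [], []
    for vid in ids:
        vol = dataset.volumes[vid]
        xs.append(tile_volume(standardize_volume(vol, side=side, stretch=stretch)).pixels)
        ys.append(float(dataset.labels.table.loc[vid, label_column]))
    return xs, np.asarray(ys)


def finetune_3d(model: SlivitModel, dataset: LabeledDataset, task: str,
                label_column: str, init: str = "random",
                pretrained_backbone: dict | None = None,
                config: TrainConfig | None = None, stretch: bool = True,
                flip_augment: bool = True, checkpoint_path=None) -> TrainRecord:
    """End-to-end fine-tuning on a split LabeledDataset; all parameters train.

    ``task`` selects the loss: 'binary' -> binary cross entropy on the logit,
    'regression' -> L1. ``init='transferred'`` loads 2D-pretrained backbone
    weights before fitting.
    """
    if dataset.split is None:
        raise ValueError("dataset must carry a split")
    if task not in ("binary", "regression"):
        raise ValueError(f"unknown task {task!r}")
    config = config or TrainConfig(loss="bce_logits" if task == "binary" else "l1")
    if init == "transferred":
        if pretrained_backbone is None:
            raise ValueError("init='transferred' requires pretrained_backbone")
        model.backbone.load_state_dict(pretrained_backbone, strict=True)
    elif init != "random":
        raise ValueError(f"unknown init {init!r}")
    side = model.config.backbone.input_side
    tr_xs, tr_ys = materialize_volumes(dataset, dataset.split.train_ids,
                                       label_column, side, stretch)
    va_xs, va_ys = materialize_volumes(dataset, dataset.split.val_ids,
                                       label_column, side, stretch)
    return train_one_cycle(model, tr_xs, tr_ys, va_xs, va_ys, config,
                           checkpoint_path=checkpoint_path,
                           flip_augment=flip_augment)


def predict_volumes(model: SlivitModel, dataset: LabeledDataset, ids,
                    label_column: str, task: str, stretch: bool = True,
                    batch_size: int = 8) -> tuple:
    """Score volumes -> (y_true, y_score); sigmoid applied for binary tasks."""
    side = model.config.backbone.input_side
    xs, ys = materialize_volumes(dataset, ids, label_column, side, stretch)
    scores = []
    with nn.no_grad():
        for i in range(0, len(xs), batch_size):
            bx = xs[i:i + batch_size]
            _check_batch_shapes(bx)
            out = model(np.stack(bx)).data[:, 0]
            if task == "binary":
                out = 1.0 / (1.0 + np.exp(-out))
            scores.append(out)
    return ys, np.concatenate(scores)
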