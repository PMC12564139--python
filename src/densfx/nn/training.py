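"""Training loops, optimizer, scheduler, oversampling and augmentation for
the two networks.

Training follows the same recipe for both models: Adam with weight decay,
plateau-based learning-rate reduction, on-the-fly augmentation of the
training set (random scaling 0.8-1.2, per-axis mirror flips, random crops
retaining at least 90% of the dens), epoch-level oversampling (each fracture
case 10x, each non-fracture case 3x), and selection of the checkpoint with
the best validation metric.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from ..errors import AugmentationError, ParameterError, TrainingError, ValidationError
from ..io import Mask, Volume, pad_crop
from ..mask_analysis import dice_coefficient
from .losses import compute_class_weights, cross_entropy_loss, dice_ce_loss, softmax
from .models import M1Config, M1Net, UNet3d, UNetConfig

__all__ = [
    "TrainingConfig",
    "Adam",
    "ReduceLROnPlateau",
    "oversample_indices",
    "augment_case",
    "train_segmenter",
    "predict_mask",
    "train_m1",
    "predict_m1",
    "SegmenterModel",
    "M1Model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization schedule shared by both models.

    Clinical-scale defaults (120^3 inputs, 50 epochs) are retained as the
    stated values; desk-scale runs override ``input_shape``, ``max_epochs``
    and optionally ``max_steps``.
    """

    learning_rate: float = 0.01
    weight_decay: float = 1e-6
    max_epochs: int = 50
    batch_size: int = 4
    input_shape: tuple = (120, 120, 120)
    fracture_repeats: int = 10
    nonfracture_repeats: int = 3
    scheduler_patience: int = 10
    scheduler_cooldown: int = 10
    scheduler_factor: float = 0.1
    class_weights: tuple | None = None
    scale_range: tuple = (0.8, 1.2)
    min_dens_retention: float = 0.9
    crop_retries: int = 50
    max_steps: int | None = None
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if not self.learning_rate > 0 or not self.weight_decay > 0:
            raise ParameterError("learning_rate and weight_decay must be > 0")
        if self.fracture_repeats < 1 or self.nonfracture_repeats < 1:
            raise ParameterError("oversampling repeats must be >= 1")


class Adam:
    def __init__(self, params, lr: float, weight_decay: float = 0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement, then rest for ``cooldown`` epochs."""

    def __init__(self, optimizer: Adam, mode="max", factor=0.1, patience=10, cooldown=10):
        self.opt = optimizer
        self.sign = 1.0 if mode == "max" else -1.0
        self.factor = factor
        self.patience = patience
        self.cooldown = cooldown
        self.best = -np.inf
        self.bad_epochs = 0
        self.cooldown_left = 0

    def step(self, metric: float):
        value = self.sign * metric
        if value > self.best:
            self.best = value
            self.bad_epochs = 0
            return
        if self.cooldown_left > 0:
            self.cooldown_left -= 1
            return
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.opt.lr *= self.factor
            self.bad_epochs = 0
            self.cooldown_left = self.cooldown


def oversample_indices(labels, cfg: TrainingConfig, rng: np.random.Generator) -> np.ndarray:
    """One epoch's sample order: each fracture case exactly
    ``fracture_repeats`` times, each non-fracture case
    ``nonfracture_repeats`` times, shuffled."""
    idx = []
    for i, lab in enumerate(labels):
        idx.extend([i] * (cfg.fracture_repeats if lab else cfg.nonfracture_repeats))
    idx = np.array(idx, dtype=np.intp)
    rng.shuffle(idx)
    return idx


def _random_crop(arrs, target, dens, cfg, rng):
    """Random crop of aligned arrays keeping >= min_dens_retention of dens voxels."""
    shape = arrs[0].shape
    # pad first if any axis is smaller than the crop
    if any(s < t for s, t in zip(shape, target)):
        pads = [(max(0, (t - s + 1) // 2), max(0, t - s - (t - s + 1) // 2)) for s, t in zip(shape, target)]
        arrs = [np.pad(a, pads) for a in arrs]
        dens = np.pad(dens, pads)
        shape = arrs[0].shape
    total = dens.sum()
    # propose origins whose window overlaps the dens bounding box (plus a
    # 2-voxel context margin); the retention test below is what enforces
    # the >= 90% constraint
    if total > 0:
        idx = np.argwhere(dens)
        ranges = []
        for ax, (s, t) in enumerate(zip(shape, target)):
            lo = max(0, int(idx[:, ax].max()) - t + 1 - 2)
            hi = min(s - t, int(idx[:, ax].min()) + 2)
            ranges.append((lo, hi) if lo <= hi else (0, s - t))
    else:
        ranges = [(0, s - t) for s, t in zip(shape, target)]
    for _ in range(cfg.crop_retries):
        start = [int(rng.integers(lo, hi + 1)) for lo, hi in ranges]
        sl = tuple(slice(st, st + t) for st, t in zip(start, target))
        if total == 0 or dens[sl].sum() >= cfg.min_dens_retention * total:
            return [a[sl] for a in arrs], dens[sl]
    raise AugmentationError(
        f"no crop of size {tuple(target)} retains >= {cfg.min_dens_retention:.0%} "
        "of the dens after the configured retries"
    )


def augment_case(vol: np.ndarray, dens: np.ndarray, frac: np.ndarray | None,
                 cfg: TrainingConfig, rng: np.random.Generator):
    """Random scaling, mirror flips and a dens-retaining random crop.

    Identical geometric transforms are applied to the volume and both masks;
    the draw order is fixed so a seeded generator reproduces the output.
    """
    s = float(rng.uniform(*cfg.scale_range))
    vol = ndimage.zoom(vol, s, order=1, mode="nearest")
    dens = ndimage.zoom(dens.astype(np.uint8), s, order=0, mode="nearest")
    frac = None if frac is None else ndimage.zoom(frac.astype(np.uint8), s, order=0, mode="nearest")
    for ax in range(3):
        if rng.random() < 0.5:
            vol = np.flip(vol, axis=ax)
            dens = np.flip(dens, axis=ax)
            frac = None if frac is None else np.flip(frac, axis=ax)
    arrs = [vol] if frac is None else [vol, frac]
    arrs, dens = _random_crop(arrs, cfg.input_shape, dens, cfg, rng)
    vol = np.ascontiguousarray(arrs[0])
    frac = None if frac is None else np.ascontiguousarray(arrs[1])
    return vol, np.ascontiguousarray(dens), frac


def _center_crop(vol: np.ndarray, dens: np.ndarray | None, shape):
    v = Volume(vol)
    center = None
    if dens is not None and dens.any():
        center = tuple(c for c in np.argwhere(dens).mean(axis=0))
    vc = pad_crop(v, shape, center)
    dc = None
    if dens is not None:
        dc = pad_crop(Mask(dens), shape, center).data
    return vc.data, dc


@dataclass
class SegmenterModel:
    net: UNet3d
    cfg: TrainingConfig
    net_cfg: UNetConfig
    best_val_dice: float
    val_dice_history: list
    train_loss_history: list


@dataclass
class M1Model:
    net: M1Net
    cfg: TrainingConfig
    net_cfg: M1Config
    best_val_metric: float
    val_metric_history: list
    train_loss_history: list


def _epoch_batches(items, cfg, labels, rng):
    order = oversample_indices(labels, cfg, rng)
    for i in range(0, len(order), cfg.batch_size):
        yield order[i : i + cfg.batch_size]


def train_segmenter(train_cases, val_cases, cfg: TrainingConfig,
                    net_cfg: UNetConfig | None = None) -> SegmenterModel:
    """Train the segmentation network; returns the checkpoint with the
    highest validation Dice.

    ``train_cases``/``val_cases`` are sequences of (volume_array, dens_mask
    array, label) triples already preprocessed (windowed, z-scored).
    """
    if not train_cases or not val_cases:
        raise ValidationError("need at least one training and one validation case")
    net_cfg = net_cfg or UNetConfig()
    net = UNet3d(net_cfg, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), cfg.learning_rate, cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, "max", cfg.scheduler_factor, cfg.scheduler_patience, cfg.scheduler_cooldown)
    labels = [bool(lab) for _, _, lab in train_cases]
    cw = cfg.class_weights
    best = (-np.inf, None)
    val_hist, loss_hist = [], []
    steps = 0
    done = False
    for epoch in range(cfg.max_epochs):
        epoch_losses = []
        for batch in _epoch_batches(train_cases, cfg, labels, rng):
            xs, ts = [], []
            for i in batch:
                vol, dens, _ = train_cases[i]
                if cfg.augment:
                    v, d, _ = augment_case(vol, dens, None, cfg, rng)
                else:
                    v, d = _center_crop(vol, dens, cfg.input_shape)
                xs.append(v)
                ts.append(d)
            x = np.stack(xs)
            t = np.stack(ts)
            logits = net.forward(x, training=True)
            loss = dice_ce_loss(logits, t, net_cfg.dice_weight, net_cfg.ce_weight, cw)
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                done = True
                break
        loss_hist.append(float(np.mean(epoch_losses)))
        val = _mean_val_dice(net, val_cases, cfg)
        val_hist.append(val)
        if val >= best[0]:
            best = (val, net.named_state())
        sched.step(val)
        if done:
            break
    net.load_state(best[1])
    return SegmenterModel(net, cfg, net_cfg, best[0], val_hist, loss_hist)


def _mean_val_dice(net: UNet3d, cases, cfg: TrainingConfig) -> float:
    scores = []
    for vol, dens, _ in cases:
        v, d = _center_crop(vol, dens, cfg.input_shape)
        pred = _raw_predict(net, v)
        scores.append(dice_coefficient(Mask(pred), Mask(d)))
    return float(np.mean(scores))


def _raw_predict(net: UNet3d, vol: np.ndarray) -> np.ndarray:
    logits = net.forward(vol[None], training=False)
    return (logits.data.argmax(axis=1)[0]).astype(np.uint8)


def predict_mask(model: SegmenterModel, vol: Volume) -> Mask:
    """Segment a preprocessed volume; keeps the largest connected component.
    The network runs on a centered crop of ``input_shape`` and the result is
    pasted back into the full grid."""
    shape = vol.data.shape
    target = model.cfg.input_shape
    vc = pad_crop(vol, target) if shape != tuple(target) else vol
    pred = _raw_predict(model.net, vc.data)
    if pred.any():
        lab, nlab = ndimage.label(pred)
        if nlab > 1:
            sizes = ndimage.sum_labels(pred, lab, index=np.arange(1, nlab + 1))
            pred = (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    if shape != tuple(target):
        # paste back: pad_crop of the prediction grid with the inverse window
        full = np.zeros(shape, dtype=np.uint8)
        in_sl, out_sl = _inverse_window(shape, target)
        full[out_sl] = pred[in_sl]
        return Mask(full, vol.spacing, vol.origin)
    return Mask(pred, vol.spacing, vol.origin)


def _inverse_window(shape, target):
    in_sl, out_sl = [], []
    for s, t in zip(shape, target):
        if t <= s:
            start = min(max(s // 2 - t // 2, 0), s - t)
            in_sl.append(slice(0, t))
            out_sl.append(slice(start, start + t))
        else:
            ostart = min(max(t // 2 - s // 2, 0), t - s)
            in_sl.append(slice(ostart, ostart + s))
            out_sl.append(slice(0, s))
    return tuple(in_sl), tuple(out_sl)


def train_m1(train_cases, val_cases, cfg: TrainingConfig,
             net_cfg: M1Config | None = None) -> M1Model:
    """Train the direct classifier; returns the checkpoint with the best
    validation accuracy. Cases are (volume_array, dens_mask_array, label)."""
    if not train_cases or not val_cases:
        raise ValidationError("need at least one training and one validation case")
    labels = [bool(lab) for _, _, lab in train_cases]
    if len(set(labels)) < 2:
        raise ValidationError("training set contains a single class")
    net_cfg = net_cfg or M1Config()
    net = M1Net(net_cfg, cfg.input_shape, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    drop_rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(net.parameters(), cfg.learning_rate, cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, "max", cfg.scheduler_factor, cfg.scheduler_patience, cfg.scheduler_cooldown)
    if cfg.class_weights is None:
        # weight by the class mix the network actually sees per epoch: the
        # oversampling schedule already rebalances, so the residual weights
        # are computed on the oversampled (effective) counts, not the raw
        # prevalence, to avoid correcting the imbalance twice
        counts = (
            labels.count(False) * cfg.nonfracture_repeats,
            labels.count(True) * cfg.fracture_repeats,
        )
        cw = compute_class_weights(counts)
    else:
        cw = np.asarray(cfg.class_weights)
    best = (-np.inf, None)
    val_hist, loss_hist = [], []
    steps = 0
    done = False
    for epoch in range(cfg.max_epochs):
        epoch_losses = []
        for batch in _epoch_batches(train_cases, cfg, labels, rng):
            xs, ys = [], []
            for i in batch:
                vol, dens, lab = train_cases[i]
                if cfg.augment:
                    v, _, _ = augment_case(vol, dens, None, cfg, rng)
                else:
                    v, _ = _center_crop(vol, dens, cfg.input_shape)
                xs.append(v)
                ys.append(int(lab))
            logits = net.forward(np.stack(xs), training=True, rng=drop_rng)
            loss = cross_entropy_loss(logits, np.array(ys), cw)
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                done = True
                break
        loss_hist.append(float(np.mean(epoch_losses)))
        val = _m1_val_accuracy(net, val_cases, cfg)
        val_hist.append(val)
        if val >= best[0]:
            best = (val, net.named_state())
        sched.step(val)
        if done:
            break
    net.load_state(best[1])
    return M1Model(net, cfg, net_cfg, best[0], val_hist, loss_hist)


def _m1_val_accuracy(net: M1Net, cases, cfg: TrainingConfig) -> float:
    correct = 0
    for vol, dens, lab in cases:
        p = _m1_probs(net, vol, dens, cfg)
        correct += int((p[1] >= 0.5) == bool(lab))
    return correct / len(cases)


def _m1_probs(net: M1Net, vol: np.ndarray, dens: np.ndarray | None, cfg: TrainingConfig) -> np.ndarray:
    v, _ = _center_crop(vol, dens, cfg.input_shape)
    logits = net.forward(v[None], training=False)
    return softmax(logits.data)[0]


def predict_m1(model: M1Model, cases) -> np.ndarray:
    """Per-case (p_no_fracture, p_fracture), rows summing to 1."""
    out = []
    for vol, dens, _ in cases:
        out.append(_m1_probs(model.net, vol, dens, model.cfg))
    return np.stack(out)


def save_checkpoint(model, path) -> None:
    """Write parameters (npz) with a JSON config sidecar."""
    state = model.net.named_state()
    np.savez_compressed(str(path), **state)
    sidecar = {
        "training_config": asdict(model.cfg),
        "network_config": asdict(model.net_cfg),
        "kind": type(model).__name__,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=list)


def load_checkpoint(path, model) -> None:
    """Load parameters saved by :func:`save_checkpoint` into ``model.net``."""
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
        model.net.load_state({k: data[k] for k in data.files})
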