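"""Training protocol: grouped stratified split, class-balanced batches,
Adam with plateau learning-rate decay, and early stopping.

The split is stratified by class *and grouped by source recording*, so a
segment and its time-reversed twin always land in the same fold — a leakage
guard for the time-reverse augmentation.  Batches are class-balanced: the
majority class is drawn without replacement (each sample seen once per
epoch) while the minority class is resampled with replacement, so every
batch's class counts differ by at most one (9/8 at the default batch size
of 17) and the optimizer sees a 0.5 class prior regardless of corpus
imbalance.

Optimization is Adam on the softmax cross-entropy, starting at 1e-3; when
the validation loss plateaus the rate is halved, never below 1e-4; training
stops after 10 epochs without validation improvement and the best epoch's
weights are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, StratificationError
from .model import DualPathModel
from .preprocess import SegmentSet


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the study protocol)."""

    epochs: int = 50
    batch_size: int = 17
    lr_init: float = 1e-3
    lr_min: float = 1e-4
    lr_decay_factor: float = 0.5
    patience_early_stop: int = 10
    patience_lr: int = 5
    val_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ParameterError("val_fraction must be in (0, 1)")
        if self.lr_min > self.lr_init:
            raise ParameterError("lr_min must be <= lr_init")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ParameterError("lr_decay_factor must be in (0, 1)")
        if min(self.patience_early_stop, self.patience_lr) < 1:
            raise ParameterError("patience values must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch traces plus the stopping bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def stratified_split(segments: SegmentSet, val_fraction: float = 0.30,
                     seed: int = 0) -> tuple[SegmentSet, SegmentSet]:
    """Split segments into train/validation folds, stratified and grouped.

    Stratification is at the source-recording level per class; all segments
    of one recording (original + reversed) stay in the same fold.  Per-class
    recording counts in the validation fold equal ``round(n * val_fraction)``
    (within +-1 of the exact fraction).
    """
    y = segments.y
    if len(set(y.tolist())) < 2:
        raise StratificationError("both classes must be present to stratify")
    rng = np.random.default_rng(seed)
    # group ids in first-appearance order, with each group's class
    groups: dict[str, int] = {}
    for src, cls in zip(segments.sources, y):
        groups.setdefault(src, int(cls))
    val_groups: set[str] = set()
    for cls in (0, 1):
        names = [g for g, c in groups.items() if c == cls]
        names = [names[i] for i in rng.permutation(len(names))]
        n_val = int(round(len(names) * val_fraction))
        val_groups.update(names[:n_val])
    idx = np.arange(len(segments))
    val_mask = np.array([s in val_groups for s in segments.sources])
    return segments.subset(idx[~val_mask]), segments.subset(idx[val_mask])


def balanced_batches(train: SegmentSet, batch_size: int = 17, seed: int = 0):
    """Yield ``(X, y)`` class-balanced batches for one epoch.

    Per batch the two class counts differ by at most 1 (which class gets
    the odd sample alternates).  The majority class is chunked from a fresh
    shuffle so each of its samples appears at least once per epoch; the
    minority class is resampled with replacement.
    """
    y = train.y
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise StratificationError("balanced batches need both classes non-empty")
    rng = np.random.default_rng(seed)
    major, minor = (pos, neg) if len(pos) >= len(neg) else (neg, pos)
    half_hi = (batch_size + 1) // 2
    half_lo = batch_size // 2
    major = major[rng.permutation(len(major))]
    n_batches = int(np.ceil(len(major) / half_hi))
    for bi in range(n_batches):
        chunk = major[bi * half_hi:(bi + 1) * half_hi]
        n_major = len(chunk)
        if n_major < half_hi:  # pad the last chunk back to full batch size
            extra = rng.choice(major, size=half_hi - n_major, replace=True)
            chunk = np.concatenate([chunk, extra])
            n_major = half_hi
        odd_to_major = bool(bi % 2 == 0)
        take_major = half_hi if odd_to_major else half_lo
        take_minor = batch_size - take_major
        sel_major = chunk[:take_major]
        sel_minor = rng.choice(minor, size=take_minor, replace=True)
        idx = np.concatenate([sel_major, sel_minor])
        idx = idx[rng.permutation(len(idx))]
        yield train.data[idx], y[idx]


class Adam:
    """Adam optimizer over a model's parameter tensors."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def dataset_loss(model: DualPathModel, segs: SegmentSet,
                 batch: int = 32) -> tuple[float, float]:
    """Mean cross-entropy and accuracy of a model over a whole segment set."""
    y = segs.y
    total, correct = 0.0, 0
    for i in range(0, len(segs), batch):
        xb = np.ascontiguousarray(
            segs.data[i:i + batch].transpose(0, 2, 1), dtype=model.dtype)
        yb = y[i:i + batch]
        loss, probs = model.loss(xb, yb, train=False)
        total += float(loss.data) * len(yb)
        correct += int((probs.argmax(axis=1) == yb).sum())
    return total / len(segs), correct / len(segs)


def train(model: DualPathModel, train_segs: SegmentSet, val_segs: SegmentSet,
          cfg: TrainConfig | None = None,
          stop_callback=None) -> tuple[DualPathModel, TrainHistory]:
    """Fit a model with the balanced-batch protocol.

    Returns the model restored to its best-validation-loss epoch, plus the
    history.  ``stop_callback(history) -> bool`` is polled after each epoch
    (used by scaled-down experiments to stop once a criterion is met).
    """
    cfg = cfg or TrainConfig()
    if train_segs.data.shape[1:] != (model.cfg.n_input_channels,
                                     model.cfg.input_len):
        raise ParameterError(
            f"segment shape {train_segs.data.shape[1:]} does not match model "
            f"input ({model.cfg.n_input_channels} channels x "
            f"{model.cfg.input_len} samples)")

    def to_model_axes(x):
        # SegmentSet stores (n, channels, samples); the net wants (n, time, ch)
        return np.ascontiguousarray(x.transpose(0, 2, 1), dtype=model.dtype)

    opt = Adam(model.parameters())
    hist = TrainHistory()
    lr = cfg.lr_init
    best_loss = np.inf
    best_weights = model.get_weights()
    since_best = 0
    since_lr = 0

    for epoch in range(1, cfg.epochs + 1):
        ep_losses, ep_correct, ep_n = [], 0, 0
        for xb, yb in balanced_batches(train_segs, cfg.batch_size,
                                       seed=cfg.seed + epoch):
            opt.zero_grad()
            loss, probs = model.loss(to_model_axes(xb), yb, train=True)
            loss.backward()
            opt.step(lr)
            ep_losses.append(float(loss.data) * len(yb))
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            ep_n += len(yb)
        vl, va = dataset_loss(model, val_segs)
        hist.train_loss.append(sum(ep_losses) / ep_n)
        hist.train_acc.append(ep_correct / ep_n)
        hist.val_loss.append(vl)
        hist.val_acc.append(va)
        hist.lr.append(lr)
        hist.stopped_epoch = epoch

        if vl < best_loss - 1e-12:
            best_loss = vl
            best_weights = model.get_weights()
            hist.best_epoch = epoch
            since_best = 0
            since_lr = 0
        else:
            since_best += 1
            since_lr += 1
        if stop_callback is not None and stop_callback(hist):
            break
        if since_best >= cfg.patience_early_stop:
            break
        if since_lr >= cfg.patience_lr and lr > cfg.lr_min:
            lr = max(lr * cfg.lr_decay_factor, cfg.lr_min)
            since_lr = 0

    model.set_weights(best_weights)
    return model, hist
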