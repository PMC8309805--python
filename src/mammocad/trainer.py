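"""Training orchestration: splits, learning-rate schedule, training loop.

The default hyperparameters follow the study configuration: batch size 32,
AdaGrad at learning rate 0.001 decayed by a factor of 0.1 every 5 epochs,
dropout 0.5, 20 epochs, sparse categorical cross-entropy with
inverse-frequency class weighting against class imbalance, random seed 42,
and a stratified 60/20/20 train/validation/test split (5-fold
cross-validation is available as an alternative protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold, train_test_split

from .netcore import NetworkSpec
from .nn import AdaGrad, Model, build_model, softmax, sparse_ce_loss

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "OnlineAugment",
    "TrainingDiverged",
    "make_splits",
    "make_folds",
    "lr_schedule",
    "class_weights",
    "train_model",
]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries the epoch index."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run."""

    batch_size: int = 32
    learning_rate: float = 0.001
    dropout: float = 0.5
    epochs: int = 20
    optimizer: str = "adagrad"
    target_size: Tuple[int, int] = (320, 240)  # (width, height)
    random_seed: int = 42
    loss: str = "sparse_categorical_crossentropy"
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 5
    use_class_weights: bool = True
    # provenance string of the published configuration table; the effective
    # weighting is inverse-frequency normalized to mean 1 (see class_weights)
    class_weight_range: Tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.lr_decay_every) <= 0:
            raise ValueError("batch_size, epochs and lr_decay_every must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < self.lr_decay_every:
            raise ValueError("epochs must be at least lr_decay_every")


@dataclass(frozen=True)
class SplitPlan:
    """Stratified train/validation/test fractions plus the fold count."""

    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    n_folds: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        for f in (self.train_frac, self.val_frac, self.test_frac):
            if not (0.0 < f < 1.0):
                raise ValueError("fractions must be in (0, 1)")
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


def make_splits(labels: Sequence[int], plan: SplitPlan = SplitPlan()) -> Dict[str, np.ndarray]:
    """Assign each item to exactly one of train/val/test, stratified by label.

    Deterministic for a given (labels, plan). Raises if any partition ends
    up missing a class entirely.
    """
    y = np.asarray(labels)
    idx = np.arange(len(y))
    if len(y) < plan.n_folds:
        raise ValueError("need at least n_folds labeled items")
    train_idx, rest_idx = train_test_split(
        idx, train_size=plan.train_frac, stratify=y, random_state=plan.seed
    )
    rel_val = plan.val_frac / (plan.val_frac + plan.test_frac)
    val_idx, test_idx = train_test_split(
        rest_idx, train_size=rel_val, stratify=y[rest_idx], random_state=plan.seed
    )
    parts = {
        "train": np.sort(train_idx),
        "val": np.sort(val_idx),
        "test": np.sort(test_idx),
    }
    classes = set(np.unique(y))
    for name, part in parts.items():
        if set(np.unique(y[part])) != classes:
            raise ValueError(f"class missing from the {name} partition")
    return parts


def make_folds(
    labels: Sequence[int], plan: SplitPlan = SplitPlan()
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions: each item is in exactly one test fold."""
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Step decay: lr = learning_rate * decay_factor ** floor(epoch / every)."""
    if not (0 <= epoch < cfg.epochs):
        raise ValueError(f"epoch must be in [0, {cfg.epochs})")
    return cfg.learning_rate * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


def class_weights(y: Sequence[int], n_classes: int = 2) -> np.ndarray:
    """Inverse-frequency class weights normalized to mean 1 over classes."""
    y = np.asarray(y)
    counts = np.bincount(y, minlength=n_classes).astype(float)
    if np.any(counts == 0):
        raise ValueError("every class must be present to weight the loss")
    w = counts.sum() / (n_classes * counts)
    return w / w.mean()


@dataclass(frozen=True)
class OnlineAugment:
    """On-the-fly batch augmentation: small random rotations, shifts, shears
    and flips applied to each training batch. Ranges are fractions of the
    image size (shift/shear) and degrees (rotation)."""

    rotation_deg: float = 20.0
    shift_frac: float = 0.1
    shear_frac: float = 0.1
    hflip: bool = True
    vflip: bool = True

    def apply(self, batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n, h, w, _ = batch.shape
        out = np.empty_like(batch)
        for i in range(n):
            ang = np.deg2rad(rng.uniform(-self.rotation_deg, self.rotation_deg))
            shear = rng.uniform(-self.shear_frac, self.shear_frac)
            dy = rng.uniform(-self.shift_frac, self.shift_frac) * h
            dx = rng.uniform(-self.shift_frac, self.shift_frac) * w
            cos, sin = np.cos(ang), np.sin(ang)
            lin = np.array([[cos, -sin], [sin + shear * cos, cos - shear * sin]])
            ctr = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
            offset = ctr - lin @ ctr + np.array([dy, dx])
            img = batch[i]
            if self.hflip and rng.random() < 0.5:
                img = img[:, ::-1]
            if self.vflip and rng.random() < 0.5:
                img = img[::-1]
            for ch in range(img.shape[2]):
                out[i, :, :, ch] = ndimage.affine_transform(
                    img[:, :, ch], lin, offset=offset, order=1, mode="constant"
                )
        return out


def _epoch_metrics(model: Model, x: np.ndarray, y: np.ndarray,
                   weights: Optional[np.ndarray]) -> Tuple[float, float]:
    logits = []
    for i in range(0, len(x), 64):
        logits.append(model.forward(x[i : i + 64], training=False))
    logits = np.concatenate(logits)
    sw = weights[y] if weights is not None else None
    loss, _ = sparse_ce_loss(logits, y, sw)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def train_model(
    spec: NetworkSpec,
    data: Dict[str, np.ndarray],
    cfg: TrainConfig = TrainConfig(),
    online_augment: bool | OnlineAugment = False,
) -> Tuple[Model, List[Dict[str, float]]]:
    """Train a model on ``data`` and return it with its per-epoch history.

    ``data`` must hold ``x_train``/``y_train`` and optionally ``x_val``/
    ``y_val`` (``(N, H, W, C)`` images and integer labels). The history
    records epoch, learning rate, and train/val loss and accuracy. Raises
    :class:`TrainingDiverged` if the loss turns non-finite.
    """
    x_train = np.asarray(data["x_train"], dtype=np.float64)
    y_train = np.asarray(data["y_train"], dtype=np.int64)
    x_val = data.get("x_val")
    y_val = data.get("y_val")

    rng = np.random.default_rng(cfg.random_seed)
    model = build_model(spec, seed=cfg.random_seed)
    opt = AdaGrad(model)
    weights = class_weights(y_train) if cfg.use_class_weights else None
    aug = (
        online_augment
        if isinstance(online_augment, OnlineAugment)
        else (OnlineAugment() if online_augment else None)
    )

    history: List[Dict[str, float]] = []
    n = len(x_train)
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        losses, hits, seen = [], 0, 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            if aug is not None:
                xb = aug.apply(xb, rng)
            logits = model.forward(xb, training=True)
            sw = weights[yb] if weights is not None else None
            loss, dlogits = sparse_ce_loss(logits, yb, sw)
            if not np.isfinite(loss):
                raise TrainingDiverged(epoch)
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == yb).sum())
            seen += len(yb)
        entry = {
            "epoch": float(epoch),
            "lr": lr,
            "train_loss": float(np.mean(losses)),
            "train_acc": hits / seen,
        }
        if x_val is not None and y_val is not None:
            val_loss, val_acc = _epoch_metrics(
                model, np.asarray(x_val, float), np.asarray(y_val), weights
            )
            if not np.isfinite(val_loss):
                raise TrainingDiverged(epoch)
            entry["val_loss"] = val_loss
            entry["val_acc"] = val_acc
        history.append(entry)
    return model, history
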