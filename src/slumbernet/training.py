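"""Training protocol: stratified five-fold cross-validation and final fit.

Optimization follows the published recipe: Adam on categorical
cross-entropy, batch size 128, up to 50 passes over shuffled training
epochs, augmentation applied to the training side only, the best
weights checkpointed on the monitored (training) loss, and the learning
rate halved whenever that loss fails to improve for three consecutive
passes (floor 1e-8). Folds come from a stratified k-fold split so each
20% test fold preserves the global Wake/NREM/REM proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .augment import AugmentConfig, augment_batch
from .metrics import (
    categorical_cross_entropy,
    confusion_matrix,
    explained_variance,
    stage_metrics_row,
)
from .model import ModelConfig, build_model
from .nn import Adam, Network, cross_entropy
from .preprocess import EpochDataset

LR_REDUCTION_FACTOR = 0.5
LR_PLATEAU_PATIENCE = 3
LR_FLOOR = 1e-8

#: Table-style metric columns: accuracy/precision/recall/F1/kappa per stage.
FOLD_TABLE_COLUMNS = [
    f"{s}_{m}" for s in ("W", "N", "R")
    for m in ("accuracy", "precision", "recall", "f1", "kappa")
]


class PlateauScheduler:
    """Halve the learning rate when the monitored loss stalls.

    A reduction fires after exactly ``patience`` consecutive passes without
    improvement over the best loss seen; the rate never drops below
    ``floor``. Mirrors the reduce-on-plateau callback convention.
    """

    def __init__(self, initial_lr: float, factor: float = LR_REDUCTION_FACTOR,
                 patience: int = LR_PLATEAU_PATIENCE, floor: float = LR_FLOOR):
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.floor = floor
        self.best = np.inf
        self.wait = 0

    def step(self, loss: float) -> tuple[float, bool]:
        """Feed one epoch's monitored loss; returns (lr, improved)."""
        if loss < self.best:
            self.best = loss
            self.wait = 0
            return self.lr, True
        self.wait += 1
        if self.wait >= self.patience:
            self.lr = max(self.lr * self.factor, self.floor)
            self.wait = 0
        return self.lr, False


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray

    def class_proportions(self, stage_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(train, test) per-class fractions for diagnostics."""
        def frac(ix):
            return np.bincount(stage_idx[ix], minlength=3) / len(ix)
        return frac(self.train_indices), frac(self.test_indices)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1  # epoch index with the lowest monitored loss
    best_weights: dict = field(default_factory=dict)
    final_weights: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "learning_rate": self.learning_rate,
        })


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Disjoint, covering k-fold splits preserving class proportions.

    Each fold's test side is ~1/k of the data (an 80/20 partition at k=5)
    and per-class counts on both sides are within one sample of the
    proportional share.
    """
    labels = np.asarray(labels)
    y = labels.argmax(axis=1) if labels.ndim == 2 else labels
    counts = np.bincount(y, minlength=3)
    if np.any(counts[counts > 0] < k) or len(np.unique(y)) < 2:
        raise ValueError(f"every class needs at least k={k} members; got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        FoldSplit(fold_id=i + 1, train_indices=tr, test_indices=te)
        for i, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y))
    ]


def train_fold(model: Network, split: FoldSplit, data: EpochDataset,
               cfg: ModelConfig, aug: AugmentConfig | None = None) -> TrainHistory:
    """Train one fold; the test side is used for monitoring only, never updated on."""
    X = data.signals[..., None]  # (N, 256, 2, 1)
    Y = data.labels
    return _fit(model, X[split.train_indices], Y[split.train_indices],
                X[split.test_indices], Y[split.test_indices], cfg, aug)


def cross_validate(data: EpochDataset, cfg: ModelConfig,
                   aug: AugmentConfig | None = None,
                   k: int = 5, seed: int = 0) -> pd.DataFrame:
    """k-fold cross-validation; per-fold stage metrics plus mean and SEM rows."""
    from .metrics import fold_summary

    splits = stratified_kfold(data.labels, k=k, seed=seed)
    rows = []
    for split in splits:
        model = build_model(cfg.scaled(seed=cfg.seed + split.fold_id))
        hist = train_fold(model, split, data, cfg, aug)
        model.set_weights(hist.best_weights)
        probs = model.predict_proba(data.signals[split.test_indices][..., None],
                                    batch_size=cfg.batch_size)
        cm = confusion_matrix(data.stage_indices[split.test_indices],
                              probs.argmax(axis=1))
        rows.append(stage_metrics_row(cm))
    table = pd.DataFrame(rows, index=[s.fold_id for s in splits])[FOLD_TABLE_COLUMNS]
    return fold_summary(table)


def train_final(data: EpochDataset, cfg: ModelConfig,
                aug: AugmentConfig | None = None,
                monitor_fraction: float = 0.2) -> tuple[Network, TrainHistory]:
    """Train on the full dataset with an internal stratified monitor split.

    The final-epoch weights are the deliverable (training runs the full
    budget rather than early-stopping); the history still records the
    best-loss epoch.
    """
    y = data.stage_indices
    tr, va = train_test_split(np.arange(len(data)), test_size=monitor_fraction,
                              stratify=y, random_state=cfg.seed)
    model = build_model(cfg)
    X = data.signals[..., None]
    hist = _fit(model, X[tr], data.labels[tr], X[va], data.labels[va], cfg, aug)
    model.set_weights(hist.final_weights)
    return model, hist


def evaluate_model(model: Network, data: EpochDataset,
                   batch_size: int = 256) -> dict[str, float]:
    """Stage metrics plus overall accuracy/kappa, log loss and explained variance."""
    probs = model.predict_proba(data.signals[..., None], batch_size=batch_size)
    pred = probs.argmax(axis=1)
    true = data.stage_indices
    cm = confusion_matrix(true, pred)
    out = stage_metrics_row(cm)
    out["log_loss"] = categorical_cross_entropy(data.labels, probs)
    out["explained_variance"] = explained_variance(true, pred)
    return out


def _fit(model: Network, X_tr, Y_tr, X_va, Y_va,
         cfg: ModelConfig, aug: AugmentConfig | None) -> TrainHistory:
    params, grads = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed)
    aug_rng = np.random.default_rng(aug.seed) if aug is not None else None

    hist = TrainHistory()
    sched = PlateauScheduler(cfg.learning_rate)
    n = len(X_tr)
    for _ in range(cfg.num_epochs):
        order = shuffle_rng.permutation(n)
        losses, accs, weights = [], [], []
        for start in range(0, n, cfg.batch_size):
            ix = order[start:start + cfg.batch_size]
            xb, yb = X_tr[ix], Y_tr[ix]
            if aug is not None:
                xb2, _ = augment_batch(xb[..., 0], yb, aug, training=True, rng=aug_rng)
                xb = xb2[..., None]
            loss = model.loss_and_grads(xb, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at step {opt.t} "
                    f"(lr={opt.lr:g}, batch={len(ix)})")
            opt.step(grads)
            losses.append(loss)
            accs.append((model._probs.argmax(1) == yb.argmax(1)).mean())
            weights.append(len(ix))
        train_loss = float(np.average(losses, weights=weights))
        train_acc = float(np.average(accs, weights=weights))

        va_probs = model.predict_proba(X_va, batch_size=cfg.batch_size)
        val_loss = cross_entropy(va_probs, Y_va)
        val_acc = float((va_probs.argmax(1) == Y_va.argmax(1)).mean())

        hist.train_loss.append(train_loss)
        hist.train_accuracy.append(train_acc)
        hist.val_loss.append(val_loss)
        hist.val_accuracy.append(val_acc)
        hist.learning_rate.append(opt.lr)

        # checkpoint + plateau rule, both monitored on training loss
        opt.lr, improved = sched.step(train_loss)
        if improved:
            hist.best_epoch = len(hist.train_loss) - 1
            hist.best_weights = model.get_weights()
    hist.final_weights = model.get_weights()
    return hist
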