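"""Training protocol and evaluation for the segment classifier.

The protocol mirrors standard deep-learning practice for this task:
a stratified 60/20/20 train/validation/test split, Adam at learning rate
1e-3 minimizing binary cross-entropy for up to 150 epochs at batch size
512, checkpointing weights whenever validation loss improves, reducing the
learning rate on a validation-loss plateau (factor 0.5, patience 5,
floor 1e-5), and early stopping after 10 epochs without improvement. The
returned weights are the checkpointed best, not the final ones.

Evaluation reports accuracy, precision, recall, F1 and the confusion
matrix at a 0.5 threshold, and threshold-free ROC AUC over the score
ranking (positive class = prominent). A sweep harness re-segments,
re-featurizes and retrains over a grid of segment lengths and batch
sizes, emitting one result row per combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import nn
from .annotations import AnnotatedRecording
from .mfcc import MfccConfig, mfcc_batch
from .model import BowelSoundClassifier, ModelConfig
from .segmentation import SegmentationConfig, build_dataset

__all__ = [
    "TrainConfig",
    "MetricsHistory",
    "EvalReport",
    "EarlyStopping",
    "ReduceLROnPlateau",
    "split_indices",
    "fit_loop",
    "train",
    "evaluate",
    "report_from_scores",
    "sweep",
]


@dataclass(frozen=True)
class TrainConfig:
    split: tuple[float, float, float] = (0.60, 0.20, 0.20)
    max_epochs: int = 150
    batch_size: int = 512
    learning_rate: float = 0.001
    lr_factor: float = 0.5
    lr_patience: int = 5
    min_lr: float = 1e-5
    early_stop_patience: int = 10
    seed: int = 0
    split_unit: str = "segment"  # or "recording"
    class_weighting: bool = False  # off by default: plain BCE despite imbalance

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.early_stop_patience < 1 or self.lr_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.split_unit not in ("segment", "recording"):
            raise ValueError("split_unit must be 'segment' or 'recording'")


@dataclass
class MetricsHistory:
    """Per-epoch training record: loss, val_loss, accuracy, AUC,
    precision and recall, plus where training stopped and which epoch's
    weights were checkpointed (1-based)."""

    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    auc: list[float] = field(default_factory=list)
    precision: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def append(self, metrics: dict[str, float]) -> None:
        for key in ("loss", "val_loss", "accuracy", "auc", "precision", "recall"):
            getattr(self, key).append(float(metrics.get(key, np.nan)))

    def save(self, path: str | Path) -> Path:
        """Persist as a reloadable array archive."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, loss=self.loss, val_loss=self.val_loss,
                 accuracy=self.accuracy, auc=self.auc, precision=self.precision,
                 recall=self.recall,
                 stopped_epoch=self.stopped_epoch, best_epoch=self.best_epoch)
        return path

    @staticmethod
    def load(path: str | Path) -> "MetricsHistory":
        with np.load(path) as data:
            hist = MetricsHistory(
                loss=list(data["loss"]), val_loss=list(data["val_loss"]),
                accuracy=list(data["accuracy"]), auc=list(data["auc"]),
                precision=list(data["precision"]), recall=list(data["recall"]),
                stopped_epoch=int(data["stopped_epoch"]),
                best_epoch=int(data["best_epoch"]),
            )
        return hist


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float = 0.5

    @property
    def confusion(self) -> np.ndarray:
        """[[TN, FP], [FN, TP]] — rows true class, columns predicted."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "threshold": self.threshold,
        }


# ---------------------------------------------------------------------------
# splitting


def split_indices(
    labels: np.ndarray,
    cfg: TrainConfig,
    groups: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded stratified train/val/test index split.

    At segment granularity the split is stratified per label: validation
    and test sizes round to nearest within each class and train absorbs
    the remainder. At recording granularity (``groups`` given and
    ``split_unit == 'recording'``) whole recordings are assigned to one
    partition each, so no recording leaks across partitions.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)
    _, p_val, p_test = cfg.split

    if cfg.split_unit == "recording":
        if groups is None:
            raise ValueError("recording-level split requires group ids")
        unique = np.array(sorted(set(groups)), dtype=object)
        rng.shuffle(unique)
        n = len(unique)
        n_val = int(round(p_val * n))
        n_test = int(round(p_test * n))
        val_g = set(unique[:n_val])
        test_g = set(unique[n_val : n_val + n_test])
        groups = np.asarray(groups, dtype=object)
        val_idx = np.flatnonzero([g in val_g for g in groups])
        test_idx = np.flatnonzero([g in test_g for g in groups])
        train_idx = np.flatnonzero(
            [(g not in val_g) and (g not in test_g) for g in groups]
        )
    else:
        parts: dict[str, list[np.ndarray]] = {"train": [], "val": [], "test": []}
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            n_val = int(round(p_val * idx.size))
            n_test = int(round(p_test * idx.size))
            parts["val"].append(idx[:n_val])
            parts["test"].append(idx[n_val : n_val + n_test])
            parts["train"].append(idx[n_val + n_test :])
        train_idx = np.sort(np.concatenate(parts["train"]))
        val_idx = np.sort(np.concatenate(parts["val"]))
        test_idx = np.sort(np.concatenate(parts["test"]))

    for name, part in (("train", train_idx), ("val", val_idx), ("test", test_idx)):
        if cfg.split_unit == "segment" and len(np.unique(labels[part])) < len(
            np.unique(labels)
        ):
            raise ValueError(f"class missing from {name} partition")
    return train_idx, val_idx, test_idx


# ---------------------------------------------------------------------------
# callbacks and the fit loop


class EarlyStopping:
    """Stop when the monitored loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.wait = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record this epoch's value; return True if training should stop."""
        if value < self.best:
            self.best = value
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


class ReduceLROnPlateau:
    """Halve the learning rate after ``patience`` epochs without improvement."""

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-5):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.wait = 0

    def update(self, value: float) -> float:
        if value < self.best:
            self.best = value
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr = max(self.min_lr, self.lr * self.factor)
                self.wait = 0
        return self.lr


def fit_loop(
    run_epoch: Callable[[int], tuple[dict[str, float], dict[str, np.ndarray]]],
    max_epochs: int,
    patience: int,
) -> tuple[dict[str, np.ndarray] | None, MetricsHistory]:
    """Generic epoch loop with best-checkpointing and early stopping.

    ``run_epoch(epoch)`` (1-based) returns (metrics, weight snapshot); the
    metrics dict must contain ``val_loss``. Returns the snapshot from the
    best-validation-loss epoch and the full history. Factored out of
    ``train`` so the stopping protocol is testable against constructed
    loss sequences.
    """
    stopper = EarlyStopping(patience)
    history = MetricsHistory()
    best_weights: dict[str, np.ndarray] | None = None
    for epoch in range(1, max_epochs + 1):
        metrics, weights = run_epoch(epoch)
        history.append(metrics)
        stop = stopper.update(metrics["val_loss"], epoch)
        if stopper.best_epoch == epoch:  # this epoch improved: checkpoint
            best_weights = weights
        history.stopped_epoch = epoch
        if stop:
            break
    history.best_epoch = stopper.best_epoch
    return best_weights, history


# ---------------------------------------------------------------------------
# metrics


def report_from_scores(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Thresholded confusion metrics plus threshold-free AUC.

    Raises if the test set contains a single class (AUC undefined).
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(y_true).size < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    n = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(
        accuracy=(tp + tn) / n, precision=precision, recall=recall, f1=f1,
        auc=float(roc_auc_score(y_true, scores)),
        tp=tp, fp=fp, fn=fn, tn=tn, threshold=threshold,
    )


def evaluate(
    model: BowelSoundClassifier, x: np.ndarray, y: np.ndarray,
    threshold: float = 0.5, batch_size: int = 512,
) -> EvalReport:
    scores = predict_in_batches(model, x, batch_size)
    return report_from_scores(y, scores, threshold)


def predict_in_batches(
    model: BowelSoundClassifier, x: np.ndarray, batch_size: int = 512
) -> np.ndarray:
    out = [
        model.predict_proba(x[i : i + batch_size])
        for i in range(0, x.shape[0], batch_size)
    ]
    return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------------
# training


def _logits_in_batches(
    model: BowelSoundClassifier, x: np.ndarray, batch_size: int = 512
) -> np.ndarray:
    out = [
        model.forward_logits(x[i : i + batch_size], training=False)
        for i in range(0, x.shape[0], batch_size)
    ]
    return np.concatenate(out) if out else np.empty(0)


def _epoch_metrics(model: BowelSoundClassifier, x_val, y_val,
                   train_loss: float, batch_size: int) -> dict[str, float]:
    logits = _logits_in_batches(model, x_val, batch_size)
    scores = nn.sigmoid(logits)
    val_loss, _ = nn.bce_with_logits(logits, np.asarray(y_val, dtype=np.float64))
    pred = (scores >= 0.5).astype(int)
    y = np.asarray(y_val).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    auc = float(roc_auc_score(y, scores)) if np.unique(y).size == 2 else np.nan
    return {
        "loss": train_loss,
        "val_loss": val_loss,
        "accuracy": float(np.mean(pred == y)),
        "auc": auc,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
    }


def train(
    model: BowelSoundClassifier,
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    history_path: str | Path | None = None,
) -> MetricsHistory:
    """Fit ``model`` in place, restoring the best-validation-loss weights.

    Seeded batch shuffling makes repeated runs bit-identical. The history
    is returned and, if ``history_path`` is given, persisted as an array
    archive for later analysis without retraining.
    """
    x_train = np.asarray(x_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(lr=cfg.learning_rate)
    scheduler = ReduceLROnPlateau(cfg.learning_rate, cfg.lr_factor,
                                  cfg.lr_patience, cfg.min_lr)
    n = x_train.shape[0]

    def run_epoch(epoch: int) -> tuple[dict[str, float], dict[str, np.ndarray]]:
        order = rng.permutation(n)
        batch_losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss = model.loss_and_grad_step(x_train[idx], y_train[idx], training=True)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            optimizer.step(model.named_parameters(), model.named_grads())
            batch_losses.append(loss)
        metrics = _epoch_metrics(model, x_val, y_val,
                                 float(np.mean(batch_losses)), cfg.batch_size)
        optimizer.lr = scheduler.update(metrics["val_loss"])
        return metrics, model.get_weights()

    best_weights, history = fit_loop(run_epoch, cfg.max_epochs,
                                     cfg.early_stop_patience)
    if best_weights is not None:
        model.set_weights(best_weights)
    if history_path is not None:
        history.save(history_path)
    return history


# ---------------------------------------------------------------------------
# segment/batch-size sweep


def sweep(
    recordings: Sequence[AnnotatedRecording],
    segment_sizes_s: Sequence[float],
    batch_sizes: Sequence[int],
    model_factory: Callable[[tuple[int, int]], ModelConfig] | None = None,
    train_cfg: TrainConfig = TrainConfig(),
    mfcc_cfg: MfccConfig = MfccConfig(),
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Re-segment, re-featurize, retrain and evaluate over a size grid.

    The overlap scales with the segment length, keeping the 200/375
    overlap fraction of the default geometry. Returns one row per
    (segment size, batch size) with accuracy, AUC, precision, recall, F1.
    """
    rows = []
    for seg_s in segment_sizes_s:
        L = int(round(seg_s * 1000))
        overlap = int(round(L * 200 / 375))
        seg_cfg = SegmentationConfig(segment_length_ms=L, overlap_ms=overlap)
        ds = build_dataset(recordings, seg_cfg)
        x_raw, y = ds.to_arrays()
        sr = recordings[0].recording.sample_rate_hz
        feats = mfcc_batch(x_raw, sr, mfcc_cfg)
        input_shape = (feats.shape[1], feats.shape[2])
        tr, va, te = split_indices(y, train_cfg,
                                  groups=[s.recording_id for s in ds.segments])
        for batch in batch_sizes:
            cfg_b = replace(train_cfg, batch_size=int(batch))
            mcfg = (model_factory(input_shape) if model_factory
                    else ModelConfig(input_shape=input_shape, seed=cfg_b.seed))
            model = BowelSoundClassifier(mcfg)
            train(model, feats[tr], y[tr], feats[va], y[va], cfg_b)
            report = evaluate(model, feats[te], y[te])
            rows.append({
                "segment_size_s": seg_s, "batch_size": int(batch),
                "accuracy": report.accuracy, "auc": report.auc,
                "precision": report.precision, "recall": report.recall,
                "f1": report.f1,
            })
    table = pd.DataFrame(rows)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_csv, index=False)
    return table
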