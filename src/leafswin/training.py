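"""Training loop, stratified cross-validation and evaluation utilities.

Defaults follow the reference protocol: mini-batches of 8, the Adam optimizer
at learning rate 1e-4, 100 epochs, 10-fold stratified cross-validation.  Desk
experiments use far smaller models and datasets via the same code path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .augment import AugPolicy, augment_batch
from .autodiff import Tensor
from .metrics import ConfusionCounts, MetricsReport, compute_metrics
from .model import DualSwinTransformer, cross_entropy, save_checkpoint
from .nn import Adam

logger = logging.getLogger("leafswin")

__all__ = ["TrainConfig", "TrainResult", "kfold_split", "train", "evaluate", "export_features"]


@dataclass
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 1e-4
    epochs: int = 100
    folds: int = 10
    seed: int = 0
    weight_decay: float = 0.0
    betas: tuple[float, float] = (0.9, 0.999)
    augment: AugPolicy | None = None
    device: str = "cpu"
    checkpoint_path: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate < 0:
            raise ValueError("batch size, epochs and learning rate must be non-negative (batch >= 1)")
        if self.folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")
        if self.device != "cpu":
            raise ValueError("only CPU execution is supported")


@dataclass
class TrainResult:
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -1.0
    best_state: dict[str, np.ndarray] | None = None


def kfold_split(labels, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition of sample indices.

    Folds are disjoint, cover every index, and per-class counts across folds
    differ by at most one.  Classes with fewer samples than ``k`` trigger a
    warning and a best-effort stratification (some folds then lack that
    class).  Bit-identical for a fixed seed.
    """
    y = np.asarray(labels)
    if y.ndim != 1:
        raise ValueError("labels must be a 1-D array of class indices")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} samples < {k} folds; "
            "stratification is best-effort", UserWarning)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn re-warns about small classes
        return [(tr, va) for tr, va in skf.split(np.zeros_like(y), y)]


def _log_line(config: TrainConfig, text: str) -> None:
    logger.info(text)
    if config.log_path:
        with open(config.log_path, "a") as fh:
            fh.write(text + "\n")


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train(model: DualSwinTransformer, train_data, config: TrainConfig,
          val_data=None) -> TrainResult:
    """Optimize the model on ``(images, labels)`` arrays.

    ``train_data``/``val_data`` are tuples ``(X, y)`` with ``X`` of shape
    ``(n, H, W, 3)`` in [0, 1] and ``y`` integer class indices.  Per-epoch
    loss and accuracy are logged; the checkpoint with the best validation
    accuracy (ties: latest epoch) is retained in the result and optionally
    written to disk.  A non-finite loss aborts with a diagnostic.
    """
    X, y = train_data
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("training dataset is empty")
    if X.shape[0] != y.shape[0]:
        raise ValueError("images and labels disagree in length")
    rng = np.random.default_rng(config.seed)
    aug_rng = np.random.default_rng(config.seed + 1)
    optimizer = Adam(model.parameters(), lr=config.learning_rate,
                     betas=config.betas, weight_decay=config.weight_decay)
    result = TrainResult()
    for epoch in range(config.epochs):
        model.train()
        epoch_loss, n_seen, n_correct = 0.0, 0, 0
        for idx in _iter_batches(X.shape[0], config.batch_size, rng):
            xb, yb = X[idx], y[idx]
            if config.augment is not None:
                xb, yb = augment_batch(xb, yb, config.augment, aug_rng)
                xb = xb.astype(np.float32)
            logits = model(Tensor(xb))
            loss = cross_entropy(logits, yb)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss {loss.item()} at epoch {epoch}; aborting")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item() * len(idx)
            n_seen += len(idx)
            pred = logits.data.argmax(axis=-1)
            hard = yb if np.asarray(yb).ndim == 1 else np.asarray(yb).argmax(axis=-1)
            n_correct += int((pred == hard).sum())
        record = {"epoch": epoch, "split": "train",
                  "loss": epoch_loss / n_seen, "accuracy": n_correct / n_seen}
        _log_line(config, f"epoch={epoch} split=train loss={record['loss']:.4f} "
                          f"accuracy={record['accuracy']:.4f}")
        result.history.append(record)
        if val_data is not None:
            counts = evaluate(model, val_data, batch_size=config.batch_size)
            val_acc = float(np.trace(counts.matrix) / counts.total)
            result.history.append({"epoch": epoch, "split": "val", "accuracy": val_acc})
            _log_line(config, f"epoch={epoch} split=val accuracy={val_acc:.4f}")
        else:
            val_acc = record["accuracy"]
        if val_acc >= result.best_val_accuracy:  # ties resolved to latest epoch
            result.best_val_accuracy = val_acc
            result.best_epoch = epoch
            result.best_state = model.state_dict()
    if result.best_state is not None and config.checkpoint_path:
        snapshot = model.state_dict()
        model.load_state_dict(result.best_state)
        save_checkpoint(model, config.checkpoint_path,
                        metadata={"epoch": result.best_epoch,
                                  "val_accuracy": result.best_val_accuracy})
        model.load_state_dict(snapshot)
    return result


def evaluate(model: DualSwinTransformer, data, batch_size: int = 8) -> ConfusionCounts:
    """Argmax predictions accumulated into a confusion matrix.

    Ties in the probability vector resolve to the lowest class index
    (argmax convention).
    """
    X, y = data
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    n_classes = model.config.num_classes
    preds = []
    for start in range(0, X.shape[0], batch_size):
        pred = model.predict(X[start:start + batch_size])
        preds.append(pred.probabilities.argmax(axis=-1))
    return ConfusionCounts.from_predictions(y, np.concatenate(preds), n_classes)


def evaluate_metrics(model: DualSwinTransformer, data, batch_size: int = 8) -> MetricsReport:
    return compute_metrics(evaluate(model, data, batch_size=batch_size))


def export_features(model: DualSwinTransformer, data, path, batch_size: int = 8) -> Path:
    """Write fused pre-head features plus labels to CSV.

    One row per image: columns ``label, feat_0 .. feat_{2*8C-1}``.  Intended
    as input to a downstream embedding tool (e.g. t-SNE) for visualizing the
    learned feature space.
    """
    X, y = data
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    rows = []
    for start in range(0, X.shape[0], batch_size):
        rows.append(model.predict(X[start:start + batch_size]).features)
    feats = np.concatenate(rows, axis=0)
    path = Path(path)
    header = "label," + ",".join(f"feat_{i}" for i in range(feats.shape[1]))
    table = np.column_stack([y.astype(np.float64), feats])
    np.savetxt(path, table, delimiter=",", header=header, comments="")
    return path
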