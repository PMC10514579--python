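"""Model specification, training, cross-validation and evaluation.

The classifier maps F selected wavelengths to a D-dimensional feature
vector, reshapes it into a 3-channel square image and applies a
five-layer 3x3 CNN whose channel widths (16, 32, 64, 32, 16) are
scaled by a depth factor d in {0.75, 1.0, 1.25}; D in {192, 768, 3072}
gives 8x8x3, 16x16x3 and 32x32x3 images.  Training is SGD with
momentum under a polynomial learning-rate decay; evaluation reports
accuracy, macro one-vs-rest precision/recall and the confusion matrix,
plus analytic parameter and multiply-accumulate counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import SeedCNN
from .spectra import SpectraTable

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "Prediction",
    "EvalReport",
    "widths_for",
    "reshape_geometry",
    "build_model",
    "count_params",
    "count_macs",
    "cross_entropy",
    "lr_at",
    "stratified_split",
    "train",
    "predict",
    "evaluate",
    "fit_and_evaluate",
    "cross_validate",
]

_BASE_WIDTHS = (16, 32, 64, 32, 16)
_STRIDES = (1, 1, 2, 1, 1)


def widths_for(d: float) -> tuple[int, int, int, int, int]:
    """Channel widths of the five conv layers under depth factor d."""
    if d <= 0:
        raise ValueError("depth factor must be positive")
    return tuple(int(round(d * w)) for w in _BASE_WIDTHS)


def reshape_geometry(D: int) -> tuple[int, int, int]:
    """(channels, height, width) = (3, s, s) for D = 3*s^2, s even."""
    s2, rem = divmod(int(D), 3)
    s = int(round(s2**0.5))
    if rem or s * s != s2 or s % 2 or s <= 0:
        raise ValueError(f"map dimension {D} is not 3*s^2 with s a positive even integer")
    return (3, s, s)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of one classifier variant."""

    depth_factor: float = 1.0
    map_dim: int = 768
    n_input_bands: int = 56
    n_classes: int = 7

    def __post_init__(self) -> None:
        reshape_geometry(self.map_dim)  # validates
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_input_bands < 1:
            raise ValueError("need at least 1 input band")

    @property
    def widths(self) -> tuple[int, ...]:
        return widths_for(self.depth_factor)

    @property
    def strides(self) -> tuple[int, ...]:
        return _STRIDES

    @property
    def reshape(self) -> tuple[int, int, int]:
        return reshape_geometry(self.map_dim)

    @property
    def name(self) -> str:
        return f"d{self.depth_factor}_D{self.map_dim}"


def build_model(spec: ModelSpec, seed: int = 0) -> SeedCNN:
    """Instantiate the network for a spec with seeded initialization."""
    return SeedCNN(
        n_input_bands=spec.n_input_bands,
        map_dim=spec.map_dim,
        widths=spec.widths,
        n_classes=spec.n_classes,
        seed=seed,
    )


def _conv_spatial_sizes(spec: ModelSpec) -> list[int]:
    s = spec.reshape[1]
    out = []
    for stride in _STRIDES:
        s = (s - 1) // stride + 1
        out.append(s)
    return out


def count_params(spec: ModelSpec) -> int:
    """Trainable parameters (weights + biases), closed form."""
    total = spec.n_input_bands * spec.map_dim + spec.map_dim
    c_in = 3
    for c_out in spec.widths:
        total += 9 * c_in * c_out + c_out
        c_in = c_out
    total += spec.widths[-1] * spec.n_classes + spec.n_classes
    return total


def count_macs(spec: ModelSpec) -> int:
    """Multiply-accumulate operations for one forward pass."""
    total = spec.n_input_bands * spec.map_dim
    c_in = 3
    for c_out, side in zip(spec.widths, _conv_spatial_sizes(spec)):
        total += 9 * c_in * c_out * side * side
        c_in = c_out
    total += spec.widths[-1] * spec.n_classes
    return total


# ----------------------------------------------------------------------
# Loss, schedule, splits
# ----------------------------------------------------------------------

def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log probability of the true class.

    Zero probabilities at the true class are clamped to 1e-12 with a
    warning instead of producing infinities.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    p_true = probs[np.arange(len(labels)), labels]
    if np.any(p_true <= 0):
        warnings.warn("zero probability at true class clamped to 1e-12", stacklevel=2)
        p_true = np.clip(p_true, 1e-12, None)
    return float(-np.log(p_true).mean())


@dataclass(frozen=True)
class TrainConfig:
    """SGD training settings.

    ``epochs`` defaults to 300 (the package's desk-scale training
    length; the schedule end-point scales with it).  ``batch_size``
    None means full-batch gradient steps; the default of 64 gives
    enough gradient steps for SGD at lr0 = 0.01 to converge within a
    few hundred epochs.
    """

    lr0: float = 0.01
    epochs: int = 300
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int | None = 64
    seed: int = 0
    folds: int = 3
    schedule: str = "lambda_poly"

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.schedule != "lambda_poly":
            raise ValueError(f"unknown schedule {self.schedule!r}")


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Polynomial decay lr0 * (1 - epoch/epochs)^0.9."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside 0..{cfg.epochs - 1}")
    return cfg.lr0 * (1.0 - epoch / cfg.epochs) ** 0.9


def stratified_split(labels: np.ndarray, folds: int, seed: int = 0) -> np.ndarray:
    """Per-class shuffled round-robin fold assignment.

    Returns an integer fold id per sample; per-class fold sizes differ
    by at most one, so 7 x 105 samples under 3 folds give exactly 35
    per class per fold (245-sample test sides, 490-sample train sides).
    """
    labels = np.asarray(labels, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < folds:
            raise ValueError(f"class {cls} has {idx.size} samples < {folds} folds")
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % folds
    return assignment


# ----------------------------------------------------------------------
# Training and evaluation
# ----------------------------------------------------------------------

def train(
    model: SeedCNN, table: SpectraTable, cfg: TrainConfig = TrainConfig()
) -> list[float]:
    """SGD-train a model in place; returns the per-epoch loss history."""
    if table.n_bands != model.n_input_bands:
        raise ValueError(
            f"table has {table.n_bands} bands but model expects {model.n_input_bands}"
        )
    X = table.values.astype(np.float32)
    y = table.labels
    n = len(y)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        lr = lr_at(epoch, cfg)
        if cfg.batch_size is None or cfg.batch_size >= n:
            loss, grads = model.loss_and_grads(X, y)
            model.sgd_step(grads, lr, cfg.momentum, cfg.weight_decay)
        else:
            order = rng.permutation(n)
            losses, weights = [], []
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                loss_b, grads = model.loss_and_grads(X[idx], y[idx])
                model.sgd_step(grads, lr, cfg.momentum, cfg.weight_decay)
                losses.append(loss_b)
                weights.append(len(idx))
            loss = float(np.average(losses, weights=weights))
        history.append(loss)
    return history


@dataclass
class Prediction:
    """Per-sample class probabilities and argmax classes."""

    probs: np.ndarray
    predicted_class: np.ndarray


def predict(model: SeedCNN, table: SpectraTable) -> Prediction:
    probs = model.predict_proba(table.values)
    return Prediction(probs=probs, predicted_class=probs.argmax(axis=1))


def _confusion(y_true, y_pred, q) -> np.ndarray:
    conf = np.zeros((q, q), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    return conf


def _macro_precision_recall(conf: np.ndarray) -> tuple[float, float]:
    """Unweighted one-vs-rest precision/recall means.

    A class never predicted contributes precision 0 (with a warning);
    likewise recall for a class absent from the truth.
    """
    tp = np.diag(conf).astype(float)
    pred_tot = conf.sum(axis=0).astype(float)
    true_tot = conf.sum(axis=1).astype(float)
    if np.any(pred_tot == 0):
        warnings.warn("some classes never predicted; their precision counted as 0", stacklevel=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_tot > 0, tp / np.where(pred_tot > 0, pred_tot, 1), 0.0)
        rec = np.where(true_tot > 0, tp / np.where(true_tot > 0, true_tot, 1), 0.0)
    return float(prec.mean()), float(rec.mean())


@dataclass
class EvalReport:
    """Evaluation summary of one trained model on one train/test pair."""

    train_accuracy: float
    test_accuracy: float
    macro_precision: float
    macro_recall: float
    confusion: np.ndarray
    n_params: int
    n_macs: int
    model_name: str = ""
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "seed": self.seed,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "confusion": self.confusion.tolist(),
            "n_params": self.n_params,
            "n_macs": self.n_macs,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(model: SeedCNN, table: SpectraTable, q: int | None = None):
    """Accuracy, macro precision/recall and confusion on one table.

    Returns ``(accuracy, macro_precision, macro_recall, confusion)``
    with confusion rows = true class, columns = predicted class.
    """
    if table.n_samples == 0:
        raise ValueError("cannot evaluate on an empty table")
    q = q or model.n_classes
    pred = predict(model, table)
    conf = _confusion(table.labels, pred.predicted_class, q)
    acc = float(np.trace(conf) / conf.sum())
    prec, rec = _macro_precision_recall(conf)
    return acc, prec, rec, conf


def fit_and_evaluate(
    spec: ModelSpec,
    train_table: SpectraTable,
    test_table: SpectraTable,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[EvalReport, list[float], SeedCNN]:
    """Train one model on a train/test pair and summarize it."""
    model = build_model(spec, seed=cfg.seed)
    history = train(model, train_table, cfg)
    train_acc, _, _, _ = evaluate(model, train_table)
    test_acc, prec, rec, conf = evaluate(model, test_table)
    report = EvalReport(
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        macro_precision=prec,
        macro_recall=rec,
        confusion=conf,
        n_params=count_params(spec),
        n_macs=count_macs(spec),
        model_name=spec.name,
        seed=cfg.seed,
    )
    return report, history, model


def cross_validate(
    spec: ModelSpec, table: SpectraTable, cfg: TrainConfig = TrainConfig()
) -> tuple[list[EvalReport], list[list[float]]]:
    """Stratified k-fold CV: per-fold reports and loss histories.

    Fold f's test side is the samples assigned to fold f; each fold's
    model is trained from scratch with a fold-specific seed derived
    from ``cfg.seed``.
    """
    assignment = stratified_split(table.labels, cfg.folds, seed=cfg.seed)
    reports, histories = [], []
    for f in range(cfg.folds):
        test_idx = np.nonzero(assignment == f)[0]
        train_idx = np.nonzero(assignment != f)[0]
        fold_cfg = TrainConfig(
            lr0=cfg.lr0,
            epochs=cfg.epochs,
            momentum=cfg.momentum,
            weight_decay=cfg.weight_decay,
            batch_size=cfg.batch_size,
            seed=(cfg.seed * 1000 + f) % (2**31),
            folds=cfg.folds,
            schedule=cfg.schedule,
        )
        report, history, _ = fit_and_evaluate(
            spec, table.take_rows(train_idx), table.take_rows(test_idx), fold_cfg
        )
        reports.append(report)
        histories.append(history)
    return reports, histories
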