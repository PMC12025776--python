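"""Training loop, model selection and evaluation metrics.

Training minimises binary cross-entropy with Adam, stops early when the
validation loss has not strictly improved for ``patience`` consecutive
epochs (ties do not reset the counter), and always returns the weights
from the epoch with the lowest validation loss.  Model selection runs a
grid of configurations and ranks them by validation ROC-AUC, breaking
ties by fewer trainable parameters and then enumeration order.

Evaluation follows the standard confusion-matrix metrics (accuracy,
precision, recall, F1) at a decision threshold plus the area under the
empirical ROC curve, integrated with the trapezoidal rule over all
distinct score thresholds — which equals the probability that a random
positive outscores a random negative, counting ties as one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .architectures import ModelConfig, build_model, count_trainable_parameters
from .nn import Adam, Network, sigmoid
from .signal import LabeledDataset

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "Metrics",
    "EarlyStopping",
    "stratified_split",
    "stratified_split_indices",
    "bce_loss",
    "train",
    "grid_search",
    "confusion_counts",
    "compute_metrics",
    "roc_points",
    "roc_auc",
    "evaluate_scores",
]

#: probabilities are clipped to [EPS, 1 - EPS] before taking logs
BCE_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation and evaluation settings.

    Defaults follow the study design: at most 200 epochs with early
    stopping at patience 50, Adam, a 40/30/30 stratified split and a 0.5
    decision threshold.  Learning rate and batch size are ordinary Adam
    settings for data at this scale.
    """

    max_epochs: int = 200
    patience: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 1 <= self.patience <= self.max_epochs:
            raise ValueError("patience must be in [1, max_epochs]")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be > 0 and batch_size >= 1")
        fr = self.split_fractions
        if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"split_fractions must be 3 positive numbers summing to 1, got {fr}")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix tallies with class 1 (good) as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    roc_points: np.ndarray | None = field(default=None, repr=False, compare=False)

    def as_dict(self) -> dict[str, float]:
        out = {"accuracy": self.accuracy, "precision": self.precision,
               "recall": self.recall, "f1": self.f1}
        if self.auc is not None:
            out["auc"] = self.auc
        return out


class EarlyStopping:
    """Patience-based stopping on the validation loss.

    ``update`` returns True when the loss strictly improved.  ``stop``
    becomes True after ``patience`` consecutive epochs without strict
    improvement.  ``best_epoch`` is 1-based.
    """

    def __init__(self, patience: int) -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.epochs_without_improvement = 0

    def update(self, val_loss: float) -> bool:
        epoch = self.best_epoch + self.epochs_without_improvement + 1
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.epochs_without_improvement = 0
            return True
        self.epochs_without_improvement += 1
        return False

    @property
    def stop(self) -> bool:
        return self.epochs_without_improvement >= self.patience


def stratified_split_indices(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation/test index arrays.

    Per-class proportions in each subset match the global proportions to
    within one sample.  Deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be 3 positive numbers, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has only {counts.min()} member(s); "
            "every class needs at least one per subset"
        )
    idx = np.arange(labels.size)
    f_train, f_val, f_test = fractions
    train_idx, rest_idx = train_test_split(
        idx, train_size=f_train, stratify=labels, random_state=seed, shuffle=True
    )
    val_idx, test_idx = train_test_split(
        rest_idx,
        train_size=f_val / (f_val + f_test),
        stratify=labels[rest_idx],
        random_state=seed + 1,
        shuffle=True,
    )
    return np.sort(train_idx), np.sort(val_idx), np.sort(test_idx)


def stratified_split(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Stratified 3-way split of a labeled dataset (by binary label)."""
    tr, va, te = stratified_split_indices(dataset.binary_labels, fractions, seed)
    return dataset[tr], dataset[va], dataset[te]


def bce_loss(y_true: np.ndarray, p: np.ndarray) -> float:
    """Binary cross-entropy -(1/N) sum[y log p + (1-y) log(1-p)].

    Probabilities are clipped away from {0, 1} by ``BCE_EPS`` so the logs
    stay finite; in that clipped limit the loss is 0 iff predictions match
    the labels exactly.
    """
    y = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    if y.size == 0:
        raise ValueError("empty inputs")
    p = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _forward_loss(model: Network, x: np.ndarray, y: np.ndarray) -> float:
    logits = model.forward(x, train=False)
    p = sigmoid(logits[:, 0])
    return bce_loss(y, p)


def train(
    model: Network,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[Network, dict]:
    """Train ``model`` in place and return it with its best-epoch weights.

    ``train_set`` / ``val_set`` are ``(X, y)`` pairs with X of shape
    (n, input_length) and y binary.  The returned history maps
    ``train_loss`` and ``val_loss`` to per-epoch lists; ``best_epoch`` is
    the 1-based epoch whose weights the model carries on return.
    """
    x_train, y_train = np.asarray(train_set[0], dtype=np.float64), np.asarray(train_set[1])
    x_val, y_val = np.asarray(val_set[0], dtype=np.float64), np.asarray(val_set[1])
    if x_train.size == 0 or x_val.size == 0:
        raise ValueError("training and validation sets must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model, learning_rate=cfg.learning_rate)
    stopper = EarlyStopping(cfg.patience)
    history: dict = {"train_loss": [], "val_loss": []}
    best_state = model.state_dict()

    n = x_train.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, yb = x_train[batch], y_train[batch]
            logits = model.forward(xb, train=True)
            p = sigmoid(logits[:, 0])
            epoch_loss += bce_loss(yb, p) * len(batch)
            # d(BCE)/d(logit) for a sigmoid output
            dlogits = ((p - yb) / len(batch))[:, None]
            model.backward(dlogits)
            optimizer.step()
        history["train_loss"].append(epoch_loss / n)
        val_loss = _forward_loss(model, x_val, y_val)
        history["val_loss"].append(val_loss)
        if stopper.update(val_loss):
            best_state = model.state_dict()
        if stopper.stop:
            break

    model.load_state_dict(best_state)
    history["best_epoch"] = stopper.best_epoch
    history["best_val_loss"] = stopper.best_loss
    history["stopped_epoch"] = len(history["val_loss"])
    return model, history


def grid_search(
    space: list[ModelConfig],
    datasets: tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> tuple[ModelConfig, list[dict]]:
    """Train every configuration and pick the best by validation AUC.

    Returns the winning config and the full leaderboard (one dict per
    configuration with ``val_auc``, ``n_parameters``, ``history`` and, on
    failure, ``error``).  Failed configurations stay on the leaderboard but
    are excluded from the argmax.  Ties break by fewer parameters, then by
    enumeration order.
    """
    if not space:
        raise ValueError("empty search space")
    train_set, val_set = datasets
    leaderboard: list[dict] = []
    for order, model_cfg in enumerate(space):
        entry: dict = {"config": model_cfg, "order": order}
        try:
            rng = np.random.default_rng(cfg.seed)
            model = build_model(model_cfg, rng)
            entry["n_parameters"] = count_trainable_parameters(model)
            model, history = train(model, train_set, val_set, cfg)
            entry["val_auc"] = roc_auc(val_set[1], model.scores(val_set[0]))
            entry["history"] = history
        except Exception as exc:  # noqa: BLE001 - a failed config must not kill the run
            entry["error"] = str(exc)
            entry["val_auc"] = None
        leaderboard.append(entry)
    ranked = [e for e in leaderboard if e.get("val_auc") is not None]
    if not ranked:
        raise RuntimeError("every configuration failed to train")
    best = max(ranked, key=lambda e: (e["val_auc"], -e["n_parameters"], -e["order"]))
    return best["config"], leaderboard


def confusion_counts(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with prediction = 1 iff score >= threshold."""
    y = np.asarray(y_true)
    s = np.asarray(scores)
    if y.size == 0:
        raise ValueError("empty inputs")
    if y.shape != s.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs scores {s.shape}")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning 0", UserWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall and F1 from confusion counts.

    Ratios with a zero denominator return 0 with a warning.
    """
    if counts.total == 0:
        raise ValueError("no samples")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = _safe_ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _safe_ratio(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _safe_ratio(2.0 * precision * recall, precision + recall, "F1")
    return Metrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Empirical ROC curve as (FPR, TPR) rows, one per distinct threshold.

    Points run from (0, 0) to (1, 1) and are monotone non-decreasing in
    both coordinates; tied scores collapse into a single point.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    last = np.concatenate([distinct, [y.size - 1]])
    fpr = np.concatenate([[0.0], fp[last] / n_neg])
    tpr = np.concatenate([[0.0], tp[last] / n_pos])
    return np.column_stack([fpr, tpr])


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Equals the probability that a uniformly random positive receives a
    higher score than a uniformly random negative, with ties counted half.
    """
    pts = roc_points(y_true, scores)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def evaluate_scores(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> Metrics:
    """All five evaluation metrics plus the ROC points for one score set."""
    counts = confusion_counts(y_true, scores, threshold)
    base = compute_metrics(counts)
    pts = roc_points(y_true, scores)
    return Metrics(accuracy=base.accuracy, precision=base.precision,
                   recall=base.recall, f1=base.f1,
                   auc=float(np.trapezoid(pts[:, 1], pts[:, 0])), roc_points=pts)
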