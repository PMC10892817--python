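"""Training, cross-validation, and the Ac/Se/Sp/AUC evaluation metrics.

The positive class throughout is ``A`` (apnea): sensitivity measures the
fraction of apnea minutes detected, specificity the fraction of normal
minutes correctly passed.  AUC is the Mann-Whitney statistic (ties counted
half), identical to the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import TrainingError, ValidationError
from .models import Classifier
from . import nn

LABELS = ("N", "A")          # index 0 = N, index 1 = A (positive class)


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0
    width_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.optimizer_name != "adam":
            raise ValidationError(f"unknown optimizer {self.optimizer_name!r}")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc}


def _as_binary(y) -> np.ndarray:
    """Map N/A symbols or 0/1 integers to {0, 1} with 1 = A."""
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        bad = sorted(set(y.tolist()) - set(LABELS))
        if bad:
            raise ValidationError(f"labels must be 'N'/'A', got {bad}")
        return (y == "A").astype(int)
    y = y.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("integer labels must be 0 (N) or 1 (A)")
    return y


def kfold_indices(n: int, k: int, seed: int,
                  labels=None) -> list[np.ndarray]:
    """Split ``range(n)`` into k shuffled folds (stratified when labeled)."""
    if not 2 <= k <= n:
        raise ValidationError(f"need 2 <= k <= n, got k={k}, n={n}")
    if labels is not None:
        y = _as_binary(labels)
        if len(y) != n:
            raise ValidationError("labels length must equal n")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n), y)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]


def train(classifier: Classifier, images: np.ndarray, labels,
          config: TrainConfig) -> Classifier:
    """Fit a classifier by minibatch cross-entropy with Adam.

    ``images`` is (n, 224, 224, 3); ``labels`` is N/A symbols or 0/1.  The
    shuffle order and dropout are seeded, so a fixed config reproduces the
    loss history exactly.  The history (per-epoch loss and training accuracy)
    is stored on the classifier.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4 or len(images) == 0:
        raise ValidationError("training set must be a non-empty image batch")
    y = _as_binary(labels)
    if len(y) != len(images):
        raise ValidationError("images and labels must align")
    optimizer = nn.Adam(lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = {"loss": [], "accuracy": []}
    n = len(images)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = classifier.network.train_step(images[idx], y[idx], optimizer)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            losses.append(loss)
        probs = classifier.network.predict_proba(images)
        acc = float(np.mean(probs.argmax(axis=1) == y))
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(acc)
    classifier.fitted = True
    classifier.history = history
    return classifier


def predict_proba(classifier: Classifier, images: np.ndarray) -> np.ndarray:
    """Per-image [p(N), p(A)] rows in evaluation mode."""
    return classifier.predict_proba(np.asarray(images, dtype=np.float32))


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally the 2x2 confusion table with A as the positive class."""
    t, p = _as_binary(y_true), _as_binary(y_pred)
    if len(t) != len(p):
        raise ValidationError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def classification_metrics(cc: ConfusionCounts) -> MetricsReport:
    """Accuracy (TP+TN)/total, sensitivity TP/(TP+FN), specificity TN/(TN+FP).

    A zero denominator (class absent) yields NaN with a warning rather than
    an error, so single-class evaluations degrade visibly.
    """
    if cc.total == 0:
        raise ValidationError("empty confusion table")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)",
                          RuntimeWarning, stacklevel=3)
            return float("nan")
        return num / den

    return MetricsReport(
        accuracy=(cc.tp + cc.tn) / cc.total,
        sensitivity=ratio(cc.tp, cc.tp + cc.fn, "sensitivity"),
        specificity=ratio(cc.tn, cc.tn + cc.fp, "specificity"),
    )


def roc_auc(scores: np.ndarray, y_true) -> float:
    """Area under the ROC curve of ``scores`` for the A class.

    Computed as the normalized Mann-Whitney U statistic with ties counted
    half, which equals the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = _as_binary(y_true)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC AUC requires both classes present")
    ranks = rankdata(scores)                       # mid-ranks for ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate(y_true, y_pred, scores=None) -> MetricsReport:
    """Confusion-based metrics plus AUC when scores are supplied."""
    report = classification_metrics(confusion_counts(y_true, y_pred))
    if scores is not None:
        report.auc = roc_auc(scores, y_true)
    return report


@dataclass
class FoldResult:
    fold: int
    report: MetricsReport
    counts: ConfusionCounts
    test_indices: np.ndarray = field(repr=False, default=None)


def cross_validate(make_classifier, images: np.ndarray, labels,
                   k: int, config: TrainConfig) -> list[FoldResult]:
    """k-fold CV: ``make_classifier(seed)`` builds a fresh model per fold."""
    y = _as_binary(labels)
    folds = kfold_indices(len(images), k, config.seed, labels=y)
    results = []
    all_idx = np.arange(len(images))
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        clf = make_classifier(config.seed + i)
        train(clf, images[train_idx], y[train_idx], config)
        probs = predict_proba(clf, images[test_idx])
        pred = probs.argmax(axis=1)
        cc = confusion_counts(y[test_idx], pred)
        report = classification_metrics(cc)
        if len(set(y[test_idx].tolist())) == 2:
            report.auc = roc_auc(probs[:, 1], y[test_idx])
        results.append(FoldResult(fold=i, report=report, counts=cc,
                                  test_indices=test_idx))
    return results
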