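"""Evaluation protocol: ratio splits, confusion-matrix metrics, ROC, and
the standard-MLP vs F-MLP comparison.

The positive class throughout is "regular" (label 1): sensitivity is the
true-regular rate and specificity the true-irregular rate.  Percentages
are reported to one decimal, rounding half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .exceptions import ValidationError
from .fcm import FcmConfig
from .network import (
    FuzzyNetwork,
    TypeIISigmoid,
    decide,
    predict_proba,
    select_variant,
    train,
)

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "RATIOS",
    "split",
    "metrics",
    "roc",
    "TrainSettings",
    "compare",
    "CompareReport",
]

RATIOS = ("80:20", "70:30", "60:40", "50:50")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with regular = positive: tp/fn count actual regulars,
    fp/tn actual irregulars."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionMatrix":
        yt = np.asarray(y_true).astype(int)
        yp = np.asarray(y_pred).astype(int)
        if yt.shape != yp.shape:
            raise ValidationError("label arrays must have equal length")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
        )


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    """Percent metrics for one evaluated model; None marks an undefined
    metric (zero denominator), deliberately distinct from 0."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    confusion: ConfusionMatrix
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    roc_area: float | None = None
    split_ratio: str = ""
    variant: str = ""


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy / sensitivity / specificity (in %, 1 decimal) from counts."""
    if cm.total == 0:
        raise ValidationError("confusion matrix is empty")
    accuracy = _round1(100.0 * (cm.tp + cm.tn) / cm.total)
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    sensitivity = _round1(100.0 * cm.tp / pos) if pos > 0 else None
    specificity = _round1(100.0 * cm.tn / neg) if neg > 0 else None
    return EvalReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        confusion=cm,
    )


def _parse_ratio(ratio: str) -> tuple[float, float]:
    try:
        a, b = (int(part) for part in ratio.split(":"))
    except Exception:
        raise ValidationError(f"malformed split ratio {ratio!r}") from None
    if a <= 0 or b <= 0 or a + b != 100:
        raise ValidationError(f"split ratio must sum to 100, got {ratio!r}")
    return a / 100.0, b / 100.0


def split(
    labels: Sequence[int], ratio: str, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified seeded train/test split by ratio string (e.g. "80:20").

    The overall test count is round(n * test_fraction); per-class counts
    follow largest-remainder apportionment so the totals are exact
    (310 samples at 80:20 gives exactly 248 train / 62 test).
    Returns (train_idx, test_idx).
    """
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("both classes must be present to split")
    _, test_frac = _parse_ratio(ratio)
    n = y.size
    n_test = int(round(n * test_frac))
    if n_test < 1 or n_test >= n:
        raise ValidationError("split leaves an empty train or test set")

    # largest-remainder apportionment of the test quota across classes
    quotas = {c: np.sum(y == c) * test_frac for c in classes}
    base = {c: int(np.floor(q)) for c, q in quotas.items()}
    shortfall = n_test - sum(base.values())
    by_remainder = sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True)
    for c in by_remainder[:shortfall]:
        base[c] += 1

    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for c in classes:
        members = np.nonzero(y == c)[0]
        perm = rng.permutation(members)
        test_idx.append(perm[: base[c]])
        train_idx.append(perm[base[c] :])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def roc(probs: Sequence[float], labels: Sequence[int]):
    """ROC sweep over all probability thresholds (regular = positive).

    Returns (points, area): points is a list of (FPR, TPR) pairs and area
    the trapezoid-rule area under the curve.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    if np.unique(y).size < 2:
        raise ValidationError("ROC requires both classes present")
    fpr, tpr, _ = _roc_curve(y, p)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_auc(fpr, tpr))


@dataclass(frozen=True)
class TrainSettings:
    """Training configuration for the comparison harness.

    The reference architecture is 2-4-2-1.  The harness trains to
    convergence on standardized features (z-scored with train-split
    statistics), for which a few hundred full-batch epochs at a moderate
    learning rate suffice on two-feature problems.
    """

    layer_sizes: tuple[int, ...] = (2, 4, 2, 1)
    eta: float = 1.0
    epochs: int = 300
    alpha: float = 2.0
    seed: int = 0
    ambiguity_mode: str = "per_layer"
    orientation: str = "samples"
    standardize: bool = True


@dataclass
class CompareReport:
    """Side-by-side evaluation of the standard MLP and both F-MLP bounds."""

    reports: dict[str, EvalReport]
    selected_variant: str
    selected_accuracy: float
    split_ratio: str
    seed: int


def _train_and_eval(
    variant: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    settings: TrainSettings,
    ratio: str,
) -> EvalReport:
    activation = TypeIISigmoid(
        alpha=settings.alpha,
        variant="standard" if variant == "standard" else variant,
    )
    net = FuzzyNetwork.initialize(
        settings.layer_sizes,
        eta=settings.eta,
        activation=activation,
        epochs=settings.epochs,
        seed=settings.seed,
    )
    mode = "standard" if variant == "standard" else "fuzzy"
    trained = train(
        net,
        X_train,
        y_train,
        mode=mode,
        ambiguity_mode=settings.ambiguity_mode,  # type: ignore[arg-type]
        orientation=settings.orientation,  # type: ignore[arg-type]
    )
    probs = predict_proba(trained, X_test)
    decisions = decide(probs)
    cm = ConfusionMatrix.from_predictions(y_test, decisions.decisions)
    report = metrics(cm)
    report.split_ratio = ratio
    report.variant = variant
    report.roc_points, report.roc_area = roc(probs, y_test)
    return report


def compare(
    features: "np.ndarray | object",
    labels: Sequence[int] | None = None,
    *,
    ratio: str = "80:20",
    settings: TrainSettings | None = None,
) -> CompareReport:
    """Train the standard MLP and both F-MLP bounds on one split and
    report their metrics plus the max-accuracy variant selection.

    features may be a pandas DataFrame with columns
    (fractal_dimension, convexity, label) or a feature matrix with a
    separate labels sequence.  All three models share the same split,
    initialization seed and training settings.
    """
    settings = settings or TrainSettings()
    if labels is None:
        df = features
        X = np.column_stack(
            [np.asarray(df["fractal_dimension"], dtype=float),
             np.asarray(df["convexity"], dtype=float)]
        )
        y = np.asarray(df["label"]).astype(int)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        y = np.asarray(labels).astype(int)

    train_idx, test_idx = split(y, ratio, settings.seed)
    X_train, y_train = X[train_idx], y[train_idx]
    X_test, y_test = X[test_idx], y[test_idx]

    if settings.standardize:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd

    reports = {
        variant: _train_and_eval(
            variant, X_train, y_train, X_test, y_test, settings, ratio
        )
        for variant in ("standard", "lower", "upper")
    }
    tag, acc = select_variant(
        reports["lower"].accuracy, reports["upper"].accuracy
    )
    return CompareReport(
        reports=reports,
        selected_variant=tag,
        selected_accuracy=acc,
        split_ratio=ratio,
        seed=settings.seed,
    )
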