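"""Validation protocols and the confusion-derived metric suite.

Three protocols assess a classifier on the benchmark corpus:

* **SCT** (self-consistency test) — train and test on the full dataset;
  measures how well the model can fit the benchmark, not generalisation.
* **IST** (independent set test) — stratified 80/20 train/test split.
* **KFOLD** — stratified 10-fold cross-validation; the report is the
  unweighted mean of per-fold metrics.

Metrics: accuracy, sensitivity (recall on the mutated class), specificity,
Matthews correlation coefficient, and the ROC curve with trapezoidal AUC.
Label 1 (mutated) is the positive class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ConfigurationError, UndefinedMetricError, ValidationError
from .models import ModelSpec, TrainingConfig, build_model

PROTOCOLS = ("SCT", "IST", "KFOLD")


@dataclass(frozen=True)
class SplitPlan:
    protocol: str
    test_fraction: float = 0.2
    k: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError("test fraction must lie in (0, 1)")
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    folds: list["MetricReport"] = field(default_factory=list)
    protocol: str = ""
    architecture: str = ""
    seed: int | None = None

    def as_row(self) -> dict:
        return {
            "architecture": self.architecture,
            "protocol": self.protocol,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "auc": self.auc,
            "seed": self.seed,
        }


def make_split(n: int, labels: Sequence[int], plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index sets for a protocol (a list of one pair, or k pairs)."""
    labels = np.asarray(labels)
    if labels.size != n:
        raise ValidationError(f"n={n} does not match {labels.size} labels")
    idx = np.arange(n)
    if plan.protocol == "SCT":
        return [(idx, idx.copy())]
    counts = np.bincount(labels.astype(int), minlength=2)
    if plan.protocol == "IST":
        if counts.min() < 2:
            raise ConfigurationError("each class needs >= 2 samples to stratify an 80/20 split")
        train, test = train_test_split(
            idx,
            test_size=plan.test_fraction,
            stratify=labels if plan.stratified else None,
            random_state=plan.seed,
        )
        return [(np.sort(train), np.sort(test))]
    if counts.min() < plan.k:
        raise ConfigurationError(
            f"smallest class has {counts.min()} samples; cannot stratify {plan.k} folds"
        )
    skf = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    return [(tr, te) for tr, te in skf.split(idx, labels)]


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Standard 2x2 counts with label 1 = positive (mutated)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"length mismatch: {y_true.shape} labels vs {y_pred.shape} predictions"
        )
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and MCC from a confusion table."""
    if c.total == 0:
        raise ValidationError("cannot compute metrics of an empty confusion table")
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "accuracy": (tp + tn) / c.total,
        "sensitivity": _safe_ratio(tp, tp + fn, "sensitivity"),
        "specificity": _safe_ratio(tn, tn + fp, "specificity"),
        "mcc": _safe_ratio(tp * tn - fp * fn, mcc_den, "mcc"),
    }


def roc_auc(y_true: Sequence[int], probabilities: Sequence[float]) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) swept over all distinct scores, and trapezoidal AUC."""
    y_true = np.asarray(y_true).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    if len(np.unique(y_true)) < 2:
        raise UndefinedMetricError("AUC undefined when only one class is present")
    fpr, tpr, _ = roc_curve(y_true, p)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _mean_report(folds: list[MetricReport], protocol: str, architecture: str, seed: int) -> MetricReport:
    def mean(attr):
        vals = [getattr(f, attr) for f in folds]
        return float(np.mean([v for v in vals if v is not None]))

    return MetricReport(
        accuracy=mean("accuracy"),
        sensitivity=mean("sensitivity"),
        specificity=mean("specificity"),
        mcc=mean("mcc"),
        auc=mean("auc"),
        folds=folds,
        protocol=protocol,
        architecture=architecture,
        seed=seed,
    )


class FeatureScaler:
    """Column-wise z-scoring fitted on the training fold.

    The raw descriptor mixes counts, position sums and high-order moments
    whose magnitudes differ by many orders; standardisation keeps the
    recurrent gates out of saturation.  Constant columns (the structural
    zero-padding slots of full (K=20) mode) are passed through unchanged.
    """

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def run_protocol(
    X: np.ndarray,
    y: Sequence[int],
    spec: ModelSpec,
    cfg: TrainingConfig,
    plan: SplitPlan,
) -> MetricReport:
    """Train and evaluate one architecture under one protocol.

    For KFOLD the returned report is the unweighted mean over folds, with
    the per-fold reports attached.  Features are z-scored with statistics of
    each training fold.  Per-fold seeds are derived from ``cfg.seed`` so the
    whole run is reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    splits = make_split(X.shape[0], y, plan)
    fold_reports: list[MetricReport] = []
    for fold_i, (train_idx, test_idx) in enumerate(splits):
        fold_seed = int((cfg.seed + 7919 * fold_i) % (2**31 - 1))
        scaler = FeatureScaler().fit(X[train_idx])
        Xtr, Xte = scaler.transform(X[train_idx]), scaler.transform(X[test_idx])
        model = build_model(spec, X.shape[1], seed=fold_seed)
        fold_cfg = replace(cfg, seed=fold_seed)
        model.fit(Xtr, y[train_idx], fold_cfg)
        probs, labels = model.predict(Xte)
        m = metrics(confusion(y[test_idx], labels))
        try:
            roc_points, auc = roc_auc(y[test_idx], probs)
        except UndefinedMetricError:
            roc_points, auc = [], None
        fold_reports.append(
            MetricReport(
                **m,
                auc=auc,
                roc_points=roc_points,
                protocol=plan.protocol,
                architecture=spec.architecture,
                seed=fold_seed,
            )
        )
    if len(fold_reports) == 1:
        return fold_reports[0]
    return _mean_report(fold_reports, plan.protocol, spec.architecture, cfg.seed)
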