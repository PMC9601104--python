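"""RBF-kernel SVM outcome classifier with train-set min-max normalization,
inverse-frequency class weights, and the confusion/AUC metric report."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

from .cohort import LF

__all__ = [
    "SvmParams",
    "MetricReport",
    "MinMaxNormalizer",
    "fit_normalizer",
    "apply_normalizer",
    "inverse_frequency_weights",
    "train_svm",
    "select_model",
    "OutcomeModel",
    "evaluate",
    "rank_auc",
]


@dataclass(frozen=True)
class SvmParams:
    C: float = 1.0
    gamma: float | None = None  # None -> 1 / num_features
    tol: float = 1e-3

    def resolved_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


@dataclass(frozen=True)
class MetricReport:
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    auc: float | None
    f1_pct: float

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "auc": self.auc,
            "f1_pct": self.f1_pct,
        }


@dataclass(frozen=True)
class MinMaxNormalizer:
    feature_names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        x = features[list(self.feature_names)].to_numpy(dtype=np.float64)
        # intentionally unclipped: test values may fall outside [0, 1]
        z = (x - self.mins) / (self.maxs - self.mins)
        return pd.DataFrame(z, columns=self.feature_names, index=features.index)


def fit_normalizer(train_features: pd.DataFrame) -> MinMaxNormalizer:
    """Per-feature min-max scaler fitted on the training set only."""
    x = train_features.to_numpy(dtype=np.float64)
    mins, maxs = x.min(axis=0), x.max(axis=0)
    flat = maxs <= mins
    if flat.any():
        bad = [n for n, c in zip(train_features.columns, flat) if c]
        raise ValueError(f"constant training feature(s): {bad}")
    return MinMaxNormalizer(tuple(train_features.columns), mins, maxs)


def apply_normalizer(normalizer: MinMaxNormalizer, features: pd.DataFrame) -> pd.DataFrame:
    return normalizer.transform(features)


def inverse_frequency_weights(labels) -> dict:
    """Class weights inversely proportional to class frequency, scaled so the
    mean per-sample weight is 1 (w_c = n / (n_classes * count_c))."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    n = len(y)
    return {c: n / (len(classes) * int(cnt)) for c, cnt in zip(classes, counts)}


@dataclass
class OutcomeModel:
    svc: SVC
    normalizer: MinMaxNormalizer | None
    positive_label: str

    def decision_scores(self, features: pd.DataFrame) -> np.ndarray:
        x = self.normalizer.transform(features) if self.normalizer else features
        s = self.svc.decision_function(x.to_numpy(dtype=np.float64))
        # orient scores so larger means more positive-class
        return s if self.svc.classes_[1] == self.positive_label else -s

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        x = self.normalizer.transform(features) if self.normalizer else features
        return self.svc.predict(x.to_numpy(dtype=np.float64))


def train_svm(
    train_features: pd.DataFrame,
    train_labels,
    params: SvmParams = SvmParams(),
    normalizer: MinMaxNormalizer | None = None,
    positive_label: str = LF,
) -> OutcomeModel:
    """Fit the Gaussian-kernel SVM (C=1, gamma=1/num_features, tol=1e-3,
    inverse-frequency class weights by default)."""
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    x = normalizer.transform(train_features) if normalizer else train_features
    svc = SVC(
        kernel="rbf",
        C=params.C,
        gamma=params.resolved_gamma(x.shape[1]),
        tol=params.tol,
        class_weight=inverse_frequency_weights(y),
        random_state=0,
    )
    svc.fit(x.to_numpy(dtype=np.float64), y)
    return OutcomeModel(svc=svc, normalizer=normalizer, positive_label=positive_label)


def select_model(
    train_features: pd.DataFrame,
    train_labels,
    val_features: pd.DataFrame,
    val_labels,
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
    params: SvmParams = SvmParams(),
    normalizer: MinMaxNormalizer | None = None,
    positive_label: str = LF,
) -> tuple[OutcomeModel, float]:
    """Optional validation-set model selection: refit over a small C grid and
    keep the model with the best validation AUC (ties prefer the earlier,
    i.e. more regularized, grid entry)."""
    y_val = np.asarray(val_labels)
    best: tuple[OutcomeModel, float] | None = None
    for c in c_grid:
        model = train_svm(
            train_features,
            train_labels,
            SvmParams(C=c, gamma=params.gamma, tol=params.tol),
            normalizer=normalizer,
            positive_label=positive_label,
        )
        auc = rank_auc(model.decision_scores(val_features), y_val == positive_label)
        if best is None or auc > best[1]:
            best = (model, auc)
    return best


def rank_auc(scores, positives) -> float:
    """AUC as the Mann-Whitney rank statistic on decision scores; ties 0.5."""
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(positives, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes in the evaluation set")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(model: OutcomeModel, test_features: pd.DataFrame, test_labels) -> MetricReport:
    """Confusion-matrix metrics with the positive class = local failure,
    plus the rank AUC of the continuous decision scores."""
    y = np.asarray(test_labels)
    if len(y) == 0:
        raise ValueError("test set is empty")
    pred = model.predict(test_features)
    pos = model.positive_label
    tp = int(np.sum((pred == pos) & (y == pos)))
    fn = int(np.sum((pred != pos) & (y == pos)))
    tn = int(np.sum((pred != pos) & (y != pos)))
    fp = int(np.sum((pred == pos) & (y != pos)))
    accuracy = 100.0 * (tp + tn) / len(y)
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    specificity = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    try:
        auc = rank_auc(model.decision_scores(test_features), y == pos)
    except ValueError:
        auc = None
    return MetricReport(accuracy, sensitivity, specificity, auc, f1)


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> MetricReport:
    """Metric arithmetic from explicit confusion counts (no AUC)."""
    n = tp + fn + tn + fp
    return MetricReport(
        accuracy_pct=100.0 * (tp + tn) / n,
        sensitivity_pct=100.0 * tp / (tp + fn) if tp + fn else 0.0,
        specificity_pct=100.0 * tn / (tn + fp) if tn + fp else 0.0,
        auc=None,
        f1_pct=100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
    )
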