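"""Minimum-redundancy maximum-relevance feature selection (quotient form).

Relevance is the one-way ANOVA F-statistic against the binary target;
redundancy is the mean absolute Pearson correlation with already-selected
features; each greedy step maximizes their quotient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SelectionResult", "f_statistic", "f_statistic_columns", "mrmr_miq_select", "feature_overlap"]

logger = logging.getLogger(__name__)

#: floor on the mean-|r| redundancy to avoid division blow-up for candidates
#: uncorrelated with everything selected so far
REDUNDANCY_FLOOR = 1e-6


@dataclass(frozen=True)
class SelectionResult:
    names: tuple[str, ...]
    relevance: tuple[float, ...]
    redundancy: tuple[float, ...]
    score: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "relevance": list(self.relevance),
            "redundancy": list(self.redundancy),
            "score": list(self.score),
        }


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"labels must contain exactly two classes, got {classes}")
    return (y == classes[1]).astype(np.int64)


def f_statistic(values, labels) -> float:
    """One-way ANOVA F between the two class means of a single feature."""
    return float(f_statistic_columns(np.asarray(values, dtype=float)[:, None], labels)[0])


def f_statistic_columns(x: np.ndarray, labels) -> np.ndarray:
    """Vectorized two-class ANOVA F for each column of ``x``."""
    y = _as_binary(labels)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least two samples per class")
    x = np.asarray(x, dtype=np.float64)
    m0 = x[y == 0].mean(axis=0)
    m1 = x[y == 1].mean(axis=0)
    grand = x.mean(axis=0)
    ss_between = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2
    ss_within = ((x[y == 0] - m0) ** 2).sum(axis=0) + ((x[y == 1] - m1) ** 2).sum(axis=0)
    df_within = n0 + n1 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / (ss_within / df_within)
    f = np.where(ss_within <= 0, np.where(ss_between > 0, np.inf, 0.0), f)
    return np.asarray(f, dtype=np.float64)


def mrmr_miq_select(features: pd.DataFrame, labels, k: int = 7) -> SelectionResult:
    """Greedy forward selection of ``k`` features by the relevance/redundancy
    quotient.

    Step 1 picks the maximal-F feature; step j > 1 maximizes
    F(f) / mean(|pearson(f, s)| for selected s).  Constant columns are
    dropped with a warning.  Ties break by column order.
    """
    x = features.to_numpy(dtype=np.float64)
    names = list(features.columns)
    const = x.std(axis=0) == 0
    if const.any():
        dropped = [n for n, c in zip(names, const) if c]
        logger.warning("dropping %d constant feature column(s): %s", len(dropped), dropped[:5])
        x = x[:, ~const]
        names = [n for n, c in zip(names, const) if not c]
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} usable features")

    f = f_statistic_columns(x, labels)
    # standardized columns make pairwise Pearson a dot product
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    n = x.shape[0]

    selected: list[int] = []
    relevance, redundancy, score = [], [], []
    abs_corr_sum = np.zeros(len(names))
    for step in range(k):
        if step == 0:
            red = np.zeros(len(names))
            sc = f.copy()
        else:
            red = abs_corr_sum / len(selected)
            sc = f / np.maximum(red, REDUNDANCY_FLOOR)
        sc[selected] = -np.inf
        pick = int(np.argmax(sc))
        selected.append(pick)
        relevance.append(float(f[pick]))
        redundancy.append(float(red[pick]))
        score.append(float(sc[pick]))
        abs_corr_sum += np.abs(z.T @ z[:, pick]) / n

    return SelectionResult(
        names=tuple(names[i] for i in selected),
        relevance=tuple(relevance),
        redundancy=tuple(redundancy),
        score=tuple(score),
    )


def feature_overlap(a: SelectionResult | list[str], b: SelectionResult | list[str]) -> int:
    """Number of shared feature names, order-insensitive."""
    sa = set(a.names if isinstance(a, SelectionResult) else a)
    sb = set(b.names if isinstance(b, SelectionResult) else b)
    return len(sa & sb)
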