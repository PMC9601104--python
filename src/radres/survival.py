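"""Kaplan-Meier estimation, the two-group log-rank test, and the
patient-cohort stratification rule (cohort 2 = any predicted-LF lesion)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .cohort import LF, SurvivalRecord

__all__ = ["KMCurve", "LogRankResult", "stratify_cohorts", "km_curve", "logrank_test"]


@dataclass(frozen=True)
class KMCurve:
    times: np.ndarray  # distinct event times, sorted
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time

    def probability_at(self, t: float) -> float:
        """Step-function value of S at time t (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float


def stratify_cohorts(
    predictions: dict[str, str],
    lesion_to_patient: dict[str, str],
    test_patients: list[str],
) -> tuple[list[str], list[str]]:
    """Partition test patients: cohort 2 has >= 1 predicted-LF lesion,
    cohort 1 is everyone else."""
    flagged: set[str] = set()
    for lesion_id, label in predictions.items():
        if lesion_id not in lesion_to_patient:
            raise KeyError(f"lesion {lesion_id!r} has no patient mapping")
        if label == LF:
            flagged.add(lesion_to_patient[lesion_id])
    cohort2 = [p for p in test_patients if p in flagged]
    cohort1 = [p for p in test_patients if p not in flagged]
    return cohort1, cohort2


def _check_times(times: np.ndarray) -> None:
    if times.size == 0:
        raise ValueError("no survival records")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")


def km_curve(times, events) -> KMCurve:
    """Product-limit estimator.  ``events`` is 1/True for an observed event,
    0/False for censoring; at tied times events precede censorings."""
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events, dtype=bool)
    _check_times(t)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = len(t)
    surv, risk = [], []
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & e))
        s *= 1.0 - d / n_risk
        surv.append(s)
        risk.append(n_risk)
    return KMCurve(times=event_times, survival=np.array(surv), at_risk=np.array(risk, dtype=int))


def logrank_test(times, events, groups) -> LogRankResult:
    """Standard two-group log-rank chi-square (1 df): sum of observed-minus-
    expected events in group 1 over the hypergeometric variance."""
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    _check_times(t)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {labels}")
    in1 = g == labels[1]
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t[e]):
        at_risk = t >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == et) & e).sum())
        d1 = int(((t == et) & e & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return LogRankResult(statistic=0.0, p_value=1.0)
    stat = o_minus_e**2 / var
    return LogRankResult(statistic=float(stat), p_value=float(chi2.sf(stat, df=1)))


def logrank_between(
    records: list[SurvivalRecord], cohort1: list[str], cohort2: list[str]
) -> LogRankResult:
    """Log-rank test between two patient cohorts given survival records."""
    by_patient = {r.patient_id: r for r in records}
    times, events, groups = [], [], []
    for label, cohort in ((0, cohort1), (1, cohort2)):
        for pid in cohort:
            rec = by_patient[pid]
            times.append(rec.pfs_time)
            events.append(rec.event)
            groups.append(label)
    return logrank_test(times, events, groups)
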