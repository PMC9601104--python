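"""First-order intensity statistics (19 features)."""

from __future__ import annotations

import numpy as np

from .preprocess import discretize

__all__ = ["first_order_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]

_EPS = np.spacing(1.0)


def first_order_features(
    volume: np.ndarray,
    roi: np.ndarray,
    spacing_mm: float = 1.0,
    n_bins: int = 32,
) -> dict[str, float]:
    """The 19 first-order statistics of the ROI intensities.

    Entropy and Uniformity are computed on the equal-width discretized
    histogram (``n_bins`` bins over the ROI range); moments are population
    moments.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    v = np.asarray(volume, dtype=np.float64)[roi]
    n = v.size
    mean = float(v.mean())
    var = float(v.var())
    sd = float(np.sqrt(var))
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    disc = discretize(volume, roi, n_bins=n_bins)
    counts = np.bincount(disc.levels[roi], minlength=n_bins + 1)[1:]
    p = counts / n
    p_nz = p[p > 0]
    if sd > 0:
        skew = float(np.mean((v - mean) ** 3) / sd**3)
        kurt = float(np.mean((v - mean) ** 4) / var**2)
    else:
        skew, kurt = 0.0, 0.0
    energy = float(np.sum(v**2))
    return {
        "Energy": energy,
        "TotalEnergy": energy * spacing_mm**3,
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz + _EPS))),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": mean,
        "Median": float(np.median(v)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(v**2))),
        "StandardDeviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }
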