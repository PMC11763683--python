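"""First-order intensity statistics over the raw ROI values.

Eighteen features following the standard radiomics definitions.  Entropy
and Uniformity are the only two computed on discretised intensities; they
share the fixed-bin-count quantisation used by the texture matrices so the
whole feature set depends on a single discretisation setting.

Conventions: population moments (ddof=0); Kurtosis is not excess-corrected
(a Gaussian scores 3); percentiles use linear interpolation between order
statistics; Energy/TotalEnergy assume unit pixel area (planar DXA, no
calibrated spacing).
"""

from __future__ import annotations

import numpy as np

from .quantise import EmptyMask, quantise

__all__ = ["FIRSTORDER_NAMES", "first_order_features"]

FIRSTORDER_NAMES: tuple[str, ...] = (
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
    "RootMeanSquare",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(image: np.ndarray, mask: np.ndarray,
                         n_levels: int = 32) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMask("mask selects no pixels")
    x = np.asarray(image, dtype=np.float64)[mask]
    n = x.size
    mean = x.mean()
    dev = x - mean
    var = float(np.mean(dev ** 2))
    sd = np.sqrt(var)

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    q = quantise(image, mask, n_levels)
    counts = np.bincount(q.levels[q.mask], minlength=n_levels + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    if sd > 0:
        skew = float(np.mean(dev ** 3) / sd ** 3)
        kurt = float(np.mean(dev ** 4) / var ** 2)
    else:
        skew, kurt = 0.0, 0.0

    energy = float((x ** 2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy,  # unit pixel area
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(dev).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquare": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
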