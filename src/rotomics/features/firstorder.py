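"""First-order (histogram/intensity) features, 18 per channel."""

from __future__ import annotations

import numpy as np

__all__ = ["firstorder_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10", "Percentile90",
    "Maximum", "Mean", "Median", "InterquartileRange", "Range",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "Kurtosis", "Variance", "Uniformity",
)

_EPS = np.finfo(np.float64).eps


def firstorder_features(image: np.ndarray, mask: np.ndarray, bin_width: float,
                        voxel_volume: float = 1.0) -> dict[str, float]:
    """18 first-order statistics over in-mask voxels.

    Entropy and Uniformity use the fixed-bin-width histogram (same anchoring
    rule as the texture discretization).  Skewness and Kurtosis are the
    population moment ratios (Kurtosis is *not* excess-corrected); both are 0
    by convention on constant regions.
    """
    mask = np.asarray(mask) > 0
    x = np.asarray(image, dtype=np.float64)[mask]
    if x.size == 0:
        raise ValueError("empty mask")
    mean = float(x.mean())
    p10, p25, med, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 50, 75, 90]))
    m2 = float(((x - mean) ** 2).mean())
    sd = np.sqrt(m2)
    scale = max(abs(float(x.min())), abs(float(x.max())))
    # treat float-cancellation jitter as a constant region (stable conventions
    # skew = kurt = 0) instead of forming noise-ratio moments
    if sd > max(1e-9 * scale, 1e-9):
        skew = float(((x - mean) ** 3).mean()) / sd**3
        kurt = float(((x - mean) ** 4).mean()) / m2**2
    else:
        skew, kurt = 0.0, 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    # fixed-bin-width histogram probabilities (same constant guard as discretize)
    rng_ = float(x.max() - x.min())
    if rng_ <= max(1e-12 * bin_width, 1e-9 * scale, 1e-9):
        probs = np.array([1.0])
    else:
        edge0 = np.floor(x.min() / bin_width) * bin_width
        idx = np.floor((x - edge0) / bin_width).astype(np.int64)
        probs = np.bincount(idx) / x.size
        probs = probs[probs > 0]
    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-(probs * np.log2(probs)).sum()),
        "Minimum": float(x.min()),
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": med,
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": float((probs**2).sum()),
    }
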