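"""First-order (intensity histogram) features of the ROI.

Fourteen statistics of the ROI intensity distribution, ignoring spatial
arrangement.  Entropy and Uniformity are computed from an ``n_bins``
equal-width histogram over the ROI range, normalized to probabilities;
Entropy uses base-2 logs with the 0*log0 = 0 convention.  Moments use the
population convention (divisor N).  Skewness and Kurtosis of a constant
region are reported as 0 by convention.
"""

from __future__ import annotations

import numpy as np

FIRST_ORDER_NAMES = (
    "Energy",
    "Entropy",
    "Kurtosis",
    "Maximum",
    "Mean",
    "Mean Absolute Deviation",
    "Median",
    "Minimum",
    "Range",
    "Root Mean Square",
    "Skewness",
    "Standard Deviation",
    "Uniformity",
    "Variance",
)


def first_order_features(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """Compute the 14 first-order features from ROI voxel intensities.

    ``values`` is the flat array of ROI voxel intensities (any order; all
    features are permutation invariant).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")

    mean = float(x.mean())
    var = float(x.var())  # population
    sd = float(np.sqrt(var))

    if x.min() == x.max():
        # all mass in one histogram bin
        p = np.array([1.0])
    else:
        counts, _ = np.histogram(x, bins=n_bins, range=(float(x.min()), float(x.max())))
        p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p**2).sum())

    if sd > 0:
        z = (x - mean) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean())  # Pearson (non-excess) kurtosis
    else:
        skew = 0.0
        kurt = 0.0

    return {
        "Energy": float((x**2).sum()),
        "Entropy": entropy,
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Mean Absolute Deviation": float(np.abs(x - mean).mean()),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "Root Mean Square": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Standard Deviation": sd,
        "Uniformity": uniformity,
        "Variance": var,
    }
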