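"""Single-level undecimated 3D wavelet decomposition.

Directional low-pass (L) / high-pass (H) filtering along x, y, z gives the
2^3 = 8 sub-bands LLL .. HHH; band names list the per-axis filter in x, y, z
order (axis 0 = x).  The transform is stationary (no decimation), so every
band keeps the input shape.

Filters: the Coiflet-1 analysis pair, rescaled so the low-pass branch has
unit DC gain — the LLL band of a constant image equals that constant, and
any band containing an H annihilates constants.  Filtering is correlation
with the filter centered at tap ``len(w)//2`` under symmetric (half-sample
reflect) boundary extension, i.e. for the extended signal x:

    y[n] = sum_j w[j] * x[n + j - len(w)//2]
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# Coiflet-1 decomposition low-pass filter (sums to sqrt(2)).
_COIF1_LO = np.array(
    [
        -0.01565572813546454,
        -0.0727326195128539,
        0.38486484686420286,
        0.8525720202122554,
        0.3378976624578092,
        -0.0727326195128539,
    ]
)
# quadrature mirror: hi[k] = (-1)^k * lo[N-1-k]
_COIF1_HI = ((-1.0) ** np.arange(_COIF1_LO.size)) * _COIF1_LO[::-1]

# unit DC gain on the low-pass branch; same rescale on the high-pass branch
LOW_PASS = _COIF1_LO / _COIF1_LO.sum()
HIGH_PASS = _COIF1_HI / _COIF1_LO.sum()

BAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _filter_axis(data: np.ndarray, kind: str, axis: int) -> np.ndarray:
    w = LOW_PASS if kind == "L" else HIGH_PASS
    return ndimage.correlate1d(data, w, axis=axis, mode="reflect")


def wavelet_decompose(voxels: np.ndarray) -> dict[str, np.ndarray]:
    """Decompose a 3D array into the 8 undecimated sub-bands.

    Returns a dict keyed LLL..HHH; each band has the input's shape.  The
    first letter is the filter applied along axis 0 (x), the second along
    axis 1 (y), the third along axis 2 (z).
    """
    v = np.asarray(voxels, dtype=np.float64)
    if v.ndim != 3:
        raise ValueError(f"expected a 3D array, got shape {v.shape}")
    if min(v.shape) < LOW_PASS.size:
        raise ValueError(
            f"volume shape {v.shape} smaller than the wavelet filter support "
            f"({LOW_PASS.size} taps)"
        )
    bands: dict[str, np.ndarray] = {}
    # filter axis by axis, sharing the partial results across bands
    for fx in "LH":
        vx = _filter_axis(v, fx, 0)
        for fy in "LH":
            vxy = _filter_axis(vx, fy, 1)
            for fz in "LH":
                bands[fx + fy + fz] = _filter_axis(vxy, fz, 2)
    return bands
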