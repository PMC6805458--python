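"""Gray-level co-occurrence (GLCM) and run-length (GLRLM) texture features.

Both matrices are computed fully in 3D over the 13 unique voxel offsets
(the 26-connected neighbourhood modulo sign).  ROI intensities are first
discretized into ``n_levels`` equal-width gray levels spanning the ROI
range; all logs are base 2 with 0*log0 = 0.

GLCM: voxel pairs at distance 1 with both ends inside the ROI, counted in
both orders (symmetric), summed over directions, then normalized to a joint
probability matrix.

GLRLM: maximal runs of constant gray level along each direction, counted
inside the ROI only (an out-of-ROI voxel terminates a run), matrices summed
over directions.  Run Percentage divides by voxels x directions so it stays
in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GLCM_NAMES = (
    "Autocorrelation",
    "Cluster Prominence",
    "Cluster Shade",
    "Cluster Tendency",
    "Contrast",
    "Correlation",
    "Difference Entropy",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity 1",
    "Homogeneity 2",
    "Informational Measure of Correlation 1",
    "Informational Measure of Correlation 2",
    "Inverse Difference Moment Normalized",
    "Inverse Difference Normalized",
    "Inverse Variance",
    "Maximum Probability",
    "Sum Average",
    "Sum Entropy",
    "Sum Variance",
    "Variance",
)

GLRLM_NAMES = (
    "Short Run Emphasis",
    "Long Run Emphasis",
    "Gray Level Non-uniformity",
    "Run Length Non-uniformity",
    "Run Percentage",
    "Low Gray Level Run Emphasis",
    "High Gray Level Run Emphasis",
    "Short Run Low Gray Level Emphasis",
    "Short Run High Gray Level Emphasis",
    "Long Run Low Gray Level Emphasis",
    "Long Run High Gray Level Emphasis",
)

# 13 unique 3D offsets: one representative per antipodal pair of the
# 26-connected neighbourhood; the first nonzero component is always +1.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


@dataclass(frozen=True)
class Quantization:
    """Equal-width binning of the ROI intensity range into 1-based levels."""

    n_levels: int
    edges: np.ndarray


def quantize(
    values: np.ndarray, mask: np.ndarray, n_levels: int = 32
) -> tuple[np.ndarray, Quantization]:
    """Discretize ROI intensities into 1..n_levels; 0 marks out-of-ROI voxels.

    Equal-width bins span [ROI min, ROI max]; the maximum maps to level
    ``n_levels``.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be positive")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty ROI")
    vals = np.asarray(values, dtype=np.float64)
    lo, hi = float(vals[mask].min()), float(vals[mask].max())
    if lo == hi:
        raise ValueError("cannot quantize constant region")
    edges = np.linspace(lo, hi, n_levels + 1)
    levels = np.zeros(vals.shape, dtype=np.int32)
    scaled = (vals[mask] - lo) / (hi - lo) * n_levels
    levels[mask] = np.clip(np.floor(scaled).astype(np.int32), 0, n_levels - 1) + 1
    return levels, Quantization(n_levels, edges)


def _pairwise_slices(shape, d):
    """Slices (src, dst) so that src voxel + offset d = dst voxel, in bounds."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, max(n - step, 0)))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, max(n + step, 0)))
    return tuple(src), tuple(dst)


def glcm(
    levels: np.ndarray,
    n_levels: int,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
    aggregate: str = "sum",
) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix (Ng x Ng).

    ``aggregate='sum'`` (default) pools raw pair counts across directions
    before normalizing; ``'mean'`` normalizes each direction's matrix and
    averages them.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    lv = np.asarray(levels, dtype=np.int64)
    mats = []
    for d in directions:
        s, t = _pairwise_slices(lv.shape, d)
        a, b = lv[s].ravel(), lv[t].ravel()
        valid = (a > 0) & (b > 0)
        a, b = a[valid], b[valid]
        counts = np.bincount((a - 1) * n_levels + (b - 1), minlength=n_levels * n_levels)
        C = counts.reshape(n_levels, n_levels).astype(np.float64)
        C = C + C.T  # count each pair in both orders
        mats.append(C)
    if aggregate == "sum":
        P = np.sum(mats, axis=0)
        total = P.sum()
        if total == 0:
            raise ValueError("no co-occurrences: ROI has no valid voxel pair")
        return P / total
    normed = []
    for C in mats:
        tot = C.sum()
        if tot > 0:
            normed.append(C / tot)
    if not normed:
        raise ValueError("no co-occurrences: ROI has no valid voxel pair")
    return np.mean(normed, axis=0)


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 22 Haralick-style features of a normalized symmetric GLCM."""
    P = np.asarray(P, dtype=np.float64)
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    def _h(p):  # Shannon entropy in bits, 0*log0 = 0
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    # diagonal (difference) and anti-diagonal (sum) marginals
    diff = np.abs(I - J).astype(np.int64)
    p_diff = np.bincount(diff.ravel(), weights=P.ravel(), minlength=Ng)  # k = 0..Ng-1
    ks = np.arange(2, 2 * Ng + 1, dtype=np.float64)
    summ = (I + J).astype(np.int64)
    p_sum = np.bincount(summ.ravel(), weights=P.ravel(), minlength=2 * Ng + 1)[2:]

    autocorr = float((I * J * P).sum())
    clus = I + J - mu_x - mu_y
    contrast = float(((I - J) ** 2 * P).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0  # degenerate marginal: documented convention

    HXY = _h(P.ravel())
    HX, HY = _h(px), _h(py)
    pxpy = np.outer(px, py)
    valid = pxpy > 0
    HXY1 = float(-(P[valid] * np.log2(pxpy[valid])).sum())
    HXY2 = _h(pxpy.ravel())
    denom = max(HX, HY)
    imc1 = (HXY - HXY1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))

    off = I != J
    inv_var = float((P[off] / (I[off] - J[off]) ** 2).sum())

    sum_avg = float((ks * p_sum).sum())

    return {
        "Autocorrelation": autocorr,
        "Cluster Prominence": float((clus**4 * P).sum()),
        "Cluster Shade": float((clus**3 * P).sum()),
        "Cluster Tendency": float((clus**2 * P).sum()),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "Difference Entropy": _h(p_diff),
        "Dissimilarity": float((np.abs(I - J) * P).sum()),
        "Energy": float((P**2).sum()),
        "Entropy": HXY,
        "Homogeneity 1": float((P / (1.0 + np.abs(I - J))).sum()),
        "Homogeneity 2": float((P / (1.0 + (I - J) ** 2)).sum()),
        "Informational Measure of Correlation 1": float(imc1),
        "Informational Measure of Correlation 2": imc2,
        "Inverse Difference Moment Normalized": float((P / (1.0 + ((I - J) / Ng) ** 2)).sum()),
        "Inverse Difference Normalized": float((P / (1.0 + np.abs(I - J) / Ng)).sum()),
        "Inverse Variance": inv_var,
        "Maximum Probability": float(P.max()),
        "Sum Average": sum_avg,
        "Sum Entropy": _h(p_sum),
        "Sum Variance": float(((ks - sum_avg) ** 2 * p_sum).sum()),
        "Variance": float(((I - mu_x) ** 2 * P).sum()),
    }


def _runs_one_direction(levels: np.ndarray, d: tuple[int, int, int]):
    """(gray level, run length) of every maximal in-ROI run along direction d."""
    lv = np.asarray(levels)
    coords = np.indices(lv.shape)
    ax = next(k for k in range(3) if d[k] != 0)  # first nonzero component is +1
    t = coords[ax]
    keys = [coords[k] - t * d[k] for k in range(3)]
    order = np.lexsort(
        (t.ravel(), keys[2].ravel(), keys[1].ravel(), keys[0].ravel())
    )
    v = lv.ravel()[order]
    k0, k1, k2 = (k.ravel()[order] for k in keys)
    new_run = np.ones(v.size, dtype=bool)
    new_run[1:] = (
        (k0[1:] != k0[:-1])
        | (k1[1:] != k1[:-1])
        | (k2[1:] != k2[:-1])
        | (v[1:] != v[:-1])
    )
    lengths = np.diff(np.append(np.flatnonzero(new_run), v.size))
    run_val = v[new_run]
    keep = run_val > 0
    return run_val[keep], lengths[keep]


def glrlm(
    levels: np.ndarray,
    n_levels: int,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> np.ndarray:
    """Run-length matrix (Ng x Rmax) summed over directions.

    Rmax is the longest grid axis, so run-cover conservation
    sum_l l * R_d(i, l) = ROI voxel count holds per direction.
    """
    lv = np.asarray(levels)
    if not (lv > 0).any():
        raise ValueError("empty ROI")
    rmax = max(lv.shape)
    R = np.zeros((n_levels, rmax), dtype=np.float64)
    for d in directions:
        val, length = _runs_one_direction(lv, d)
        np.add.at(R, (val - 1, length - 1), 1.0)
    return R


def glrlm_features(
    R: np.ndarray, n_voxels: int, n_directions: int = len(DIRECTIONS_3D)
) -> dict[str, float]:
    """The 11 Galloway/Chu run-length features of a direction-summed GLRLM."""
    R = np.asarray(R, dtype=np.float64)
    Nr = R.sum()
    if Nr == 0:
        raise ValueError("empty run-length matrix")
    Ng, Lmax = R.shape
    i = np.arange(1, Ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, Lmax + 1, dtype=np.float64)[None, :]
    return {
        "Short Run Emphasis": float((R / j**2).sum() / Nr),
        "Long Run Emphasis": float((R * j**2).sum() / Nr),
        "Gray Level Non-uniformity": float((R.sum(axis=1) ** 2).sum() / Nr),
        "Run Length Non-uniformity": float((R.sum(axis=0) ** 2).sum() / Nr),
        "Run Percentage": float(Nr / (n_voxels * n_directions)),
        "Low Gray Level Run Emphasis": float((R / i**2).sum() / Nr),
        "High Gray Level Run Emphasis": float((R * i**2).sum() / Nr),
        "Short Run Low Gray Level Emphasis": float((R / (i**2 * j**2)).sum() / Nr),
        "Short Run High Gray Level Emphasis": float((R * i**2 / j**2).sum() / Nr),
        "Long Run Low Gray Level Emphasis": float((R * j**2 / i**2).sum() / Nr),
        "Long Run High Gray Level Emphasis": float((R * i**2 * j**2).sum() / Nr),
    }
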