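"""Independent, deliberately naive reference implementations used as oracles.

Everything here is written with explicit Python loops straight from the
textbook definitions and shares no code with the package implementation.
Only usable on small inputs.
"""

from __future__ import annotations

import math

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def ref_first_order(values, n_bins):
    x = sorted(float(v) for v in np.asarray(values).ravel())
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    lo, hi = x[0], x[-1]
    if lo == hi:
        probs = [1.0]
    else:
        counts = [0] * n_bins
        width = (hi - lo) / n_bins
        for v in x:
            b = min(int((v - lo) / width), n_bins - 1)
            counts[b] += 1
        probs = [c / n for c in counts]
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    uniformity = sum(p * p for p in probs)
    if n % 2:
        median = x[n // 2]
    else:
        median = (x[n // 2 - 1] + x[n // 2]) / 2
    skew = sum(((v - mean) / sd) ** 3 for v in x) / n if sd > 0 else 0.0
    kurt = sum(((v - mean) / sd) ** 4 for v in x) / n if sd > 0 else 0.0
    return {
        "Energy": sum(v * v for v in x),
        "Entropy": entropy,
        "Kurtosis": kurt,
        "Maximum": hi,
        "Mean": mean,
        "Mean Absolute Deviation": sum(abs(v - mean) for v in x) / n,
        "Median": median,
        "Minimum": lo,
        "Range": hi - lo,
        "Root Mean Square": math.sqrt(sum(v * v for v in x) / n),
        "Skewness": skew,
        "Standard Deviation": sd,
        "Uniformity": uniformity,
        "Variance": var,
    }


def ref_quantize(values, mask, n_levels):
    vals = np.asarray(values, float)
    mask = np.asarray(mask).astype(bool)
    roi = vals[mask]
    lo, hi = roi.min(), roi.max()
    levels = np.zeros(vals.shape, dtype=int)
    it = np.ndindex(*vals.shape)
    for idx in it:
        if mask[idx]:
            b = int((vals[idx] - lo) / (hi - lo) * n_levels)
            levels[idx] = min(b, n_levels - 1) + 1
    return levels


def ref_glcm(levels, n_levels, directions=DIRS_13):
    lv = np.asarray(levels)
    nx, ny, nz = lv.shape
    C = np.zeros((n_levels, n_levels))
    for (dx, dy, dz) in directions:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    a = lv[x, y, z]
                    if a == 0:
                        continue
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz:
                        b = lv[u, v, w]
                        if b > 0:
                            C[a - 1, b - 1] += 1
                            C[b - 1, a - 1] += 1
    return C / C.sum()


def ref_glcm_features(P):
    P = np.asarray(P, float)
    Ng = P.shape[0]
    f = {k: 0.0 for k in (
        "Autocorrelation", "Cluster Prominence", "Cluster Shade", "Cluster Tendency",
        "Contrast", "Dissimilarity", "Energy", "Entropy", "Homogeneity 1",
        "Homogeneity 2", "Inverse Difference Moment Normalized",
        "Inverse Difference Normalized", "Inverse Variance", "Sum Average",
        "Variance",
    )}
    px = [sum(P[i][j] for j in range(Ng)) for i in range(Ng)]
    py = [sum(P[i][j] for i in range(Ng)) for j in range(Ng)]
    mux = sum((i + 1) * px[i] for i in range(Ng))
    muy = sum((j + 1) * py[j] for j in range(Ng))
    sdx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(Ng)))
    sdy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(Ng)))
    p_sum = [0.0] * (2 * Ng + 1)
    p_diff = [0.0] * Ng
    for i in range(Ng):
        for j in range(Ng):
            p = P[i][j]
            gi, gj = i + 1, j + 1
            f["Autocorrelation"] += gi * gj * p
            f["Cluster Prominence"] += (gi + gj - mux - muy) ** 4 * p
            f["Cluster Shade"] += (gi + gj - mux - muy) ** 3 * p
            f["Cluster Tendency"] += (gi + gj - mux - muy) ** 2 * p
            f["Contrast"] += (gi - gj) ** 2 * p
            f["Dissimilarity"] += abs(gi - gj) * p
            f["Energy"] += p * p
            if p > 0:
                f["Entropy"] -= p * math.log2(p)
            f["Homogeneity 1"] += p / (1 + abs(gi - gj))
            f["Homogeneity 2"] += p / (1 + (gi - gj) ** 2)
            f["Inverse Difference Moment Normalized"] += p / (1 + ((gi - gj) / Ng) ** 2)
            f["Inverse Difference Normalized"] += p / (1 + abs(gi - gj) / Ng)
            if gi != gj:
                f["Inverse Variance"] += p / (gi - gj) ** 2
            f["Variance"] += (gi - mux) ** 2 * p
            p_sum[gi + gj] += p
            p_diff[abs(gi - gj)] += p
    f["Correlation"] = (
        (f["Autocorrelation"] - mux * muy) / (sdx * sdy) if sdx > 0 and sdy > 0 else 0.0
    )
    f["Maximum Probability"] = float(P.max())
    f["Sum Average"] = sum(k * p_sum[k] for k in range(2, 2 * Ng + 1))
    f["Sum Entropy"] = -sum(p * math.log2(p) for p in p_sum if p > 0)
    f["Sum Variance"] = sum(
        (k - f["Sum Average"]) ** 2 * p_sum[k] for k in range(2, 2 * Ng + 1)
    )
    f["Difference Entropy"] = -sum(p * math.log2(p) for p in p_diff if p > 0)
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hy = -sum(p * math.log2(p) for p in py if p > 0)
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * py[j])
        for i in range(Ng) for j in range(Ng)
        if px[i] * py[j] > 0 and P[i][j] > 0
    )
    # include terms where P=0 but pxpy>0? 0*log -> 0, so skip is fine
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(Ng) for j in range(Ng)
        if px[i] * py[j] > 0
    )
    f["Informational Measure of Correlation 1"] = (
        (f["Entropy"] - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    )
    f["Informational Measure of Correlation 2"] = math.sqrt(
        max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - f["Entropy"])))
    )
    return f


def ref_glrlm(levels, n_levels, directions=DIRS_13):
    """Walk every line voxel by voxel; runs break at ROI/level changes."""
    lv = np.asarray(levels)
    nx, ny, nz = lv.shape
    rmax = max(lv.shape)
    R = np.zeros((n_levels, rmax))
    for d in directions:
        dx, dy, dz = d
        # line starts: voxels with no in-grid predecessor along d
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    px_, py_, pz_ = x - dx, y - dy, z - dz
                    if 0 <= px_ < nx and 0 <= py_ < ny and 0 <= pz_ < nz:
                        continue
                    cx, cy, cz = x, y, z
                    cur, length = 0, 0
                    while 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz:
                        v = lv[cx, cy, cz]
                        if v == cur:
                            length += 1
                        else:
                            if cur > 0:
                                R[cur - 1, length - 1] += 1
                            cur, length = v, 1
                        cx, cy, cz = cx + dx, cy + dy, cz + dz
                    if cur > 0:
                        R[cur - 1, length - 1] += 1
    return R


def ref_glrlm_features(R, n_voxels, n_directions=13):
    R = np.asarray(R, float)
    Ng, Lmax = R.shape
    Nr = R.sum()
    out = {
        "Short Run Emphasis": 0.0, "Long Run Emphasis": 0.0,
        "Low Gray Level Run Emphasis": 0.0, "High Gray Level Run Emphasis": 0.0,
        "Short Run Low Gray Level Emphasis": 0.0, "Short Run High Gray Level Emphasis": 0.0,
        "Long Run Low Gray Level Emphasis": 0.0, "Long Run High Gray Level Emphasis": 0.0,
    }
    for i in range(Ng):
        for j in range(Lmax):
            r = R[i][j]
            gi, gj = i + 1, j + 1
            out["Short Run Emphasis"] += r / gj**2
            out["Long Run Emphasis"] += r * gj**2
            out["Low Gray Level Run Emphasis"] += r / gi**2
            out["High Gray Level Run Emphasis"] += r * gi**2
            out["Short Run Low Gray Level Emphasis"] += r / (gi**2 * gj**2)
            out["Short Run High Gray Level Emphasis"] += r * gi**2 / gj**2
            out["Long Run Low Gray Level Emphasis"] += r * gj**2 / gi**2
            out["Long Run High Gray Level Emphasis"] += r * gi**2 * gj**2
    out = {k: v / Nr for k, v in out.items()}
    out["Gray Level Non-uniformity"] = sum(
        sum(R[i][j] for j in range(Lmax)) ** 2 for i in range(Ng)
    ) / Nr
    out["Run Length Non-uniformity"] = sum(
        sum(R[i][j] for i in range(Ng)) ** 2 for j in range(Lmax)
    ) / Nr
    out["Run Percentage"] = Nr / (n_voxels * n_directions)
    return out


def ref_shape_derived(V, A):
    """Shape formulas recomputed independently from volume and surface area."""
    r = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    return {
        "Compactness 1": V / (math.sqrt(math.pi) * A ** 1.5),
        "Compactness 2": 36.0 * math.pi * V**2 / A**3,
        "Spherical Disproportion": A / (4.0 * math.pi * r**2),
        "Sphericity": math.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / A,
        "Surface to Volume Ratio": A / V,
    }


def ref_max_diameter(mask, spacing):
    """Brute-force largest pairwise distance over boundary voxel centers."""
    m = np.asarray(mask).astype(bool)
    nx, ny, nz = m.shape
    pts = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not m[x, y, z]:
                    continue
                for dx, dy, dz in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                    u, v, w = x + dx, y + dy, z + dz
                    if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz) or not m[u, v, w]:
                        pts.append((x * spacing[0], y * spacing[1], z * spacing[2]))
                        break
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.dist(pts[i], pts[j])
            best = max(best, d)
    return best


def ref_filter_1d(x, w):
    """Correlation with w centered at tap len(w)//2 under symmetric padding."""
    x = np.asarray(x, float)
    n, m = x.size, len(w)
    pad = m
    xe = np.pad(x, pad, mode="symmetric")
    c = m // 2
    return np.array(
        [sum(w[j] * xe[i + pad + j - c] for j in range(m)) for i in range(n)]
    )


def ref_wavelet_band(vol, w_by_axis):
    """Separable 3D filtering built from ref_filter_1d along each axis."""
    out = np.asarray(vol, float).copy()
    for axis, w in enumerate(w_by_axis):
        out = np.apply_along_axis(ref_filter_1d, axis, out, w)
    return out


def ref_mutual_information(x, y):
    """Plug-in MI in bits from an explicit contingency table."""
    x, y = list(x), list(y)
    n = len(x)
    xs, ys = sorted(set(x)), sorted(set(y))
    mi = 0.0
    for a in xs:
        for b in ys:
            pab = sum(1 for u, v in zip(x, y) if u == a and v == b) / n
            if pab == 0:
                continue
            pa = sum(1 for u in x if u == a) / n
            pb = sum(1 for v in y if v == b) / n
            mi += pab * math.log2(pab / (pa * pb))
    return mi


def ref_auc(scores, labels):
    """Concordant-pair count with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def ref_chi2(table):
    """Pearson chi-square statistic and p-value from the textbook formula."""
    from scipy.stats import chi2 as chi2_dist

    t = np.asarray(table, float)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    total = t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = rows[i] * cols[j] / total
            stat += (t[i, j] - e) ** 2 / e
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, float(chi2_dist.sf(stat, dof))
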