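"""ROC / optimal-cutoff analysis, feature correlations and cohort-balance tests.

AUC follows the Mann-Whitney convention (ties count one half), so it is the
probability a random positive outscores a random negative.  The optimal
cutoff maximizes the Youden index J = sensitivity + specificity - 1 over
midpoints between consecutive distinct scores (plus sentinels beyond the
extremes); ties among maximizers resolve toward the cutoff nearest the score
median.  A closest-to-(0,1) criterion is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float = float("nan")
    sens_at_cutoff: float = float("nan")
    spec_at_cutoff: float = float("nan")
    acc_at_cutoff: float = float("nan")


@dataclass
class CorrelationReport:
    names: list[str]
    coef: np.ndarray
    pvalues: np.ndarray
    summary_mean: float          # signed off-diagonal mean
    summary_sd: float
    summary_mean_abs: float      # |r| off-diagonal mean
    summary_sd_abs: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Full sensitivity/specificity profile and Mann-Whitney AUC.

    Thresholds are midpoints between consecutive distinct scores plus one
    sentinel below the minimum and one above the maximum; a sample is called
    positive when its score is >= the threshold.
    """
    s = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    y = _check_binary(labels)

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))

    pos, neg = s[y == 1], s[y == 0]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    # Mann-Whitney AUC with half credit for ties
    n1, n0 = len(pos), len(neg)
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return ROCResult(thresholds, sens, spec, float(auc))


def optimal_cutoff(
    r: ROCResult,
    labels: np.ndarray,
    scores: np.ndarray,
    criterion: str = "youden",
) -> ROCResult:
    """Fill in the optimal cutoff and its sensitivity/specificity/accuracy."""
    if criterion not in ("youden", "closest"):
        raise ValueError(f"unknown cutoff criterion {criterion!r}")
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=np.float64)

    if criterion == "youden":
        objective = r.sensitivity + r.specificity - 1.0
    else:
        objective = -np.sqrt((1.0 - r.sensitivity) ** 2 + (1.0 - r.specificity) ** 2)

    best = objective.max()
    if criterion == "youden" and best <= 1e-12:
        warnings.warn(
            "no cutoff beats chance (J <= 0): scores may be anti-predictive "
            "under the positive-toward-high orientation",
            stacklevel=2,
        )
    cand = np.flatnonzero(np.isclose(objective, best))
    median = np.median(s)
    pick = cand[np.argmin(np.abs(r.thresholds[cand] - median))]

    cutoff = float(r.thresholds[pick])
    pred = (s >= cutoff).astype(int)
    r.optimal_cutoff = cutoff
    r.sens_at_cutoff = float(r.sensitivity[pick])
    r.spec_at_cutoff = float(r.specificity[pick])
    r.acc_at_cutoff = float((pred == y).mean())
    return r


def evaluate_scores(
    scores: np.ndarray, labels: np.ndarray, criterion: str = "youden"
) -> ROCResult:
    """Convenience wrapper: ROC profile, AUC and optimal-cutoff metrics."""
    r = roc_auc(scores, labels)
    return optimal_cutoff(r, labels, scores, criterion=criterion)


def feature_correlations(
    values: np.ndarray, names: list[str], method: str = "pearson"
) -> CorrelationReport:
    """Pairwise feature correlations with two-sided significance.

    Constant columns get coefficient 0 / p = 1 against everything (with a
    warning).  Summary mean/sd are reported over the off-diagonal upper
    triangle, both signed and in absolute value.
    """
    X = np.asarray(values, dtype=np.float64)
    k = X.shape[1]
    if k < 2:
        raise ValueError("need at least 2 features")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr

    constant = [j for j in range(k) if X[:, j].min() == X[:, j].max()]
    if constant:
        warnings.warn(
            f"constant feature(s) {[names[j] for j in constant]}: "
            "correlations reported as 0 with p = 1",
            stacklevel=2,
        )

    coef = np.eye(k)
    pval = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            if a in constant or b in constant:
                rho, p = 0.0, 1.0
            else:
                res = corr_fn(X[:, a], X[:, b])
                rho, p = float(res.statistic), float(res.pvalue)
            coef[a, b] = coef[b, a] = rho
            pval[a, b] = pval[b, a] = p

    iu = np.triu_indices(k, 1)
    off = coef[iu]
    return CorrelationReport(
        names=list(names),
        coef=coef,
        pvalues=pval,
        summary_mean=float(off.mean()),
        summary_sd=float(off.std(ddof=1)) if off.size > 1 else 0.0,
        summary_mean_abs=float(np.abs(off).mean()),
        summary_sd_abs=float(np.abs(off).std(ddof=1)) if off.size > 1 else 0.0,
    )


def cohort_balance(
    categorical: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    continuous: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    correction: bool = False,
) -> list[dict]:
    """Chi-square / t-test comparison of covariates between two cohorts.

    ``categorical`` maps covariate name to (training values, validation
    values) of category codes; ``continuous`` likewise for numeric values
    (compared with a two-sample Student t-test, equal variances).  Returns
    one row per covariate with the statistic and p-value, mirroring a
    baseline-characteristics table.
    """
    rows: list[dict] = []
    for name, (a, b) in (continuous or {}).items():
        t_stat, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
        rows.append({"covariate": name, "test": "t", "statistic": float(t_stat), "p": float(p)})
    for name, (a, b) in (categorical or {}).items():
        cats = np.unique(np.concatenate([np.asarray(a), np.asarray(b)]))
        table = np.array(
            [
                [(np.asarray(a) == c).sum() for c in cats],
                [(np.asarray(b) == c).sum() for c in cats],
            ],
            dtype=float,
        )
        present = table.sum(axis=0) > 0
        if not present.all():
            warnings.warn(
                f"{name}: dropping empty categories {cats[~present]}", stacklevel=2
            )
            table = table[:, present]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            warnings.warn(f"{name}: not testable, excluded", stacklevel=2)
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
        rows.append(
            {"covariate": name, "test": "chi2", "statistic": float(chi2), "p": float(p)}
        )
    return rows


def chi2_from_counts(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test from a raw contingency table of counts."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table, float), correction=correction)
    return float(chi2), float(p)
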