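"""RBF-kernel SVM with a cross-validated gamma/cost grid search.

Hyperparameters are chosen by stratified 10-fold cross-validated AUC over
the 9 x 9 grid gamma, cost in {1e-4 .. 1e4}; the model is refit on all
training rows with the winning pair.  Features are z-scored per column using
training-row statistics only (an RBF kernel at cost 1e-3 is meaningless on
raw scales); validation rows never touch standardization, fold assignment or
the grid.  Decision scores are signed distances to the separating surface,
positive toward the "high" class, as required for thresholding a continuous
score at an ROC cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from radsig.mrmr import FeatureTable

DEFAULT_GRID = tuple(10.0**e for e in range(-4, 5))  # 1e-4 .. 1e4


@dataclass
class GridSearchSpec:
    gammas: tuple[float, ...] = DEFAULT_GRID
    costs: tuple[float, ...] = DEFAULT_GRID
    folds: int = 10
    seed: int = 0
    standardize: bool = True


@dataclass
class TrainedClassifier:
    gamma: float
    cost: float
    feature_names: list[str]
    mean: np.ndarray       # per-feature training mean (zeros if not standardized)
    sd: np.ndarray         # per-feature training sd (ones if not standardized)
    model: object  # fitted SVC, or _RBFDecision when deserialized
    cv_grid: list[dict] = field(default_factory=list)  # 81 rows of gamma/cost/score

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _column_stats(X: np.ndarray, standardize: bool) -> tuple[np.ndarray, np.ndarray]:
    if not standardize:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant column: leave centered, do not blow up
    return mean, sd


def grid_search_cv(t: FeatureTable, spec: GridSearchSpec | None = None) -> TrainedClassifier:
    """Select (gamma, cost) by stratified k-fold CV AUC and refit on all rows.

    ``t`` must already be restricted to the signature columns and to the
    training rows.  Grid ties break toward smaller cost, then smaller gamma
    (stronger regularization).
    """
    spec = spec or GridSearchSpec()
    X_raw = t.values
    y = np.asarray(t.labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("training rows must contain both classes")
    if counts.min() < spec.folds:
        raise ValueError(
            f"minority class has {counts.min()} samples, fewer than "
            f"{spec.folds} folds; reduce the fold count"
        )

    mean, sd = _column_stats(X_raw, spec.standardize)
    X = (X_raw - mean) / sd

    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X, y))

    cv_grid: list[dict] = []
    for gamma in spec.gammas:
        for cost in spec.costs:
            aucs = []
            for tr, te in folds:
                clf = SVC(kernel="rbf", gamma=gamma, C=cost)
                clf.fit(X[tr], y[tr])
                scores = clf.decision_function(X[te])
                # a fold with one class present cannot score AUC; stratified
                # folds guarantee both classes, so this is just defensive
                aucs.append(roc_auc_score(y[te], scores))
            cv_grid.append(
                {"gamma": gamma, "cost": cost, "mean_cv_auc": float(np.mean(aucs))}
            )

    best = min(cv_grid, key=lambda r: (-r["mean_cv_auc"], r["cost"], r["gamma"]))
    model = SVC(kernel="rbf", gamma=best["gamma"], C=best["cost"])
    model.fit(X, y)
    return TrainedClassifier(
        gamma=best["gamma"],
        cost=best["cost"],
        feature_names=list(t.feature_names),
        mean=mean,
        sd=sd,
        model=model,
        cv_grid=cv_grid,
    )


class _RBFDecision:
    """Minimal RBF decision function reconstructed from serialized state."""

    def __init__(self, support_vectors, dual_coef, intercept, gamma, classes):
        self.support_vectors_ = np.asarray(support_vectors, dtype=np.float64)
        self._dual = np.asarray(dual_coef, dtype=np.float64)
        self._b = float(intercept)
        self._gamma = float(gamma)
        self.classes_ = np.asarray(classes)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        d2 = (
            (X**2).sum(axis=1)[:, None]
            + (self.support_vectors_**2).sum(axis=1)[None, :]
            - 2.0 * X @ self.support_vectors_.T
        )
        return np.exp(-self._gamma * np.maximum(d2, 0.0)) @ self._dual + self._b


def classifier_to_dict(c: TrainedClassifier) -> dict:
    """JSON-serializable model state, including the full CV grid."""
    m = c.model
    return {
        "gamma": c.gamma,
        "cost": c.cost,
        "feature_names": c.feature_names,
        "mean": c.mean.tolist(),
        "sd": c.sd.tolist(),
        "support_vectors": np.asarray(m.support_vectors_).tolist(),
        "dual_coef": np.asarray(m.dual_coef_)[0].tolist(),
        "intercept": float(np.asarray(m.intercept_)[0]),
        "classes": np.asarray(m.classes_).tolist(),
        "cv_grid": c.cv_grid,
    }


def classifier_from_dict(d: dict) -> TrainedClassifier:
    model = _RBFDecision(
        d["support_vectors"], d["dual_coef"], d["intercept"], d["gamma"], d["classes"]
    )
    return TrainedClassifier(
        gamma=d["gamma"],
        cost=d["cost"],
        feature_names=list(d["feature_names"]),
        mean=np.asarray(d["mean"], dtype=np.float64),
        sd=np.asarray(d["sd"], dtype=np.float64),
        model=model,
        cv_grid=list(d.get("cv_grid", [])),
    )


def decision_scores(c: TrainedClassifier, t: FeatureTable) -> np.ndarray:
    """Signed decision value per row; positive leans toward the "high" class."""
    missing = [f for f in c.feature_names if f not in t.feature_names]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing}")
    idx = [t.feature_names.index(f) for f in c.feature_names]
    X = c.transform(t.values[:, idx])
    scores = c.model.decision_function(X)
    # SVC orients decision_function toward classes_[1]; labels are coded
    # 0 = low, 1 = high, so positive is already "high"
    if c.model.classes_[1] != 1:
        scores = -scores
    return scores
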