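"""Minimum-redundancy-maximum-relevance (mRMR) greedy feature selection.

Features are discretized into equal-frequency bins; relevance and redundancy
are plug-in mutual information (base-2 logs) on the resulting categorical
variables.  Greedy forward selection picks first the most label-relevant
feature, then repeatedly the feature maximizing

    difference criterion:  MI(f; label) - mean_{s in S} MI(f; s)
    quotient criterion:    MI(f; label) / mean_{s in S} MI(f; s)

Ties break on (higher score, then lexicographically smaller feature name),
so the selection is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureTable:
    """Samples x features matrix with sample ids, names, labels and groups."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray  # 0 = low, 1 = high
    groups: np.ndarray | None = None  # 'training' / 'validation'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("values shape inconsistent with ids/names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains missing/non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            [self.sample_ids[i] for i in np.flatnonzero(idx)] if idx.dtype == bool
            else [self.sample_ids[i] for i in idx],
            self.feature_names,
            self.values[idx],
            self.labels[idx],
            None if self.groups is None else self.groups[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        df["label"] = np.where(self.labels == 1, "high", "low")
        if self.groups is not None:
            df["group"] = self.groups
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        meta = [c for c in ("sample_id", "label", "group") if c in df.columns]
        feats = [c for c in df.columns if c not in meta]
        labels = (df["label"].astype(str) == "high").astype(int).to_numpy()
        groups = df["group"].to_numpy() if "group" in df.columns else None
        return cls(
            df["sample_id"].astype(str).tolist() if "sample_id" in df.columns
            else [str(i) for i in range(len(df))],
            feats,
            df[feats].to_numpy(dtype=np.float64),
            labels,
            groups,
        )


@dataclass
class SelectionResult:
    """Ordered mRMR signature with per-step scores and relevance values."""

    selected: list[str]
    scores: list[float]
    relevance: dict[str, float]
    settings: dict = field(default_factory=dict)


def discretize_feature(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning into 0..n_bins-1 categories.

    Sample i's category is floor(rank_i * n_bins / n) with ranks assigned by
    a stable sort, so ties resolve by original sample order (documented,
    deterministic rule).  A constant feature collapses to one category.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def discretize_table(t: FeatureTable, n_bins: int = 3) -> np.ndarray:
    """Per-feature equal-frequency discretization of the whole table."""
    codes = np.empty(t.values.shape, dtype=np.int64)
    for j in range(t.p):
        col = t.values[:, j]
        if col.min() == col.max():
            warnings.warn(
                f"constant feature {t.feature_names[j]!r}: single category, "
                "relevance will be 0",
                stacklevel=2,
            )
            codes[:, j] = 0
        else:
            codes[:, j] = discretize_feature(col, n_bins)
    return codes


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information in bits between two categorical vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nzmask = pxy > 0
    return float((pxy[nzmask] * np.log2(pxy[nzmask] / (px @ py)[nzmask])).sum())


def mrmr_select(
    t: FeatureTable,
    k: int = 9,
    criterion: str = "difference",
    n_bins: int = 3,
) -> SelectionResult:
    """Greedy mRMR selection of ``k`` features against the binary label."""
    if criterion not in ("difference", "quotient"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if k > t.p:
        raise ValueError(f"k={k} exceeds the number of features p={t.p}")
    if len(np.unique(t.labels)) != 2:
        raise ValueError("labels must contain both classes")

    codes = discretize_table(t, n_bins)
    y = t.labels
    relevance = np.array(
        [mutual_information(codes[:, j], y) for j in range(t.p)]
    )
    if np.all(relevance <= 0):
        raise ValueError("no informative features: all relevances are zero")

    names = t.feature_names
    selected_idx: list[int] = []
    scores: list[float] = []
    # cached pairwise MI against already-selected features
    redundancy = np.zeros((0, t.p))

    for _ in range(k):
        if selected_idx:
            mean_red = redundancy.mean(axis=0)
            if criterion == "difference":
                crit = relevance - mean_red
            else:
                crit = relevance / np.maximum(mean_red, 1e-12)
        else:
            crit = relevance.copy()
        crit[selected_idx] = -np.inf
        best = min(
            (j for j in range(t.p) if j not in selected_idx),
            key=lambda j: (-crit[j], names[j]),
        )
        selected_idx.append(best)
        scores.append(float(crit[best]))
        row = np.array(
            [mutual_information(codes[:, best], codes[:, j]) for j in range(t.p)]
        )
        redundancy = np.vstack([redundancy, row])

    return SelectionResult(
        selected=[names[j] for j in selected_idx],
        scores=scores,
        relevance={names[j]: float(relevance[j]) for j in range(t.p)},
        settings={"k": k, "criterion": criterion, "n_bins": n_bins},
    )
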