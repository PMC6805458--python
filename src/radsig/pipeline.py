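"""End-to-end study orchestration: simulate -> preprocess -> extract ->
select -> train -> score -> evaluate/correlate.

`run_study` drives the whole analysis from in-memory samples or a manifest
and returns a JSON-serializable report: the mRMR signature, the CV-grid
optimum, training and validation ROC results (AUC, Youden cutoff,
sensitivity/specificity/accuracy) and the signature correlation summaries
for both groups.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from radsig.classifier import (
    GridSearchSpec,
    classifier_to_dict,
    decision_scores,
    grid_search_cv,
)
from radsig.evaluation import evaluate_scores, feature_correlations
from radsig.features import FeatureConfig, extract_all, feature_names
from radsig.mrmr import FeatureTable, mrmr_select
from radsig.preprocess import Sample, load_mask, load_volume, preprocess_sample, validate_sample
from radsig.synthetic import PhantomSpec, generate_phantom_samples

log = logging.getLogger("radsig")


@dataclass
class RunConfig:
    """All pipeline settings in one serializable bundle."""

    target_spacing_mm: float = 1.0
    preprocess_order: str = "normalize-first"
    n_bins: int = 32
    glcm_aggregate: str = "sum"
    wavelet: str = "coif1"
    k: int = 9
    criterion: str = "difference"
    mrmr_bins: int = 3
    folds: int = 10
    seed: int = 0
    cutoff_criterion: str = "youden"
    correlation_method: str = "pearson"
    simulate: dict = field(default_factory=dict)  # PhantomSpec overrides

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def as_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "image_path", "mask_path", "label", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_samples(manifest: pd.DataFrame) -> list[Sample]:
    samples = []
    for row in manifest.itertuples(index=False):
        samples.append(
            Sample(
                sample_id=str(row.sample_id),
                volume=load_volume(row.image_path),
                mask=load_mask(row.mask_path),
                label=str(row.label),
                group=str(row.group),
            )
        )
    return samples


def extract_table(
    samples: list[Sample], config: RunConfig, preprocessed: bool = False
) -> FeatureTable:
    """Preprocess (optionally) and extract the 431-feature table."""
    cfg = FeatureConfig(
        n_bins=config.n_bins,
        glcm_aggregate=config.glcm_aggregate,
        wavelet=config.wavelet,
    )
    rows, ids, labels, groups = [], [], [], []
    for s in samples:
        issues = validate_sample(s)
        if issues:
            raise ValueError(f"sample {s.sample_id}: {'; '.join(issues)}")
        if not preprocessed:
            s = preprocess_sample(
                s, target_mm=config.target_spacing_mm, order=config.preprocess_order
            )
        vec = extract_all(s.volume, s.mask, cfg)
        rows.append([vec[name] for name in feature_names()])
        ids.append(s.sample_id)
        labels.append(1 if s.label == "high" else 0)
        groups.append(s.group)
    return FeatureTable(
        sample_ids=ids,
        feature_names=feature_names(),
        values=np.asarray(rows),
        labels=np.asarray(labels),
        groups=np.asarray(groups, dtype=object),
    )


def _restrict(table: FeatureTable, names: list[str]) -> FeatureTable:
    idx = [table.feature_names.index(n) for n in names]
    return FeatureTable(
        table.sample_ids, list(names), table.values[:, idx], table.labels, table.groups
    )


def run_study(table: FeatureTable, config: RunConfig | None = None) -> dict:
    """Select features on training rows, train the SVM, evaluate both groups."""
    config = config or RunConfig()
    if table.groups is None:
        raise ValueError("feature table has no train/validation group column")
    is_train = table.groups == "training"
    train = table.subset_rows(is_train)
    valid = table.subset_rows(~is_train)

    t0 = time.perf_counter()
    selection = mrmr_select(
        train, k=config.k, criterion=config.criterion, n_bins=config.mrmr_bins
    )
    log.info("mRMR selected %s in %.1fs", selection.selected, time.perf_counter() - t0)

    sig_train = _restrict(train, selection.selected)
    sig_valid = _restrict(valid, selection.selected)

    t0 = time.perf_counter()
    spec = GridSearchSpec(folds=config.folds, seed=config.seed)
    clf = grid_search_cv(sig_train, spec)
    log.info(
        "grid search done (gamma=%g, cost=%g) in %.1fs",
        clf.gamma, clf.cost, time.perf_counter() - t0,
    )

    report: dict = {
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "signature": selection.selected,
        "mrmr_scores": selection.scores,
        "model": classifier_to_dict(clf),
        "roc": {},
        "correlations": {},
    }
    for name, part in (("training", sig_train), ("validation", sig_valid)):
        scores = decision_scores(clf, part)
        roc = evaluate_scores(scores, part.labels, criterion=config.cutoff_criterion)
        report["roc"][name] = {
            "auc": roc.auc,
            "optimal_cutoff": roc.optimal_cutoff,
            "sensitivity": roc.sens_at_cutoff,
            "specificity": roc.spec_at_cutoff,
            "accuracy": roc.acc_at_cutoff,
            "n": len(part.sample_ids),
        }
        corr = feature_correlations(
            part.values, part.feature_names, method=config.correlation_method
        )
        report["correlations"][name] = {
            "mean": corr.summary_mean,
            "sd": corr.summary_sd,
            "mean_abs": corr.summary_mean_abs,
            "sd_abs": corr.summary_sd_abs,
        }
    return report


def run_all(config: RunConfig | None = None, samples: list[Sample] | None = None) -> dict:
    """One-command study: simulate phantoms (unless given), extract, analyze."""
    config = config or RunConfig()
    if samples is None:
        spec = PhantomSpec(seed=config.seed, **config.simulate)
        log.info("simulating %d phantoms (%s effect)", spec.n_train + spec.n_validation, spec.effect)
        samples = generate_phantom_samples(spec)
    table = extract_table(samples, config)
    return run_study(table, config)
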