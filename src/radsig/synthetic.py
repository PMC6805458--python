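"""Synthetic phantom cohorts and feature tables.

The original cohort (239 glioma patients, T2 volumes with manually drawn
ROIs, binary VEGF labels, a random 2:1 training/validation split) is not
publicly deposited, so this module generates stand-ins with the statistical
structure the analysis assumes:

* **Phantoms** — 3D volumes with Gaussian background noise and an ellipsoidal
  ROI whose interior is a smoothed Gaussian random field.  The class signal
  is carried by texture: the "high" class gets a mean shift ``delta`` and a
  longer spatial correlation length ``ell`` than the "low" class.  The
  ``null`` preset makes the two class distributions identical; ``moderate``
  and ``strong`` increase (delta, ell separation).

* **Feature tables** — n x p Gaussian tables where ``k_informative`` columns
  carry a standardized class mean difference ``effect_size`` and the rest
  are class-independent, with block-equicorrelated nuisance structure.

Everything is fully determined by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from radsig.mrmr import FeatureTable
from radsig.preprocess import Mask3D, Sample, Volume3D, save_volume

# (mean shift delta, ell_low, ell_high) in voxels; null has identical classes
EFFECT_PRESETS: dict[str, tuple[float, float, float]] = {
    "null": (0.0, 1.5, 1.5),
    "moderate": (0.5, 1.2, 1.8),
    "strong": (1.0, 1.0, 2.0),
}


@dataclass
class PhantomSpec:
    """Cohort-shaped phantom generator settings (defaults mirror the study)."""

    n_train: int = 160
    n_validation: int = 79
    low_fraction: float = 90.0 / 239.0  # 63+27 lows of 239 overall
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_semiaxes: tuple[float, float] = (6.0, 12.0)  # uniform range, voxels
    baseline: float = 2.0  # ROI hyperintensity over the noise background
    noise_sd: float = 1.0
    effect: str = "strong"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_PRESETS:
            raise ValueError(f"unknown effect preset {self.effect!r}")
        if self.n_train <= 0 or self.n_validation <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 < self.low_fraction < 1.0:
            raise ValueError("low_fraction must be in (0, 1)")


@dataclass
class TableSpec:
    """Feature-table generator settings (defaults mirror the 239 x 431 study)."""

    n: int = 239
    p: int = 431
    k_informative: int = 9
    effect_size: float = 1.0
    rho: float = 0.3
    block_size: int = 10
    low_fraction: float = 90.0 / 239.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.p:
            raise ValueError("k_informative exceeds p")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")


def split_assignment(n: int, seed: int, ratio: tuple[int, int] = (2, 1)) -> np.ndarray:
    """Random training/validation assignment at the requested ratio.

    The validation count is floored (n=239 at 2:1 gives 160/79); assignment
    is independent of any label.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_val = (n * ratio[1]) // (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    groups = np.array(["training"] * n, dtype=object)
    groups[rng.choice(n, size=n_val, replace=False)] = "validation"
    return groups


def split_cohort(manifest: pd.DataFrame, seed: int, ratio: tuple[int, int] = (2, 1)) -> pd.DataFrame:
    """Add/overwrite the ``group`` column of a manifest with a random split."""
    out = manifest.copy()
    out["group"] = split_assignment(len(manifest), seed, ratio)
    return out


def _labels(n: int, low_fraction: float, rng: np.random.Generator) -> np.ndarray:
    n_low = int(round(n * low_fraction))
    labels = np.array(["low"] * n_low + ["high"] * (n - n_low), dtype=object)
    rng.shuffle(labels)
    return labels


def _ellipsoid_mask(shape, semiaxes, rng) -> np.ndarray:
    axes = rng.uniform(semiaxes[0], semiaxes[1], size=3)
    center = np.array(shape) / 2.0 + rng.uniform(-2.0, 2.0, size=3)
    grids = np.indices(shape).astype(np.float64)
    d2 = sum(((grids[k] - center[k]) / axes[k]) ** 2 for k in range(3))
    return (d2 <= 1.0).astype(np.uint8)


def _textured_roi(shape, ell, delta, baseline, mask, rng) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=ell)
    roi = field[mask.astype(bool)]
    sd = roi.std()
    if sd == 0:  # pathological smoothing; keep the field flat
        sd = 1.0
    return baseline + delta + (field - roi.mean()) / sd


def generate_phantom_samples(spec: PhantomSpec) -> list[Sample]:
    """Generate the in-memory phantom cohort (volumes, masks, labels, split)."""
    n = spec.n_train + spec.n_validation
    rng = np.random.default_rng(spec.seed)
    labels = _labels(n, spec.low_fraction, rng)
    # split drawn independently of the labels, like the study's random 2:1
    groups = split_assignment(n, seed=int(rng.integers(2**31)), ratio=(2, 1))
    delta, ell_low, ell_high = EFFECT_PRESETS[spec.effect]

    samples: list[Sample] = []
    for i in range(n):
        vox = spec.noise_sd * rng.standard_normal(spec.volume_shape)
        mask = _ellipsoid_mask(spec.volume_shape, spec.roi_semiaxes, rng)
        if labels[i] == "high":
            ell, dlt = ell_high, delta
        else:
            ell, dlt = ell_low, 0.0
        texture = _textured_roi(
            spec.volume_shape, ell, dlt, spec.baseline, mask, rng
        )
        fg = mask.astype(bool)
        vox[fg] = texture[fg]
        samples.append(
            Sample(
                sample_id=f"phantom_{i:04d}",
                volume=Volume3D(vox, spec.spacing),
                mask=Mask3D(mask, spec.spacing),
                label=str(labels[i]),
                group=str(groups[i]),
            )
        )
    return samples


def generate_phantom_cohort(spec: PhantomSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write NIfTI volume/mask pairs plus a manifest CSV; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in generate_phantom_samples(spec):
        img_path = out / f"{s.sample_id}_img.nii.gz"
        msk_path = out / f"{s.sample_id}_msk.nii.gz"
        save_volume(s.volume, img_path)
        save_volume(s.mask, msk_path)
        rows.append(
            {
                "sample_id": s.sample_id,
                "image_path": str(img_path),
                "mask_path": str(msk_path),
                "label": s.label,
                "group": s.group,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def generate_feature_table(spec: TableSpec) -> tuple[FeatureTable, np.ndarray]:
    """Gaussian feature table with k planted informative columns.

    Returns the table and a boolean mask over columns marking the planted
    signal.  Informative columns have standardized between-class mean
    difference equal to ``effect_size``; nuisance columns are label-free with
    within-block correlation ``rho``.
    """
    rng = np.random.default_rng(spec.seed)
    labels01 = (_labels(spec.n, spec.low_fraction, rng) == "high").astype(int)
    X = np.empty((spec.n, spec.p))

    informative = np.zeros(spec.p, dtype=bool)
    informative[rng.choice(spec.p, size=spec.k_informative, replace=False)] = True

    z = rng.standard_normal((spec.n, spec.p))
    n_blocks = int(np.ceil(spec.p / spec.block_size))
    shared = rng.standard_normal((spec.n, n_blocks))
    block_of = np.arange(spec.p) // spec.block_size
    r = abs(spec.rho)
    X = np.sqrt(r) * np.sign(spec.rho) * shared[:, block_of] + np.sqrt(1 - r) * z
    X[:, informative] = rng.standard_normal((spec.n, spec.k_informative))
    X[:, informative] += spec.effect_size * labels01[:, None]

    groups = split_assignment(spec.n, seed=int(rng.integers(2**31)))
    names = [f"f{j:04d}" for j in range(spec.p)]
    table = FeatureTable(
        sample_ids=[f"s{i:04d}" for i in range(spec.n)],
        feature_names=names,
        values=X,
        labels=labels01,
        groups=groups,
    )
    return table, informative
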