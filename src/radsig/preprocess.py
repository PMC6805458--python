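"""Volume/mask I/O, intensity normalization, isotropic resampling and validation.

Native clinical T2 volumes are anisotropic (slice thickness of several mm);
texture matrices assume comparable voxel neighbourhoods along every axis, so
each volume is z-normalized over all voxels and resampled to isotropic
spacing (default 1 mm) before feature extraction.  Masks travel with their
volume and are resampled with nearest-neighbour interpolation so they stay
binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

VALID_LABELS = ("low", "high")
VALID_GROUPS = ("training", "validation")


@dataclass(frozen=True)
class Volume3D:
    """A 3D intensity grid with voxel spacing in millimetres."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float64)
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"not a 3D volume: shape {v.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing {self.spacing}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class Mask3D:
    """A binary region-of-interest grid aligned with a :class:`Volume3D`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"not a 3D mask: shape {v.shape}")
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        object.__setattr__(self, "voxels", v.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing {self.spacing}")
        if not v.any():
            raise ValueError("mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class Sample:
    """One subject: image, ROI mask, VEGF label and train/validation group."""

    sample_id: str
    volume: Volume3D
    mask: Mask3D
    label: str
    group: str
    metadata: dict = field(default_factory=dict)


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # squeeze singleton trailing dimensions (e.g. shape (X, Y, Z, 1))
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: not a 3D volume (shape {data.shape})")
    zooms = img.header.get_zooms()[:3]
    return np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms)


def load_volume(path: str | Path) -> Volume3D:
    """Read a 3D NIfTI image; spacing is taken from the header zooms."""
    data, spacing = _load_nifti(path)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    return Volume3D(data, spacing)


def load_mask(path: str | Path) -> Mask3D:
    """Read a 3D NIfTI mask; any nonzero voxel is foreground."""
    data, spacing = _load_nifti(path)
    return Mask3D((data > 0).astype(np.uint8), spacing)


def save_volume(v: Volume3D | Mask3D, path: str | Path) -> None:
    """Write a volume or mask as NIfTI with a diagonal spacing affine."""
    affine = np.diag(list(v.spacing) + [1.0])
    arr = np.asarray(v.voxels, dtype=np.float64)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def znormalize(v: Volume3D) -> Volume3D:
    """Standardize all voxel intensities to zero mean and unit (population) SD."""
    mean = float(v.voxels.mean())
    sd = float(v.voxels.std())  # population convention, divisor N
    if sd == 0:
        raise ValueError("degenerate intensity distribution: constant volume (sd = 0)")
    return replace(v, voxels=(v.voxels - mean) / sd)


def resample_isotropic(
    v: Volume3D, m: Mask3D, target_mm: float = 1.0
) -> tuple[Volume3D, Mask3D]:
    """Resample a volume/mask pair to isotropic ``target_mm`` spacing.

    The volume is interpolated trilinearly, the mask with nearest neighbour
    and re-binarized.  ``grid_mode`` zoom semantics preserve the physical
    extent covered by the voxel grid.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    if v.shape != m.shape or v.spacing != m.spacing:
        raise ValueError("volume and mask are not aligned")
    factors = tuple(s / target_mm for s in v.spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        iso = (target_mm,) * 3
        return Volume3D(v.voxels.copy(), iso), Mask3D(m.voxels.copy(), iso)
    new_vox = ndimage.zoom(v.voxels, factors, order=1, mode="nearest", grid_mode=True)
    new_msk = ndimage.zoom(m.voxels, factors, order=0, mode="nearest", grid_mode=True)
    new_msk = (new_msk > 0).astype(np.uint8)
    if not new_msk.any():
        raise ValueError("ROI vanished under resampling")
    iso = (target_mm,) * 3
    return Volume3D(new_vox, iso), Mask3D(new_msk, iso)


def validate_sample(s: Sample) -> list[str]:
    """Return a list of human-readable issues; empty means the sample is usable.

    Never raises: this is a reporting operation used to build validation
    reports over whole manifests.
    """
    issues: list[str] = []
    vol = np.asarray(s.volume.voxels) if s.volume is not None else None
    msk = np.asarray(s.mask.voxels) if s.mask is not None else None
    if vol is not None and msk is not None:
        if vol.shape != msk.shape:
            issues.append(f"shape mismatch: volume {vol.shape} vs mask {msk.shape}")
        if s.volume.spacing != s.mask.spacing:
            issues.append(
                f"spacing mismatch: volume {s.volume.spacing} vs mask {s.mask.spacing}"
            )
        if not np.all(np.isin(np.unique(msk), (0, 1))):
            issues.append("mask is not binary")
        if not msk.any():
            issues.append("empty ROI")
        if not np.all(np.isfinite(vol)):
            issues.append("non-finite voxels")
    if s.label not in VALID_LABELS:
        issues.append(f"invalid label {s.label!r} (expected one of {VALID_LABELS})")
    if s.group not in VALID_GROUPS:
        issues.append(f"invalid group {s.group!r} (expected one of {VALID_GROUPS})")
    return issues


def preprocess_sample(s: Sample, target_mm: float = 1.0, order: str = "normalize-first") -> Sample:
    """Normalize and resample one sample.

    ``order`` selects ``normalize-first`` (default) or ``resample-first``;
    the original processing order is not fully determined, so both are
    supported.
    """
    if order not in ("normalize-first", "resample-first"):
        raise ValueError(f"unknown preprocessing order {order!r}")
    if order == "normalize-first":
        vol = znormalize(s.volume)
        vol, msk = resample_isotropic(vol, s.mask, target_mm)
    else:
        vol, msk = resample_isotropic(s.volume, s.mask, target_mm)
        vol = znormalize(vol)
    return Sample(s.sample_id, vol, msk, s.label, s.group, dict(s.metadata))
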