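"""Assembly of the 431-feature radiomic vector.

The vector is 14 first-order + 8 shape + 33 texture (22 GLCM + 11 GLRLM)
features on the original image, plus the 47 non-shape features recomputed on
each of the 8 undecimated wavelet sub-bands: 14 + 8 + 33 + 47*8 = 431.
Shape depends only on the mask, so it is not recomputed per band.  Wavelet
features are named ``"<Feature Name>_<BAND>"`` (e.g. ``Cluster
Tendency_HLL``); original-image features carry the bare name.

Quantization for the texture matrices uses each image's (or band's) own ROI
min/max, with a configurable number of gray levels (default 32).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from radsig.firstorder import FIRST_ORDER_NAMES, first_order_features
from radsig.preprocess import Mask3D, Volume3D
from radsig.shape import SHAPE_NAMES, shape_features
from radsig.texture import (
    DIRECTIONS_3D,
    GLCM_NAMES,
    GLRLM_NAMES,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    quantize,
)
from radsig.wavelet import BAND_NAMES, wavelet_decompose

# Energy, Entropy and Variance exist in both the first-order and GLCM sets;
# in the flat 431-name vector the first-order ones keep the bare name (the
# signature's "Entropy_LLL" is first-order derived) and the GLCM ones are
# qualified.
GLCM_VECTOR_NAMES = tuple(
    f"{n} (GLCM)" if n in FIRST_ORDER_NAMES else n for n in GLCM_NAMES
)
TEXTURE_NAMES = GLCM_VECTOR_NAMES + GLRLM_NAMES  # 33
N_FEATURES = 431


@dataclass(frozen=True)
class FeatureConfig:
    """Settings that determine the extracted feature values.

    n_bins: gray levels for texture quantization and the first-order
        histogram (Entropy/Uniformity).
    glcm_distance: voxel offset length for co-occurrence pairs.
    glcm_aggregate: 'sum' pools counts over the 13 directions before
        normalizing; 'mean' averages per-direction probability matrices.
    wavelet: filter family tag (informational; only coif1 is built in).
    """

    n_bins: int = 32
    glcm_distance: int = 1
    glcm_aggregate: str = "sum"
    wavelet: str = "coif1"

    def as_dict(self) -> dict:
        return asdict(self)


def feature_names() -> list[str]:
    """The documented, deterministic order of all 431 feature names."""
    names = list(FIRST_ORDER_NAMES) + list(SHAPE_NAMES) + list(TEXTURE_NAMES)
    for band in BAND_NAMES:
        for base in FIRST_ORDER_NAMES + TEXTURE_NAMES:
            names.append(f"{base}_{band}")
    assert len(names) == N_FEATURES
    return names


def _intensity_features(
    voxels: np.ndarray, mask: np.ndarray, cfg: FeatureConfig
) -> dict[str, float]:
    """First-order + GLCM + GLRLM features of one image (original or band)."""
    roi = voxels[mask]
    out = first_order_features(roi, n_bins=cfg.n_bins)
    levels, _ = quantize(voxels, mask, n_levels=cfg.n_bins)
    if cfg.glcm_distance != 1:
        dirs = tuple(
            tuple(cfg.glcm_distance * c for c in d) for d in DIRECTIONS_3D
        )
    else:
        dirs = DIRECTIONS_3D
    P = glcm(levels, cfg.n_bins, directions=dirs, aggregate=cfg.glcm_aggregate)
    gf = glcm_features(P)
    out.update({qn: gf[n] for n, qn in zip(GLCM_NAMES, GLCM_VECTOR_NAMES)})
    R = glrlm(levels, cfg.n_bins)
    out.update(glrlm_features(R, n_voxels=int(mask.sum())))
    return out


def extract_all(
    v: Volume3D, m: Mask3D, cfg: FeatureConfig | None = None
) -> dict[str, float]:
    """Extract the ordered 431-entry feature vector from one sample.

    Raises if the sample is degenerate (constant ROI, single-voxel ROI with
    no co-occurrences, ...) or if any feature comes out non-finite.
    """
    cfg = cfg or FeatureConfig()
    if v.shape != m.shape:
        raise ValueError(f"shape mismatch: volume {v.shape} vs mask {m.shape}")
    mask = m.voxels.astype(bool)

    vec: dict[str, float] = {}
    original = _intensity_features(v.voxels, mask, cfg)
    for name in FIRST_ORDER_NAMES:
        vec[name] = original[name]
    vec.update(shape_features(m))
    for name in TEXTURE_NAMES:
        vec[name] = original[name]

    bands = wavelet_decompose(v.voxels)
    for band in BAND_NAMES:
        feats = _intensity_features(bands[band], mask, cfg)
        for base in FIRST_ORDER_NAMES + TEXTURE_NAMES:
            vec[f"{base}_{band}"] = feats[base]

    assert len(vec) == N_FEATURES
    bad = [k for k, val in vec.items() if not np.isfinite(val)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad[:5]}")
    return vec
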