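"""Radiomic feature extraction: 107 features per modality, 214 per patient.

Per modality: 14 shape + 18 first-order intensity statistics (the 32
"first-order" block) and 24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM +
14 GLDM texture features (the 75 "textural" block).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from radpipe.features.discretize import DiscretizedVolume, discretize
from radpipe.features.firstorder import FIRSTORDER_NAMES, firstorder_features
from radpipe.features.shape import SHAPE_NAMES, shape_features
from radpipe.features.texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    texture_family_features,
)

N_FEATURES_PER_MODALITY = 107
N_FEATURES_TOTAL = 214


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the extraction stage."""

    n_bins: int = 32
    glcm_distance: int = 1
    mode: str = "3d"          # "3d": 13 directions / 26-neighborhoods; "2d": per-slice

    def __post_init__(self) -> None:
        if self.mode not in ("3d", "2d"):
            raise ValueError("mode must be '3d' or '2d'")


def base_features(values: np.ndarray, mask: np.ndarray, spacing,
                  levels: np.ndarray | None = None) -> OrderedDict:
    """The 32 first-order features: 14 shape + 18 intensity statistics."""
    out = OrderedDict()
    for k, v in shape_features(mask, spacing).items():
        out[f"shape_{k}"] = v
    vv = float(np.prod(spacing))
    for k, v in firstorder_features(values, levels=levels, voxel_volume=vv).items():
        out[f"firstorder_{k}"] = v
    return out


def extract_modality_features(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing,
    config: FeatureConfig | None = None,
) -> OrderedDict:
    """All 107 features for one modality, as an ordered name -> value map."""
    cfg = config or FeatureConfig()
    mask = np.asarray(mask, dtype=bool)
    disc = discretize(volume, mask, cfg.n_bins)
    values = np.asarray(volume, dtype=float)[mask]

    out = base_features(values, mask, spacing, levels=disc.levels[mask])
    for k, v in glcm_features(disc, cfg.glcm_distance, cfg.mode).items():
        out[f"glcm_{k}"] = v
    for k, v in glrlm_features(disc, cfg.mode).items():
        out[f"glrlm_{k}"] = v
    for k, v in glszm_features(disc, cfg.mode).items():
        out[f"glszm_{k}"] = v
    for k, v in ngtdm_features(disc, cfg.mode).items():
        out[f"ngtdm_{k}"] = v
    for k, v in gldm_features(disc, cfg.mode).items():
        out[f"gldm_{k}"] = v
    assert len(out) == N_FEATURES_PER_MODALITY
    return out


def extract_feature_vector(pair, mask_t1c, mask_t2,
                           config: FeatureConfig | None = None) -> pd.Series:
    """Two-modality feature vector: 107 ``T1_`` + 107 ``T2_`` named values.

    ``mask_t1c`` / ``mask_t2`` may be raw boolean arrays or TumorMask
    objects on the respective grids; the ordering of the returned Series
    is fixed across runs.
    """
    m1 = getattr(mask_t1c, "mask", mask_t1c)
    m2 = getattr(mask_t2, "mask", mask_t2)
    out = OrderedDict()
    for k, v in extract_modality_features(pair.volume_t1c, m1, pair.spacing, config).items():
        out[f"T1_{k}"] = v
    for k, v in extract_modality_features(pair.volume_t2, m2, pair.spacing, config).items():
        out[f"T2_{k}"] = v
    assert len(out) == N_FEATURES_TOTAL
    return pd.Series(out)


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """The fixed, documented 214-name ordering of the feature vector."""
    per_mod = (
        [f"shape_{k}" for k in SHAPE_NAMES]
        + [f"firstorder_{k}" for k in FIRSTORDER_NAMES]
        + [f"glcm_{k}" for k in GLCM_NAMES]
        + [f"glrlm_{k}" for k in GLRLM_NAMES]
        + [f"glszm_{k}" for k in GLSZM_NAMES]
        + [f"ngtdm_{k}" for k in NGTDM_NAMES]
        + [f"gldm_{k}" for k in GLDM_NAMES]
    )
    return [f"T1_{k}" for k in per_mod] + [f"T2_{k}" for k in per_mod]


__all__ = [
    "DiscretizedVolume", "discretize", "FeatureConfig",
    "base_features", "firstorder_features", "shape_features",
    "glcm_features", "glrlm_features", "glszm_features", "ngtdm_features",
    "gldm_features", "texture_family_features",
    "extract_modality_features", "extract_feature_vector", "feature_names",
    "N_FEATURES_PER_MODALITY", "N_FEATURES_TOTAL",
    "SHAPE_NAMES", "FIRSTORDER_NAMES", "GLCM_NAMES", "GLRLM_NAMES",
    "GLSZM_NAMES", "NGTDM_NAMES", "GLDM_NAMES",
]
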