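"""NIfTI and table I/O."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


class VolumeIOError(IOError):
    """Raised when a volume or mask file cannot be parsed."""


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    nib.save(img, path)
    return path


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.asarray(affine))
    nib.save(img, path)
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    """Load a NIfTI volume; returns ``(data, spacing, affine)``."""
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asarray(img.get_fdata())
        affine = np.asarray(img.affine)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # noqa: BLE001
        raise VolumeIOError(f"cannot parse NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return data, spacing, affine


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    data, spacing, affine = load_volume(path)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise VolumeIOError(f"{path}: mask voxels must be 0/1, found {uniq[:5]}")
    return data.astype(bool), spacing, affine


def load_covariates(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise VolumeIOError(f"cannot parse covariate table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VolumeIOError(f"{path}: missing required column(s) {missing}")
    return df
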