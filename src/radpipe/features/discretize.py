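"""Fixed-bin-count gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizedVolume:
    """Integer gray levels 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray           # int array, full grid, 0 = outside mask
    n_levels: int                # number of distinct levels possible (bin count)
    mapping: tuple[float, float]  # (min, max) intensity used for binning

    def __post_init__(self) -> None:
        inside = self.levels[self.levels > 0]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, n_levels]")


def discretize(volume: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> DiscretizedVolume:
    """Discretize in-mask intensities into ``n_bins`` equal-width levels.

    ``level = floor((x - min) / (max - min) * n_bins) + 1`` with the
    maximum mapped into the top bin; a constant region maps entirely to
    level 1.  Fixed-bin-count binning makes every downstream texture
    feature invariant to positive affine intensity rescaling.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(volume, dtype=float)
    lo, hi = float(x[mask].min()), float(x[mask].max())
    levels = np.zeros(x.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
    else:
        binned = np.floor((x[mask] - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
        levels[mask] = np.minimum(binned, n_bins)
    return DiscretizedVolume(levels=levels, n_levels=n_bins, mapping=(lo, hi))
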