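"""Direction and neighborhood offsets for 3D/2D texture matrices."""

from __future__ import annotations

from itertools import product

import numpy as np


def direction_offsets(mode: str = "3d", distance: int = 1) -> list[tuple[int, int, int]]:
    """Unique (up to sign) voxel offsets: 13 in 3D, 4 in-plane in 2D."""
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        if mode == "2d" and d[2] != 0:
            continue
        # keep one representative of each +/- pair
        if d[2] > 0 or (d[2] == 0 and (d[1] > 0 or (d[1] == 0 and d[0] > 0))):
            offs.append(tuple(distance * c for c in d))
    return offs


def neighbor_offsets(mode: str = "3d") -> list[tuple[int, int, int]]:
    """All 26 (3D) or in-plane 8 (2D) unit neighborhood offsets."""
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        if mode == "2d" and d[2] != 0:
            continue
        offs.append(d)
    return offs


def zone_structure(mode: str = "3d") -> np.ndarray:
    """Connectivity structuring element for zone labeling."""
    s = np.ones((3, 3, 3), dtype=bool)
    if mode == "2d":
        s[:, :, 0] = s[:, :, 2] = False
    return s


def crop_to_mask(levels: np.ndarray, margin: int = 0) -> np.ndarray:
    """Crop a level array (0 = outside mask) to the mask bounding box."""
    nz = np.nonzero(levels)
    slices = tuple(
        slice(max(int(a.min()) - margin, 0), int(a.max()) + 1 + margin) for a in nz
    )
    return levels[slices]
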