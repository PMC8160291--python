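"""Automatic tumor delineation on the contrast channel.

Slice-wise two-cluster fuzzy c-means inside an operator seed box,
followed by 3D largest-component selection and hole filling, plus affine
mapping of the final mask onto the second channel's grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class DegenerateInputError(ValueError):
    """Clustering input has no intensity variation."""


class SegmentationError(RuntimeError):
    """Post-processed mask is empty; manual correction would be required."""


@dataclass
class VolumePair:
    """Two co-registered 3D intensity volumes for one patient."""

    volume_t1c: np.ndarray
    volume_t2: np.ndarray
    spacing: tuple[float, float, float]
    affine_t1c: np.ndarray
    affine_t2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("volume_t1c", "volume_t2"):
            v = getattr(self, name)
            if np.ndim(v) != 3:
                raise ValueError(f"{name} must be 3D, got ndim={np.ndim(v)}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for name in ("affine_t1c", "affine_t2"):
            a = np.asarray(getattr(self, name))
            if a.shape != (4, 4) or abs(np.linalg.det(a)) < 1e-12:
                raise ValueError(f"{name} must be an invertible 4x4 affine")


@dataclass
class TumorMask:
    """Binary 3D mask aligned with a reference grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SeedBox:
    """Operator-supplied initial region: axial slice range + in-plane rectangle.

    ``rectangle`` is ``(x0, x1, y0, y1)`` with exclusive upper bounds, in
    0-based voxel indices on the first two axes; slices index the third.
    """

    slice_first: int
    slice_last: int
    rectangle: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.slice_first > self.slice_last:
            raise ValueError("slice_first must be <= slice_last")
        x0, x1, y0, y1 = self.rectangle
        if x0 >= x1 or y0 >= y1 or min(x0, y0) < 0:
            raise ValueError(f"invalid rectangle {self.rectangle}")

    def validate_for(self, shape: tuple[int, ...]) -> None:
        x0, x1, y0, y1 = self.rectangle
        if x1 > shape[0] or y1 > shape[1] or self.slice_last >= shape[2]:
            raise ValueError(f"seed box {self} exceeds grid {shape}")


def fcm_cluster(
    values: np.ndarray,
    n_clusters: int = 2,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means on a 1D intensity sample.

    Standard fixed-point iteration: memberships
    ``u_ik proportional to (1/|x_i - c_k|)^(2/(m-1))`` row-normalized,
    centroids ``c_k = sum(u^m x) / sum(u^m)``, stopped when the largest
    centroid move is below ``tol`` or after ``max_iter`` sweeps.
    Centroids are initialized deterministically at evenly spread intensity
    quantiles (0.25/0.75 for two clusters); ``seed`` is only consulted for
    the optional random initialization and is unused by default.

    Returns ``(memberships, centroids)`` with memberships of shape
    ``(n_values, n_clusters)`` summing to 1 per row and centroids sorted
    ascending.
    """
    x = np.asarray(values, dtype=float).ravel()
    if fuzziness <= 1:
        raise ValueError("fuzziness must be > 1")
    if x.size == 0 or np.ptp(x) == 0:
        raise DegenerateInputError("all input values are identical")
    if np.unique(x).size < n_clusters:
        raise DegenerateInputError(
            f"need >= {n_clusters} distinct values, got {np.unique(x).size}")

    q = (np.arange(n_clusters) + 0.5) / n_clusters
    centroids = np.quantile(x, q)
    if np.unique(centroids).size < n_clusters:
        # heavily skewed histograms can collapse the quantiles; fall back to
        # quantiles of the distinct-value support, which are always separated
        centroids = np.quantile(np.unique(x), q)

    expo = 2.0 / (fuzziness - 1.0)
    u = np.empty((x.size, n_clusters))
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centroids[None, :])
        zero = d < 1e-12
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            inv = d ** (-expo)
            u = inv / inv.sum(axis=1, keepdims=True)
        # exact-hit rows: full membership split among coincident centroids
        hit = zero.any(axis=1)
        if hit.any():
            u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        um = u ** fuzziness
        new_centroids = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            break
    order = np.argsort(centroids)
    return u[:, order], centroids[order]


@dataclass(frozen=True)
class SegmentationConfig:
    n_clusters: int = 2
    fuzziness: float = 2.0
    tol: float = 1e-5
    max_iter: int = 200
    membership_threshold: float = 0.5


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _postprocess(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 26-connected component, then fill enclosed holes."""
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    # 3D filling misses holes open along the slice axis; per-slice 2D pass
    for z in range(mask.shape[2]):
        mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    return mask


def segment_volume(
    pair: VolumePair,
    box: SeedBox,
    config: SegmentationConfig | None = None,
) -> TumorMask:
    """Segment the lesion on the contrast channel within a seed box.

    Per axial slice in the box, two-cluster FCM splits the in-box
    intensities; the cluster with the higher centroid is the tumor and
    voxels with tumor membership above 0.5 are kept.  The stacked slices
    are reduced to the largest 26-connected 3D component and holes are
    filled.  Slices without intensity variation contribute nothing.
    """
    cfg = config or SegmentationConfig()
    vol = pair.volume_t1c
    box.validate_for(vol.shape)
    x0, x1, y0, y1 = box.rectangle

    mask = np.zeros(vol.shape, dtype=bool)
    for z in range(box.slice_first, box.slice_last + 1):
        patch = vol[x0:x1, y0:y1, z]
        try:
            u, centroids = fcm_cluster(
                patch.ravel(), n_clusters=cfg.n_clusters, fuzziness=cfg.fuzziness,
                tol=cfg.tol, max_iter=cfg.max_iter)
        except DegenerateInputError:
            continue
        tumor_cluster = int(np.argmax(centroids))
        in_tumor = u[:, tumor_cluster] > cfg.membership_threshold
        mask[x0:x1, y0:y1, z] = in_tumor.reshape(patch.shape)

    mask = _postprocess(mask)
    if not mask.any():
        raise SegmentationError(
            "segmentation produced an empty mask; supply an external mask instead")
    return TumorMask(mask=mask, spacing=pair.spacing, affine=pair.affine_t1c)


def map_mask(
    mask: TumorMask,
    affine_src: np.ndarray,
    affine_dst: np.ndarray,
    dst_shape: tuple[int, int, int],
    dst_spacing: tuple[float, float, float] | None = None,
) -> TumorMask:
    """Resample a binary mask onto another grid through the composed affine.

    The destination voxel grid is pulled back through
    ``inv(affine_src) @ affine_dst``, interpolated linearly and
    re-binarized at 0.5.
    """
    src = np.asarray(affine_src, dtype=float)
    dst = np.asarray(affine_dst, dtype=float)
    for name, a in (("affine_src", src), ("affine_dst", dst)):
        if a.shape != (4, 4) or abs(np.linalg.det(a)) < 1e-12:
            raise ValueError(f"{name} must be an invertible 4x4 affine")
    compose = np.linalg.inv(src) @ dst
    out = ndimage.affine_transform(
        mask.mask.astype(float), matrix=compose[:3, :3], offset=compose[:3, 3],
        output_shape=tuple(dst_shape), order=1, mode="constant", cval=0.0)
    binary = out >= 0.5
    if not binary.any():
        raise SegmentationError("mapped mask is empty on the destination grid")
    spacing = dst_spacing or mask.spacing
    return TumorMask(mask=binary, spacing=spacing, affine=dst)
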