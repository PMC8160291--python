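"""Texture-matrix feature families: GLCM, GLRLM, GLSZM, NGTDM, GLDM.

All families operate on a :class:`~radpipe.features.discretize.DiscretizedVolume`
level array (integer levels 1..Ng inside the mask, 0 outside).  Matrices
are built in 3D with distance-1 offsets (13 unique directions, 26-voxel
neighborhoods) by default; a 2D per-slice mode restricts offsets to the
axial plane.  GLCM and GLRLM features are computed per direction and
averaged over directions.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
from scipy import ndimage

from radpipe.features._offsets import (
    crop_to_mask,
    direction_offsets,
    neighbor_offsets,
    zone_structure,
)

_EPS = np.spacing(1.0)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# GLCM

def _glcm_matrix(lv: np.ndarray, offset: tuple[int, int, int], ng: int) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one offset."""
    sl_a, sl_b = [], []
    for o, n in zip(offset, lv.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    a, b = lv[tuple(sl_a)], lv[tuple(sl_b)]
    valid = (a > 0) & (b > 0)
    idx = (a[valid] - 1) * ng + (b[valid] - 1)
    c = np.bincount(idx, minlength=ng * ng).reshape(ng, ng).astype(float)
    return c + c.T


def _glcm_features_single(p: np.ndarray) -> OrderedDict:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = i[:, None].astype(float), i[None, :].astype(float)
    px, py = p.sum(axis=1), p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    ksum = (ii + jj).astype(int)            # 2..2Ng
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    kdiff = np.abs(ii - jj).astype(int)     # 0..Ng-1
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)

    hx, hy, hxy = _entropy(px), _entropy(py), _entropy(p)
    outer = px[:, None] * py[None, :]
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(outer[nz] + _EPS)).sum())
    onz = outer > 0
    hxy2 = float(-(outer[onz] * np.log2(outer[onz])).sum())

    f = OrderedDict()
    f["Autocorrelation"] = float((ii * jj * p).sum())
    f["JointAverage"] = mu_x
    dev = ii + jj - mu_x - mu_y
    f["ClusterProminence"] = float((dev ** 4 * p).sum())
    f["ClusterShade"] = float((dev ** 3 * p).sum())
    f["ClusterTendency"] = float((dev ** 2 * p).sum())
    f["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sig_x > 0 and sig_y > 0:
        f["Correlation"] = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        f["Correlation"] = 1.0
    kd = np.arange(ng, dtype=float)
    da = float((kd * p_diff).sum())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = _entropy(p_diff)
    f["DifferenceVariance"] = float(((kd - da) ** 2 * p_diff).sum())
    f["JointEnergy"] = float((p ** 2).sum())
    f["JointEntropy"] = hxy
    div = max(hx, hy)
    f["Imc1"] = float((hxy - hxy1) / div) if div > 0 else 0.0
    f["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    f["Idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    f["Idmn"] = float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum())
    f["Id"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    f["Idn"] = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    off_diag = ~np.eye(ng, dtype=bool)
    f["InverseVariance"] = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum())
    f["MaximumProbability"] = float(p.max())
    ks = np.arange(2, 2 * ng + 1, dtype=float)
    f["SumAverage"] = float((ks * p_sum).sum())
    f["SumEntropy"] = _entropy(p_sum)
    f["SumSquares"] = float(((ii - mu_x) ** 2 * p).sum())
    f["MCC"] = _glcm_mcc(p, px, py)
    return f


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the 2nd eigenvalue of Q."""
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    pr = p[np.ix_(keep, keep)]
    a = pr / px[keep][:, None]
    b = pr / py[keep][None, :]
    q = a @ b.T
    eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
    return float(np.sqrt(np.clip(eig[1], 0.0, 1.0)))


GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]


def glcm_features(disc, distance: int = 1, mode: str = "3d",
                  offsets: list[tuple[int, int, int]] | None = None) -> OrderedDict:
    """24 co-occurrence features, averaged over directions.

    Per direction the symmetric co-occurrence matrix is normalized to a
    probability table; directions with no valid voxel pair are skipped.
    """
    lv = crop_to_mask(disc.levels)
    ng = disc.n_levels
    offsets = offsets if offsets is not None else direction_offsets(mode, distance)
    acc: dict[str, list[float]] = {k: [] for k in GLCM_NAMES}
    for off in offsets:
        c = _glcm_matrix(lv, off, ng)
        total = c.sum()
        if total == 0:
            continue
        for k, v in _glcm_features_single(c / total).items():
            acc[k].append(v)
    if not acc["Contrast"]:
        raise ValueError("no valid voxel pairs for any GLCM direction")
    return OrderedDict((k, float(np.mean(acc[k]))) for k in GLCM_NAMES)


# ---------------------------------------------------------------------------
# GLRLM

def _glrlm_matrix(lv: np.ndarray, offset: tuple[int, int, int], ng: int) -> np.ndarray:
    """Run-length count matrix for one direction (rows: level, cols: length)."""
    shape = np.array(lv.shape)
    off = np.array(offset)
    idx = np.indices(lv.shape).reshape(3, -1)
    prev = idx - off[:, None]
    is_start = ((prev < 0) | (prev >= shape[:, None])).any(axis=0)
    starts = idx[:, is_start]
    lmax = int(shape[np.abs(off) > 0].min())
    ks = np.arange(lmax)
    pos = starts[:, :, None] + off[:, None, None] * ks[None, None, :]
    valid = ((pos >= 0) & (pos < shape[:, None, None])).all(axis=0)
    vals = np.zeros((starts.shape[1], lmax), dtype=np.int64)
    pv = pos[:, valid]
    vals[valid] = lv[pv[0], pv[1], pv[2]]
    # zero separator column so runs cannot leak across lines
    flat = np.concatenate([vals, np.zeros((vals.shape[0], 1), np.int64)], axis=1).ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    run_vals = flat[bounds[:-1]]
    run_lens = np.diff(bounds)
    keep = run_vals > 0
    mat = np.zeros((ng, lmax), dtype=np.int64)
    np.add.at(mat, (run_vals[keep] - 1, run_lens[keep] - 1), 1)
    return mat


GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]


def _weighted_matrix_features(mat: np.ndarray, n_voxels: int,
                              col_name: str) -> OrderedDict:
    """Shared emphasis/non-uniformity feature block for level-by-size matrices.

    ``mat[g, s]`` counts runs/zones/dependencies of gray level ``g+1`` and
    size ``s+1``; the same algebra serves GLRLM (size = run length), GLSZM
    (size = zone area) and GLDM (size = dependence).
    """
    total = float(mat.sum())
    ng, ns = mat.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    s = np.arange(1, ns + 1, dtype=float)[None, :]
    m = mat.astype(float)
    p = m / total
    row = m.sum(axis=1)
    col = m.sum(axis=0)

    f = OrderedDict()
    f[f"Short{col_name}Emphasis"] = float((m / s ** 2).sum() / total)
    f[f"Long{col_name}Emphasis"] = float((m * s ** 2).sum() / total)
    f["GrayLevelNonUniformity"] = float((row ** 2).sum() / total)
    f["GrayLevelNonUniformityNormalized"] = float((row ** 2).sum() / total ** 2)
    f[f"{col_name}NonUniformity"] = float((col ** 2).sum() / total)
    f[f"{col_name}NonUniformityNormalized"] = float((col ** 2).sum() / total ** 2)
    f[f"{col_name}Percentage"] = float(total / n_voxels)
    mu_i = float((p * i).sum())
    f["GrayLevelVariance"] = float((p * (i - mu_i) ** 2).sum())
    mu_s = float((p * s).sum())
    f[f"{col_name}Variance"] = float((p * (s - mu_s) ** 2).sum())
    f[f"{col_name}Entropy"] = _entropy(p.ravel())
    f["LowGrayLevelEmphasis"] = float((m / i ** 2).sum() / total)
    f["HighGrayLevelEmphasis"] = float((m * i ** 2).sum() / total)
    f["ShortLow"] = float((m / (i ** 2 * s ** 2)).sum() / total)
    f["ShortHigh"] = float((m * i ** 2 / s ** 2).sum() / total)
    f["LongLow"] = float((m * s ** 2 / i ** 2).sum() / total)
    f["LongHigh"] = float((m * i ** 2 * s ** 2).sum() / total)
    return f


def glrlm_features(disc, mode: str = "3d") -> OrderedDict:
    """16 run-length features, averaged over directions."""
    lv = crop_to_mask(disc.levels)
    n_voxels = int((lv > 0).sum())
    acc: dict[str, list[float]] = {k: [] for k in GLRLM_NAMES}
    for off in direction_offsets(mode, 1):
        mat = _glrlm_matrix(lv, off, disc.n_levels)
        if mat.sum() == 0:
            continue
        g = _weighted_matrix_features(mat, n_voxels, "Run")
        vals = {
            "ShortRunEmphasis": g["ShortRunEmphasis"],
            "LongRunEmphasis": g["LongRunEmphasis"],
            "GrayLevelNonUniformity": g["GrayLevelNonUniformity"],
            "GrayLevelNonUniformityNormalized": g["GrayLevelNonUniformityNormalized"],
            "RunLengthNonUniformity": g["RunNonUniformity"],
            "RunLengthNonUniformityNormalized": g["RunNonUniformityNormalized"],
            "RunPercentage": g["RunPercentage"],
            "GrayLevelVariance": g["GrayLevelVariance"],
            "RunVariance": g["RunVariance"],
            "RunEntropy": g["RunEntropy"],
            "LowGrayLevelRunEmphasis": g["LowGrayLevelEmphasis"],
            "HighGrayLevelRunEmphasis": g["HighGrayLevelEmphasis"],
            "ShortRunLowGrayLevelEmphasis": g["ShortLow"],
            "ShortRunHighGrayLevelEmphasis": g["ShortHigh"],
            "LongRunLowGrayLevelEmphasis": g["LongLow"],
            "LongRunHighGrayLevelEmphasis": g["LongHigh"],
        }
        for k, v in vals.items():
            acc[k].append(v)
    if not acc["RunPercentage"]:
        raise ValueError("empty mask: no runs in any direction")
    return OrderedDict((k, float(np.mean(acc[k]))) for k in GLRLM_NAMES)


# ---------------------------------------------------------------------------
# GLSZM

GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]


def glszm_matrix(disc, mode: str = "3d") -> np.ndarray:
    """Zone count matrix ``P[g-1, s-1]``: zones of level g and size s.

    Zones are maximal connected sets of equal gray level (26-connectivity
    in 3D, 8-connectivity per slice in 2D).
    """
    lv = crop_to_mask(disc.levels)
    struct = zone_structure(mode)
    zones: list[tuple[int, int]] = []
    for g in np.unique(lv[lv > 0]):
        lab, n = ndimage.label(lv == g, structure=struct)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    smax = max(s for _, s in zones)
    mat = np.zeros((disc.n_levels, smax), dtype=np.int64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def glszm_features(disc, mode: str = "3d") -> OrderedDict:
    """16 size-zone features; gray-level non-uniformity is
    ``sum_g (sum_s P(g,s))^2 / N_z``."""
    lv = crop_to_mask(disc.levels)
    n_voxels = int((lv > 0).sum())
    if n_voxels == 0:
        raise ValueError("mask is empty")
    mat = glszm_matrix(disc, mode)
    g = _weighted_matrix_features(mat, n_voxels, "Zone")
    return OrderedDict([
        ("SmallAreaEmphasis", g["ShortZoneEmphasis"]),
        ("LargeAreaEmphasis", g["LongZoneEmphasis"]),
        ("GrayLevelNonUniformity", g["GrayLevelNonUniformity"]),
        ("GrayLevelNonUniformityNormalized", g["GrayLevelNonUniformityNormalized"]),
        ("SizeZoneNonUniformity", g["ZoneNonUniformity"]),
        ("SizeZoneNonUniformityNormalized", g["ZoneNonUniformityNormalized"]),
        ("ZonePercentage", g["ZonePercentage"]),
        ("GrayLevelVariance", g["GrayLevelVariance"]),
        ("ZoneVariance", g["ZoneVariance"]),
        ("ZoneEntropy", g["ZoneEntropy"]),
        ("LowGrayLevelZoneEmphasis", g["LowGrayLevelEmphasis"]),
        ("HighGrayLevelZoneEmphasis", g["HighGrayLevelEmphasis"]),
        ("SmallAreaLowGrayLevelEmphasis", g["ShortLow"]),
        ("SmallAreaHighGrayLevelEmphasis", g["ShortHigh"]),
        ("LargeAreaLowGrayLevelEmphasis", g["LongLow"]),
        ("LargeAreaHighGrayLevelEmphasis", g["LongHigh"]),
    ])


# ---------------------------------------------------------------------------
# neighborhood accumulation shared by NGTDM / GLDM

def _neighbor_slices(shape, off):
    sl_c, sl_n = [], []
    for o, n in zip(off, shape):
        if o >= 0:
            sl_c.append(slice(0, n - o))
            sl_n.append(slice(o, n))
        else:
            sl_c.append(slice(-o, n))
            sl_n.append(slice(0, n + o))
    return tuple(sl_c), tuple(sl_n)


NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def ngtdm_features(disc, mode: str = "3d") -> OrderedDict:
    """5 neighborhood gray-tone difference features.

    For each in-mask voxel with at least one in-mask neighbor, the
    absolute difference between its level and the mean level of its valid
    neighbors is accumulated per gray level.
    """
    lv = crop_to_mask(disc.levels)
    ng = disc.n_levels
    nsum = np.zeros(lv.shape)
    ncnt = np.zeros(lv.shape)
    for off in neighbor_offsets(mode):
        sl_c, sl_n = _neighbor_slices(lv.shape, off)
        nb = lv[sl_n]
        nsum[sl_c] += np.where(nb > 0, nb, 0)
        ncnt[sl_c] += nb > 0
    valid = (lv > 0) & (ncnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(valid, nsum / np.maximum(ncnt, 1), 0.0)
    diffs = np.abs(lv - a)[valid]
    lv_valid = lv[valid]
    n = np.bincount(lv_valid - 1, minlength=ng).astype(float)
    s = np.bincount(lv_valid - 1, weights=diffs, minlength=ng)

    nvp = n.sum()
    if nvp == 0:
        raise ValueError("no voxel has any in-mask neighbor")
    p = n / nvp
    i = np.arange(1, ng + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())

    f = OrderedDict()
    denom = float((p * s).sum())
    f["Coarseness"] = 1.0 / denom if denom != 0 else 1e6
    if ngp > 1:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        f["Contrast"] = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * s.sum() / nvp)
        bus_den = float(np.abs(ii * pi - jj * pj).sum())
        f["Busyness"] = denom / bus_den if bus_den != 0 else 0.0
        si, sj = np.meshgrid(s[present], s[present], indexing="ij")
        f["Complexity"] = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / nvp)
        s_tot = float(s.sum())
        f["Strength"] = float(((pi + pj) * (ii - jj) ** 2).sum()) / s_tot \
            if s_tot != 0 else 0.0
    else:
        f["Contrast"] = 0.0
        f["Busyness"] = 0.0
        f["Complexity"] = 0.0
        f["Strength"] = 0.0
    return f


GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]


def gldm_features(disc, mode: str = "3d", alpha: int = 0) -> OrderedDict:
    """14 gray-level dependence features.

    The dependence of a voxel is one plus the number of neighbors whose
    level differs from the center by at most ``alpha`` (default 0).
    """
    lv = crop_to_mask(disc.levels)
    ng = disc.n_levels
    offsets = neighbor_offsets(mode)
    cnt = np.zeros(lv.shape, dtype=np.int64)
    for off in offsets:
        sl_c, sl_n = _neighbor_slices(lv.shape, off)
        nb, ce = lv[sl_n], lv[sl_c]
        cnt[sl_c] += (nb > 0) & (ce > 0) & (np.abs(nb - ce) <= alpha)
    m = lv > 0
    if not m.any():
        raise ValueError("mask is empty")
    dep = cnt[m] + 1
    mat = np.zeros((ng, len(offsets) + 1), dtype=np.int64)
    np.add.at(mat, (lv[m] - 1, dep - 1), 1)

    g = _weighted_matrix_features(mat, int(m.sum()), "Dependence")
    return OrderedDict([
        ("SmallDependenceEmphasis", g["ShortDependenceEmphasis"]),
        ("LargeDependenceEmphasis", g["LongDependenceEmphasis"]),
        ("GrayLevelNonUniformity", g["GrayLevelNonUniformity"]),
        ("DependenceNonUniformity", g["DependenceNonUniformity"]),
        ("DependenceNonUniformityNormalized", g["DependenceNonUniformityNormalized"]),
        ("GrayLevelVariance", g["GrayLevelVariance"]),
        ("DependenceVariance", g["DependenceVariance"]),
        ("DependenceEntropy", g["DependenceEntropy"]),
        ("LowGrayLevelEmphasis", g["LowGrayLevelEmphasis"]),
        ("HighGrayLevelEmphasis", g["HighGrayLevelEmphasis"]),
        ("SmallDependenceLowGrayLevelEmphasis", g["ShortLow"]),
        ("SmallDependenceHighGrayLevelEmphasis", g["ShortHigh"]),
        ("LargeDependenceLowGrayLevelEmphasis", g["LongLow"]),
        ("LargeDependenceHighGrayLevelEmphasis", g["LongHigh"]),
    ])


_FAMILY_DISPATCH = {
    "GLRLM": (glrlm_features, GLRLM_NAMES),
    "NGTDM": (ngtdm_features, NGTDM_NAMES),
    "GLDM": (gldm_features, GLDM_NAMES),
}


def texture_family_features(disc, family: str, mode: str = "3d") -> OrderedDict:
    """Dispatch to GLRLM (16), NGTDM (5) or GLDM (14) feature blocks."""
    try:
        fn, _ = _FAMILY_DISPATCH[family.upper()]
    except KeyError:
        raise ValueError(
            f"unknown texture family {family!r}; expected one of "
            f"{sorted(_FAMILY_DISPATCH)}") from None
    return fn(disc, mode=mode)
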