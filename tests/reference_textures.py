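"""Independent, loop-based reference implementations of the texture families.

Deliberately naive: matrices are accumulated voxel by voxel and features
are computed with explicit sums straight from their definitions, sharing
no code with the package implementation.  Used as the oracle for
equivalence tests.
"""

from __future__ import annotations

import math
from collections import defaultdict, deque

import numpy as np

OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in_grid(p, shape):
    return all(0 <= p[a] < shape[a] for a in range(3))


# ---------------------------------------------------------------------------
# GLCM

def ref_glcm_matrix(levels, ng, offset):
    p = np.zeros((ng, ng))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                q = (x + offset[0], y + offset[1], z + offset[2])
                if a == 0 or not _in_grid(q, shape):
                    continue
                b = levels[q]
                if b == 0:
                    continue
                p[a - 1, b - 1] += 1
                p[b - 1, a - 1] += 1
    return p


def ref_glcm_features(levels, ng, offset):
    c = ref_glcm_matrix(levels, ng, offset)
    total = c.sum()
    if total == 0:
        return None
    p = c / total
    px = [p[i, :].sum() for i in range(ng)]
    py = [p[:, j].sum() for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))

    psum = defaultdict(float)
    pdiff = defaultdict(float)
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hx, hy, hxy = ent(px), ent(py), ent(p.ravel())
    eps = np.spacing(1.0)
    hxy1 = -sum(p[i, j] * math.log2(px[i] * py[j] + eps)
                for i in range(ng) for j in range(ng) if p[i, j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if px[i] * py[j] > 0)

    f = {}
    f["Autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j]
                               for i in range(ng) for j in range(ng))
    f["JointAverage"] = mux
    for name, k in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
        f[name] = sum((i + 1 + j + 1 - mux - muy) ** k * p[i, j]
                      for i in range(ng) for j in range(ng))
    f["Contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    if sigx > 0 and sigy > 0:
        f["Correlation"] = (f["Autocorrelation"] - mux * muy) / (sigx * sigy)
    else:
        f["Correlation"] = 1.0
    da = sum(k * v for k, v in pdiff.items())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = ent(pdiff.values())
    f["DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    f["JointEnergy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["JointEntropy"] = hxy
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["Idm"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["Idmn"] = sum(p[i, j] / (1 + ((i - j) / ng) ** 2)
                    for i in range(ng) for j in range(ng))
    f["Id"] = sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["Idn"] = sum(p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    f["InverseVariance"] = sum(p[i, j] / (i - j) ** 2
                               for i in range(ng) for j in range(ng) if i != j)
    f["MaximumProbability"] = p.max()
    f["SumAverage"] = sum(k * v for k, v in psum.items())
    f["SumEntropy"] = ent(psum.values())
    f["SumSquares"] = sum((i + 1 - mux) ** 2 * p[i, j]
                          for i in range(ng) for j in range(ng))
    keep = [i for i in range(ng) if px[i] > 0]
    if len(keep) < 2:
        f["MCC"] = 1.0
    else:
        q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                q[a, b] = sum(p[i, k] * p[j, k] / (px[i] * py[k])
                              for k in keep if py[k] > 0)
        eig = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
        f["MCC"] = math.sqrt(min(max(eig[1], 0.0), 1.0))
    return f


def ref_glcm_averaged(levels, ng, offsets=OFFSETS_13):
    per_dir = [ref_glcm_features(levels, ng, off) for off in offsets]
    per_dir = [d for d in per_dir if d is not None]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM

def ref_glrlm_matrix(levels, offset):
    """Runs found by walking each line voxel by voxel."""
    shape = levels.shape
    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                prev = (x - offset[0], y - offset[1], z - offset[2])
                if _in_grid(prev, shape):
                    continue          # not a line start
                cur, length = 0, 0
                p = (x, y, z)
                while _in_grid(p, shape):
                    v = levels[p]
                    if v == cur:
                        length += 1
                    else:
                        if cur > 0:
                            runs.append((cur, length))
                        cur, length = v, 1
                    p = (p[0] + offset[0], p[1] + offset[1], p[2] + offset[2])
                if cur > 0:
                    runs.append((cur, length))
    return runs


def _ref_size_features(pairs, n_voxels, kind):
    """Feature block shared by the run/zone/dependence families."""
    nr = len(pairs)
    f = {}
    f["Short"] = sum(1.0 / s ** 2 for _, s in pairs) / nr
    f["Long"] = sum(float(s ** 2) for _, s in pairs) / nr
    bylevel = defaultdict(int)
    bysize = defaultdict(int)
    joint = defaultdict(int)
    for g, s in pairs:
        bylevel[g] += 1
        bysize[s] += 1
        joint[(g, s)] += 1
    f["GLN"] = sum(v ** 2 for v in bylevel.values()) / nr
    f["GLNN"] = sum(v ** 2 for v in bylevel.values()) / nr ** 2
    f["SN"] = sum(v ** 2 for v in bysize.values()) / nr
    f["SNN"] = sum(v ** 2 for v in bysize.values()) / nr ** 2
    f["Percentage"] = nr / n_voxels
    mug = sum(g for g, _ in pairs) / nr
    mus = sum(s for _, s in pairs) / nr
    f["GLV"] = sum((g - mug) ** 2 for g, _ in pairs) / nr
    f["SV"] = sum((s - mus) ** 2 for _, s in pairs) / nr
    f["Entropy"] = -sum((v / nr) * math.log2(v / nr) for v in joint.values())
    f["LGL"] = sum(1.0 / g ** 2 for g, _ in pairs) / nr
    f["HGL"] = sum(float(g ** 2) for g, _ in pairs) / nr
    f["ShortLGL"] = sum(1.0 / (g ** 2 * s ** 2) for g, s in pairs) / nr
    f["ShortHGL"] = sum(g ** 2 / s ** 2 for g, s in pairs) / nr
    f["LongLGL"] = sum(s ** 2 / g ** 2 for g, s in pairs) / nr
    f["LongHGL"] = sum(float(g ** 2 * s ** 2) for g, s in pairs) / nr
    return f


_GLRLM_MAP = {
    "ShortRunEmphasis": "Short", "LongRunEmphasis": "Long",
    "GrayLevelNonUniformity": "GLN", "GrayLevelNonUniformityNormalized": "GLNN",
    "RunLengthNonUniformity": "SN", "RunLengthNonUniformityNormalized": "SNN",
    "RunPercentage": "Percentage", "GrayLevelVariance": "GLV",
    "RunVariance": "SV", "RunEntropy": "Entropy",
    "LowGrayLevelRunEmphasis": "LGL", "HighGrayLevelRunEmphasis": "HGL",
    "ShortRunLowGrayLevelEmphasis": "ShortLGL",
    "ShortRunHighGrayLevelEmphasis": "ShortHGL",
    "LongRunLowGrayLevelEmphasis": "LongLGL",
    "LongRunHighGrayLevelEmphasis": "LongHGL",
}


def ref_glrlm_averaged(levels, offsets=OFFSETS_13):
    n_voxels = int((levels > 0).sum())
    acc = defaultdict(list)
    for off in offsets:
        runs = ref_glrlm_matrix(levels, off)
        if not runs:
            continue
        g = _ref_size_features(runs, n_voxels, "run")
        for name, key in _GLRLM_MAP.items():
            acc[name].append(g[key])
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM

def ref_zones(levels, connectivity=NEIGHBORS_26):
    """Connected equal-level zones via breadth-first flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                size = 0
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    p = queue.popleft()
                    size += 1
                    for d in connectivity:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _in_grid(q, shape) and not seen[q] and levels[q] == g:
                            seen[q] = True
                            queue.append(q)
                zones.append((int(g), size))
    return zones


_GLSZM_MAP = {
    "SmallAreaEmphasis": "Short", "LargeAreaEmphasis": "Long",
    "GrayLevelNonUniformity": "GLN", "GrayLevelNonUniformityNormalized": "GLNN",
    "SizeZoneNonUniformity": "SN", "SizeZoneNonUniformityNormalized": "SNN",
    "ZonePercentage": "Percentage", "GrayLevelVariance": "GLV",
    "ZoneVariance": "SV", "ZoneEntropy": "Entropy",
    "LowGrayLevelZoneEmphasis": "LGL", "HighGrayLevelZoneEmphasis": "HGL",
    "SmallAreaLowGrayLevelEmphasis": "ShortLGL",
    "SmallAreaHighGrayLevelEmphasis": "ShortHGL",
    "LargeAreaLowGrayLevelEmphasis": "LongLGL",
    "LargeAreaHighGrayLevelEmphasis": "LongHGL",
}


def ref_glszm_features(levels):
    zones = ref_zones(levels)
    n_voxels = int((levels > 0).sum())
    g = _ref_size_features(zones, n_voxels, "zone")
    return {name: g[key] for name, key in _GLSZM_MAP.items()}


# ---------------------------------------------------------------------------
# NGTDM

def ref_ngtdm_features(levels, ng):
    shape = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                nb = [levels[x + d[0], y + d[1], z + d[2]]
                      for d in NEIGHBORS_26
                      if _in_grid((x + d[0], y + d[1], z + d[2]), shape)]
                nb = [v for v in nb if v > 0]
                if not nb:
                    continue
                n[g - 1] += 1
                s[g - 1] += abs(g - sum(nb) / len(nb))
    nvp = n.sum()
    p = n / nvp
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    f = {}
    denom = sum(p[i] * s[i] for i in range(ng))
    f["Coarseness"] = 1.0 / denom if denom != 0 else 1e6
    if ngp > 1:
        f["Contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1)) * s.sum() / nvp)
        bus = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                  for i in present for j in present)
        f["Busyness"] = denom / bus if bus != 0 else 0.0
        f["Complexity"] = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present) / nvp
        f["Strength"] = (sum((p[i] + p[j]) * (i - j) ** 2
                             for i in present for j in present) / s.sum()
                         if s.sum() != 0 else 0.0)
    else:
        f["Contrast"] = f["Busyness"] = f["Complexity"] = f["Strength"] = 0.0
    return f


# ---------------------------------------------------------------------------
# GLDM

_GLDM_MAP = {
    "SmallDependenceEmphasis": "Short", "LargeDependenceEmphasis": "Long",
    "GrayLevelNonUniformity": "GLN", "DependenceNonUniformity": "SN",
    "DependenceNonUniformityNormalized": "SNN", "GrayLevelVariance": "GLV",
    "DependenceVariance": "SV", "DependenceEntropy": "Entropy",
    "LowGrayLevelEmphasis": "LGL", "HighGrayLevelEmphasis": "HGL",
    "SmallDependenceLowGrayLevelEmphasis": "ShortLGL",
    "SmallDependenceHighGrayLevelEmphasis": "ShortHGL",
    "LargeDependenceLowGrayLevelEmphasis": "LongLGL",
    "LargeDependenceHighGrayLevelEmphasis": "LongHGL",
}


def ref_gldm_features(levels, alpha=0):
    shape = levels.shape
    pairs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                dep = 1
                for d in NEIGHBORS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _in_grid(q, shape) and levels[q] > 0 and abs(int(levels[q]) - int(g)) <= alpha:
                        dep += 1
                pairs.append((int(g), dep))
    g = _ref_size_features(pairs, len(pairs), "dep")
    return {name: g[key] for name, key in _GLDM_MAP.items()}
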