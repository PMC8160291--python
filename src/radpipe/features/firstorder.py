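"""First-order intensity statistics (18 features)."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]


def firstorder_features(
    values: np.ndarray,
    levels: np.ndarray | None = None,
    voxel_volume: float = 1.0,
) -> OrderedDict:
    """Intensity statistics of the in-mask voxel values.

    ``Entropy`` and ``Uniformity`` are computed on the discretized level
    histogram (``levels``, integer 1..Ng); all other statistics use the raw
    intensities.  Skewness and kurtosis of a constant region are 0 by
    convention (kurtosis is otherwise non-excess, i.e. 3 for a Gaussian).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("mask is empty")
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    if m2 < np.finfo(float).eps * (1.0 + mean ** 2):
        m2 = 0.0   # constant region up to float round-off
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])

    if levels is not None:
        lv = np.asarray(levels).ravel()
        counts = np.bincount(lv[lv > 0])[1:].astype(float)
        p = counts[counts > 0] / counts.sum()
    else:
        p = np.array([1.0])

    robust = x[(x >= p10) & (x <= p90)]

    f = OrderedDict()
    f["Energy"] = float((x ** 2).sum())
    f["TotalEnergy"] = float(voxel_volume * (x ** 2).sum())
    f["Entropy"] = float(-(p * np.log2(p)).sum())
    f["Minimum"] = float(x.min())
    f["Percentile10"] = float(p10)
    f["Percentile90"] = float(p90)
    f["Maximum"] = float(x.max())
    f["Mean"] = mean
    f["Median"] = float(np.median(x))
    f["InterquartileRange"] = float(p75 - p25)
    f["Range"] = float(x.max() - x.min())
    f["MeanAbsoluteDeviation"] = float(np.abs(x - mean).mean())
    f["RobustMeanAbsoluteDeviation"] = (
        float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0)
    f["RootMeanSquared"] = float(np.sqrt((x ** 2).mean()))
    f["Skewness"] = float(m3 / m2 ** 1.5) if m2 > 0 else 0.0
    f["Kurtosis"] = float(m4 / m2 ** 2) if m2 > 0 else 0.0
    f["Variance"] = m2
    f["Uniformity"] = float((p ** 2).sum())
    return f
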