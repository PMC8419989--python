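"""First-order (intensity) statistics of the masked voxel values."""

from __future__ import annotations

import numpy as np

from lesionrad.features.texture import discretize


def first_order_features(values, bin_width: float = 25.0) -> dict[str, float]:
    """The 18-statistic intensity panel of a VOI.

    ``Entropy`` and ``Uniformity`` use the same fixed-bin-width discretisation
    as the texture families.  Moment statistics use population (ddof=0)
    conventions; ``Skewness`` is g1 and ``Kurtosis`` the non-excess m4/m2^2,
    both defined as 0 for a constant VOI.  ``rMAD`` is the mean absolute
    deviation of the values inside the [P10, P90] range.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty mask: no voxel values")
    mean = float(x.mean())
    m2 = float(np.mean((x - mean) ** 2))
    m3 = float(np.mean((x - mean) ** 3))
    m4 = float(np.mean((x - mean) ** 4))
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
    levels = discretize(x, bin_width)
    p = np.bincount(levels)[1:] / x.size
    p = p[p > 0]
    return {
        "Energy": float(np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "P10": float(p10),
        "P90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "IQR": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MAD": float(np.mean(np.abs(x - mean))),
        "rMAD": rmad,
        "RMS": float(np.sqrt(np.mean(x**2))),
        "SD": float(np.sqrt(m2)),
        "Variance": m2,
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Uniformity": float(np.sum(p**2)),
    }
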