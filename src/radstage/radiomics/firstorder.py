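"""First-order (histogram) statistics of the ROI intensity distribution.

Fifteen features.  Entropy and Uniformity are computed on the discretized
gray-level histogram (so they depend on the bin exponent); everything else is
computed on raw masked intensities.  Conventions: population (n-denominator)
variance; Pearson kurtosis (not excess); linear-interpolation percentiles.
Features that need dispersion are inoperable (returned as None) on a
single-voxel ROI.
"""

from __future__ import annotations

import numpy as np

from ..images import ImageVolume, TumorMask, check_aligned
from .discretize import discretize

FIRST_ORDER_FEATURES = (
    "Energy",
    "Entropy",
    "Kurtosis",
    "Skewness",
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "Range",
    "Variance",
    "Percentile10",
    "Percentile90",
    "InterquartileRange",
    "RootMeanSquared",
    "Uniformity",
)


def first_order_features(
    volume: ImageVolume, mask: TumorMask, bin_exponent: int
) -> dict[str, float | None]:
    check_aligned(volume, mask)
    x = volume.intensities[mask.membership].astype(np.float64)
    n = x.size
    out: dict[str, float | None] = {}

    out["Energy"] = float(np.sum(x * x))
    out["Mean"] = float(np.mean(x))
    out["Median"] = float(np.median(x))
    out["Minimum"] = float(np.min(x))
    out["Maximum"] = float(np.max(x))
    out["Range"] = float(np.max(x) - np.min(x))
    out["Percentile10"] = float(np.percentile(x, 10))
    out["Percentile90"] = float(np.percentile(x, 90))
    out["InterquartileRange"] = float(np.percentile(x, 75) - np.percentile(x, 25))
    out["RootMeanSquared"] = float(np.sqrt(np.mean(x * x)))

    if n < 2:
        out["Variance"] = None
        out["Kurtosis"] = None
        out["Skewness"] = None
    else:
        mu = np.mean(x)
        m2 = float(np.mean((x - mu) ** 2))
        out["Variance"] = m2
        if m2 == 0.0:
            # constant ROI: moments degenerate but conventionally defined
            out["Kurtosis"] = None
            out["Skewness"] = None
        else:
            m3 = float(np.mean((x - mu) ** 3))
            m4 = float(np.mean((x - mu) ** 4))
            out["Skewness"] = m3 / m2**1.5
            out["Kurtosis"] = m4 / m2**2

    disc = discretize(volume, mask, bin_exponent)
    counts = np.bincount(disc.masked_levels(), minlength=disc.n_levels + 1)[1:]
    p = counts[counts > 0] / n
    out["Entropy"] = float(-np.sum(p * np.log2(p)))
    out["Uniformity"] = float(np.sum(p * p))

    return out
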