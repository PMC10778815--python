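"""Gray-level size-zone matrix (GLSZM) and its 14 statistics.

A zone is a 26-connected component of equal-level voxels within the mask;
the matrix counts zones by (gray level, zone size) and is rotation invariant
(no angle parameter).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVolume

GLSZM_FEATURES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Zone count matrix Z[level-1, size-1]."""
    levels = disc.levels
    n = disc.n_levels
    zones: list[tuple[int, int]] = []
    max_size = 1
    for lvl in np.unique(levels[disc.mask]):
        labeled, n_comp = ndimage.label(levels == lvl, structure=_STRUCT26)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            zones.append((int(lvl), int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((n, max_size), dtype=np.float64)
    for lvl, s in zones:
        mat[lvl - 1, s - 1] += 1.0
    return mat


def glszm_features(disc: DiscretizedVolume) -> dict[str, float | None]:
    mat = glszm_matrix(disc)
    nz_zones = mat.sum()
    n_vox = int(disc.mask.sum())
    gl = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    sz = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    p = mat / nz_zones

    out: dict[str, float | None] = {}
    out["SmallAreaEmphasis"] = float(np.sum(mat / sz**2) / nz_zones)
    out["LargeAreaEmphasis"] = float(np.sum(mat * sz**2) / nz_zones)
    g_marg = mat.sum(axis=1)
    s_marg = mat.sum(axis=0)
    out["GrayLevelNonUniformity"] = float(np.sum(g_marg**2) / nz_zones)
    out["GrayLevelNonUniformityNormalized"] = float(np.sum(g_marg**2) / nz_zones**2)
    out["SizeZoneNonUniformity"] = float(np.sum(s_marg**2) / nz_zones)
    out["SizeZoneNonUniformityNormalized"] = float(np.sum(s_marg**2) / nz_zones**2)
    out["ZonePercentage"] = float(nz_zones / n_vox)
    mu_g = float(np.sum(gl * p))
    out["GrayLevelVariance"] = float(np.sum((gl - mu_g) ** 2 * p))
    mu_s = float(np.sum(sz * p))
    out["ZoneVariance"] = float(np.sum((sz - mu_s) ** 2 * p))
    nz = p > 0
    out["ZoneEntropy"] = float(-np.sum(p[nz] * np.log2(p[nz])))
    out["LowGrayLevelZoneEmphasis"] = float(np.sum(mat / gl**2) / nz_zones)
    out["HighGrayLevelZoneEmphasis"] = float(np.sum(mat * gl**2) / nz_zones)
    out["SmallAreaLowGrayLevelEmphasis"] = float(
        np.sum(mat / (gl**2 * sz**2)) / nz_zones
    )
    out["LargeAreaHighGrayLevelEmphasis"] = float(
        np.sum(mat * gl**2 * sz**2) / nz_zones
    )
    return out
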