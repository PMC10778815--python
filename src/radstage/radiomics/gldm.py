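"""Gray-level dependence matrix (GLDM) and its 12 statistics.

The dependence of a masked voxel is the number of masked neighbors within
Chebyshev distance ``kernel_size`` that share its exact gray level (the
center voxel itself is not counted, so a 3x3x1 constant ROI at kernel 1 gives
its center dependence 8).  Emphasis denominators use dependence + 1 so that
isolated voxels (dependence 0) are well defined and a checkerboard maximizes
SmallDependenceEmphasis.
"""

from __future__ import annotations

import itertools

import numpy as np

from .discretize import DiscretizedVolume

GLDM_FEATURES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def chebyshev_offsets(radius: int) -> list[tuple[int, int, int]]:
    """All nonzero 3D offsets with Chebyshev norm <= radius."""
    r = range(-radius, radius + 1)
    return [off for off in itertools.product(r, r, r) if off != (0, 0, 0)]


def _shifted_view(arr: np.ndarray, off: tuple[int, int, int]):
    """Index windows (dst, src) so that dst slice sees arr shifted by off."""
    dst, src = [], []
    for ax, d in enumerate(off):
        n = arr.shape[ax]
        if abs(d) >= n:
            return None
        dst.append(slice(max(0, -d), min(n, n - d)))
        src.append(slice(max(0, d), min(n, n + d)))
    return tuple(dst), tuple(src)


def dependence_counts(disc: DiscretizedVolume, kernel_size: int) -> np.ndarray:
    """Per-voxel count of equal-level masked neighbors (0 outside mask)."""
    levels, mask = disc.levels, disc.mask
    dep = np.zeros(levels.shape, dtype=np.int32)
    for off in chebyshev_offsets(kernel_size):
        win = _shifted_view(levels, off)
        if win is None:
            continue
        dst, src = win
        hit = (
            mask[dst]
            & mask[src]
            & (levels[dst] == levels[src])
        )
        dep[dst] += hit
    dep[~mask] = 0
    return dep


def gldm_matrix(disc: DiscretizedVolume, kernel_size: int) -> np.ndarray:
    """Count matrix D[level-1, dependence]; columns index dependence 0..max."""
    dep = dependence_counts(disc, kernel_size)
    lv = disc.levels[disc.mask]
    dp = dep[disc.mask]
    mat = np.zeros((disc.n_levels, int(dp.max()) + 1), dtype=np.float64)
    np.add.at(mat, (lv - 1, dp), 1.0)
    return mat


def gldm_features(disc: DiscretizedVolume, kernel_size: int) -> dict[str, float | None]:
    mat = gldm_matrix(disc, kernel_size)
    nz_total = mat.sum()  # == number of masked voxels
    gl = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    dp = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]  # dependence + 1
    p = mat / nz_total

    out: dict[str, float | None] = {}
    out["SmallDependenceEmphasis"] = float(np.sum(mat / dp**2) / nz_total)
    out["LargeDependenceEmphasis"] = float(np.sum(mat * dp**2) / nz_total)
    g_marg = mat.sum(axis=1)
    d_marg = mat.sum(axis=0)
    out["GrayLevelNonUniformity"] = float(np.sum(g_marg**2) / nz_total)
    out["DependenceNonUniformity"] = float(np.sum(d_marg**2) / nz_total)
    out["DependenceNonUniformityNormalized"] = float(np.sum(d_marg**2) / nz_total**2)
    mu_g = float(np.sum(gl * p))
    out["GrayLevelVariance"] = float(np.sum((gl - mu_g) ** 2 * p))
    mu_d = float(np.sum(dp * p))
    out["DependenceVariance"] = float(np.sum((dp - mu_d) ** 2 * p))
    nz = p > 0
    out["DependenceEntropy"] = float(-np.sum(p[nz] * np.log2(p[nz])))
    out["LowGrayLevelEmphasis"] = float(np.sum(mat / gl**2) / nz_total)
    out["HighGrayLevelEmphasis"] = float(np.sum(mat * gl**2) / nz_total)
    out["SmallDependenceLowGrayLevelEmphasis"] = float(
        np.sum(mat / (gl**2 * dp**2)) / nz_total
    )
    out["LargeDependenceHighGrayLevelEmphasis"] = float(
        np.sum(mat * gl**2 * dp**2) / nz_total
    )
    return out
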