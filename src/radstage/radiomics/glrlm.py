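"""Gray-level run-length matrix (GLRLM) and its 15 statistics.

Runs are maximal stretches of equal gray level along one in-plane direction,
truncated wherever the line leaves the mask.  One matrix per angle; the
consensus feature list is trimmed by one (LongRunHighGrayLevelEmphasis) to
the 15 features exposed here.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedVolume

GLRLM_FEATURES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
)


def _lines_for_angle(plane: np.ndarray, angle: int) -> list[np.ndarray]:
    """Scan lines of a 2D array along one of the four in-plane directions."""
    nr, nc = plane.shape
    if angle == 0:
        return [plane[r, :] for r in range(nr)]
    if angle == 90:
        return [plane[:, c] for c in range(nc)]
    if angle == 45:
        # direction (-1, +1): anti-diagonals
        flipped = plane[::-1, :]
        return [np.diagonal(flipped, offset=k) for k in range(-nr + 1, nc)]
    if angle == 135:
        # direction (-1, -1): main diagonals
        return [np.diagonal(plane, offset=k) for k in range(-nr + 1, nc)]
    raise ValueError(f"angle must be one of (0, 45, 90, 135), got {angle}")


def _run_lengths(line: np.ndarray) -> list[tuple[int, int]]:
    """(level, length) runs of a 1D line; level 0 (outside mask) is skipped."""
    runs: list[tuple[int, int]] = []
    prev, length = 0, 0
    for v in line:
        if v == prev:
            length += 1
        else:
            if prev != 0:
                runs.append((int(prev), length))
            prev, length = int(v), 1
    if prev != 0:
        runs.append((int(prev), length))
    return runs


def glrlm_matrix(disc: DiscretizedVolume, angle: int = 0) -> np.ndarray:
    """Run-length count matrix R[level-1, length-1], per-slice runs pooled."""
    levels = disc.levels
    n = disc.n_levels
    max_len = max(levels.shape[1], levels.shape[2])
    mat = np.zeros((n, max_len), dtype=np.float64)
    for s in range(levels.shape[0]):
        for line in _lines_for_angle(levels[s], angle):
            for lvl, length in _run_lengths(line):
                mat[lvl - 1, length - 1] += 1.0
    return mat


def glrlm_features(disc: DiscretizedVolume, angle: int = 0) -> dict[str, float | None]:
    mat = glrlm_matrix(disc, angle)
    nr_runs = mat.sum()
    if nr_runs == 0:
        return {name: None for name in GLRLM_FEATURES}
    n_vox = int(disc.mask.sum())
    gl = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    rl = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    p = mat / nr_runs

    out: dict[str, float | None] = {}
    out["ShortRunEmphasis"] = float(np.sum(mat / rl**2) / nr_runs)
    out["LongRunEmphasis"] = float(np.sum(mat * rl**2) / nr_runs)
    g_marg = mat.sum(axis=1)
    r_marg = mat.sum(axis=0)
    out["GrayLevelNonUniformity"] = float(np.sum(g_marg**2) / nr_runs)
    out["GrayLevelNonUniformityNormalized"] = float(np.sum(g_marg**2) / nr_runs**2)
    out["RunLengthNonUniformity"] = float(np.sum(r_marg**2) / nr_runs)
    out["RunLengthNonUniformityNormalized"] = float(np.sum(r_marg**2) / nr_runs**2)
    out["RunPercentage"] = float(nr_runs / n_vox)
    mu_g = float(np.sum(gl * p))
    out["GrayLevelVariance"] = float(np.sum((gl - mu_g) ** 2 * p))
    mu_r = float(np.sum(rl * p))
    out["RunVariance"] = float(np.sum((rl - mu_r) ** 2 * p))
    nz = p > 0
    out["RunEntropy"] = float(-np.sum(p[nz] * np.log2(p[nz])))
    out["LowGrayLevelRunEmphasis"] = float(np.sum(mat / gl**2) / nr_runs)
    out["HighGrayLevelRunEmphasis"] = float(np.sum(mat * gl**2) / nr_runs)
    out["ShortRunLowGrayLevelEmphasis"] = float(np.sum(mat / (gl**2 * rl**2)) / nr_runs)
    out["ShortRunHighGrayLevelEmphasis"] = float(np.sum(mat * gl**2 / rl**2) / nr_runs)
    out["LongRunLowGrayLevelEmphasis"] = float(np.sum(mat * rl**2 / gl**2) / nr_runs)
    return out
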