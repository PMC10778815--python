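"""Gray-level co-occurrence matrix (GLCM) and its 20 statistics.

Pairs are counted per axial slice at a fixed voxel offset (``distance`` along
one of the four in-plane directions 0/45/90/135 degrees); both voxels of a
pair must lie inside the mask.  The matrix is symmetrized (each pair counted
in both orders) and normalized to sum to 1, which makes opposite directions
redundant.  Feature formulas follow the IBSI consensus definitions.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedVolume

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Homogeneity",
    "InverseDifferenceMoment",
    "IMC1",
    "IMC2",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumOfSquares",
    "Dissimilarity",
)

# in-plane (row, col) unit steps for each angle
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix(
    disc: DiscretizedVolume, distance: int = 1, angle: int = 0
) -> np.ndarray | None:
    """Normalized symmetric co-occurrence matrix, or None if no valid pairs.

    ``distance`` is the offset length in voxels (1..5); ``angle`` one of
    {0, 45, 90, 135} degrees within the axial plane.
    """
    if angle not in _ANGLE_STEPS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_STEPS)}, got {angle}")
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    dr, dc = (distance * s for s in _ANGLE_STEPS[angle])
    levels, mask = disc.levels, disc.mask
    n = disc.n_levels
    ns, nr, nc = levels.shape

    # overlapping index windows for the shifted pairing
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    if r0 >= r1 or c0 >= c1:
        return None
    a = levels[:, r0:r1, c0:c1]
    b = levels[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[:, r0:r1, c0:c1] & mask[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not valid.any():
        return None

    i = a[valid] - 1
    j = b[valid] - 1
    counts = np.zeros((n, n), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T  # symmetrize
    return counts / counts.sum()


def glcm_features(p: np.ndarray) -> dict[str, float | None]:
    """The 20 co-occurrence statistics of a normalized symmetric matrix."""
    n = p.shape[0]
    idx = np.arange(1, n + 1, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    eps = np.finfo(float).tiny

    px = p.sum(axis=1)  # == py by symmetry
    mu = float(np.sum(idx * px))
    sigma2 = float(np.sum((idx - mu) ** 2 * px))

    # diagonal-band and anti-diagonal-band marginals
    k_diff = np.abs(i - j).astype(int)  # 0 .. n-1
    k_sum = (i + j).astype(int)  # 2 .. 2n
    p_diff = np.zeros(n)
    np.add.at(p_diff, k_diff.ravel(), p.ravel())
    p_sum = np.zeros(2 * n + 1)
    np.add.at(p_sum, k_sum.ravel(), p.ravel())
    p_sum = p_sum[2:]
    ks = np.arange(2, 2 * n + 1, dtype=np.float64)
    kd = np.arange(0, n, dtype=np.float64)

    out: dict[str, float | None] = {}
    out["Autocorrelation"] = float(np.sum(i * j * p))
    dev = i + j - 2 * mu
    out["ClusterProminence"] = float(np.sum(dev**4 * p))
    out["ClusterShade"] = float(np.sum(dev**3 * p))
    out["ClusterTendency"] = float(np.sum(dev**2 * p))
    out["Contrast"] = float(np.sum((i - j) ** 2 * p))
    out["Dissimilarity"] = float(np.sum(np.abs(i - j) * p))
    out["JointEnergy"] = float(np.sum(p * p))
    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    out["JointEntropy"] = hxy
    out["Homogeneity"] = float(np.sum(p / (1.0 + np.abs(i - j))))
    out["InverseDifferenceMoment"] = float(np.sum(p / (1.0 + (i - j) ** 2)))
    off = k_diff > 0
    out["InverseVariance"] = float(np.sum(p[off] / (i - j)[off] ** 2))
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float(np.sum(ks * p_sum))
    nzs = p_sum > 0
    out["SumEntropy"] = float(-np.sum(p_sum[nzs] * np.log2(p_sum[nzs])))
    out["SumOfSquares"] = float(np.sum((i - mu) ** 2 * p))
    da = float(np.sum(kd * p_diff))
    out["DifferenceVariance"] = float(np.sum((kd - da) ** 2 * p_diff))
    nzd = p_diff > 0
    out["DifferenceEntropy"] = float(-np.sum(p_diff[nzd] * np.log2(p_diff[nzd])))

    if sigma2 <= 0:
        out["Correlation"] = None
        out["IMC1"] = None
        out["IMC2"] = None
    else:
        out["Correlation"] = float((out["Autocorrelation"] - mu * mu) / sigma2)
        pxpy = px[:, None] * px[None, :]
        hxy1 = float(-np.sum(p * np.log2(pxpy + eps)))
        hxy2 = float(-np.sum(pxpy * np.log2(pxpy + eps)))
        nzx = px > 0
        hx = float(-np.sum(px[nzx] * np.log2(px[nzx])))
        if hx == 0.0:
            out["IMC1"] = None
        else:
            out["IMC1"] = (hxy - hxy1) / hx
        out["IMC2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return out
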