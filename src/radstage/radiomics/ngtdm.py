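"""Neighborhood gray-tone difference matrix (NGTDM): 5 statistics.

For every gray level i present in the ROI, s_i accumulates |i - A(v)| over
ROI voxels v of level i, where A(v) is the mean level of the masked neighbors
of v within Chebyshev radius ``kernel_size`` (center excluded).  Voxels with
no masked neighbor do not contribute.  Coarseness, Busyness and Strength have
zero denominators on degenerate ROIs and are then flagged inoperable.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedVolume
from .gldm import _shifted_view, chebyshev_offsets

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def ngtdm_table(
    disc: DiscretizedVolume, kernel_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i) arrays indexed by level-1."""
    levels, mask = disc.levels, disc.mask
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int32)
    for off in chebyshev_offsets(kernel_size):
        win = _shifted_view(levels, off)
        if win is None:
            continue
        dst, src = win
        valid = mask[src]
        nb_sum[dst] += np.where(valid, levels[src], 0)
        nb_cnt[dst] += valid

    contrib = mask & (nb_cnt > 0)
    mean_nb = np.zeros(levels.shape, dtype=np.float64)
    mean_nb[contrib] = nb_sum[contrib] / nb_cnt[contrib]
    diffs = np.abs(levels.astype(np.float64) - mean_nb)

    n_i = np.zeros(disc.n_levels, dtype=np.float64)
    s_i = np.zeros(disc.n_levels, dtype=np.float64)
    lv = levels[contrib] - 1
    np.add.at(n_i, lv, 1.0)
    np.add.at(s_i, lv, diffs[contrib])
    return n_i, s_i


def ngtdm_features(
    disc: DiscretizedVolume, kernel_size: int
) -> dict[str, float | None]:
    n_i, s_i = ngtdm_table(disc, kernel_size)
    n_vp = n_i.sum()
    out: dict[str, float | None] = {name: None for name in NGTDM_FEATURES}
    if n_vp == 0:
        return out
    p_i = n_i / n_vp
    present = p_i > 0
    n_g = int(present.sum())
    lv = np.arange(1, disc.n_levels + 1, dtype=np.float64)

    denom_coarse = float(np.sum(p_i * s_i))
    out["Coarseness"] = (1.0 / denom_coarse) if denom_coarse > 0 else None

    if n_g > 1:
        ii = lv[present][:, None]
        jj = lv[present][None, :]
        pp_i = p_i[present][:, None]
        pp_j = p_i[present][None, :]
        out["Contrast"] = float(
            np.sum(pp_i * pp_j * (ii - jj) ** 2)
            / (n_g * (n_g - 1))
            * np.sum(s_i)
            / n_vp
        )
        denom_busy = float(np.sum(np.abs(ii * pp_i - jj * pp_j)))
        num_busy = float(np.sum(p_i * s_i))
        out["Busyness"] = num_busy / denom_busy if denom_busy > 0 else None
        ss_i = s_i[present][:, None]
        ss_j = s_i[present][None, :]
        out["Complexity"] = float(
            np.sum(np.abs(ii - jj) * (pp_i * ss_i + pp_j * ss_j) / (pp_i + pp_j))
            / n_vp
        )
        denom_str = float(np.sum(s_i))
        out["Strength"] = (
            float(np.sum((pp_i + pp_j) * (ii - jj) ** 2)) / denom_str
            if denom_str > 0
            else None
        )
    else:
        out["Contrast"] = 0.0
        out["Busyness"] = None
        out["Complexity"] = 0.0
        out["Strength"] = None if float(np.sum(s_i)) == 0 else 0.0
    return out
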