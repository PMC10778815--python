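"""Intensity normalization and fixed-bin-count gray-level discretization.

Texture matrices operate on gray levels rather than raw intensities: the ROI
intensity range is mapped onto N = 2**bin_exponent equal-width bins, which
suppresses scanner-dependent contrast variation and bounds matrix size.
Because binning is computed over the ROI's own [min, max] range, every
strictly increasing affine transform of the raw intensities yields the same
level grid — the invariance the downstream texture features inherit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..images import ImageVolume, TumorMask, check_aligned


@dataclass
class DiscretizedVolume:
    """Integer gray-level grid: levels 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray  # bool grid, same shape

    def masked_levels(self) -> np.ndarray:
        """Gray levels of the ROI voxels as a flat int array."""
        return self.levels[self.mask]


def minmax_normalize(volume: ImageVolume) -> ImageVolume:
    """Scale voxel values to [0, 1] by the volume-wide min-max affine map.

    A constant volume maps to all zeros (degenerate-range convention).
    Idempotent; preserves intensity order.
    """
    v = volume.intensities
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        scaled = np.zeros_like(v)
    else:
        scaled = (v - lo) / (hi - lo)
    return ImageVolume(scaled, spacing=volume.spacing, case_id=volume.case_id)


def discretize(
    volume: ImageVolume, mask: TumorMask, bin_exponent: int
) -> DiscretizedVolume:
    """Discretize ROI intensities into N = 2**bin_exponent gray levels.

    level(v) = min(N, floor(N * (v - min) / (max - min)) + 1) over the masked
    intensity range; a constant ROI maps every voxel to level 1.
    """
    if not 1 <= int(bin_exponent) <= 8:
        raise ValueError(f"bin_exponent must be in 1..8, got {bin_exponent}")
    check_aligned(volume, mask)
    n = 1 << int(bin_exponent)
    m = mask.membership
    vals = volume.intensities[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
    else:
        binned = np.floor(n * (vals - lo) / (hi - lo)).astype(np.int32) + 1
        levels[m] = np.minimum(binned, n)
    return DiscretizedVolume(levels=levels, n_levels=n, mask=m)
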