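"""Core voxel-grid containers for MR volumes and tumor masks.

Axis order is (slice, row, col) throughout; ``spacing`` gives the physical
voxel size in millimetres along each of those axes.  Masks are boolean grids
aligned voxel-for-voxel with their volume; voxel centers are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class AlignmentError(ValueError):
    """Raised when a volume and mask do not share the same voxel grid."""


@dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    intensities : ndarray, shape (n_slices, n_rows, n_cols)
        Finite scalar voxel values.
    spacing : tuple of float
        Physical voxel size in mm along (slice, row, col); all entries > 0.
    case_id : str
        Case identifier carried through to feature tables.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    case_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D, got shape {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class TumorMask:
    """Binary region-of-interest aligned with an :class:`ImageVolume`."""

    membership: np.ndarray
    case_id: str = ""

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.ndim != 3:
            raise ValueError(
                f"membership must be 3D, got shape {self.membership.shape}"
            )
        if not self.membership.any():
            raise ValueError("mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.membership.shape

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())


def check_aligned(volume: ImageVolume, mask: TumorMask) -> None:
    """Raise :class:`AlignmentError` unless volume and mask share a grid."""
    if volume.shape != mask.shape:
        raise AlignmentError(
            f"volume grid {volume.shape} does not match mask grid {mask.shape}"
        )
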