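"""Parameter-sweep radiomic extraction producing a long-format feature table.

One record per (case, family, feature, parameter combination).  The sweep
covers bin exponents x (gray levels N = 2**x), kernel sizes (offset distance
for co-occurrence, Chebyshev neighborhood radius for dependence and gray-tone
difference) and the four in-plane angles.  Run-length and size-zone matrices
have no kernel parameter and size-zone no angle; shape features are computed
once per case; first-order once per bin exponent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..images import ImageVolume, TumorMask, check_aligned
from .discretize import discretize, minmax_normalize
from .firstorder import FIRST_ORDER_FEATURES, first_order_features
from .glcm import GLCM_FEATURES, glcm_features, glcm_matrix
from .gldm import GLDM_FEATURES, gldm_features
from .glrlm import GLRLM_FEATURES, glrlm_features
from .glszm import GLSZM_FEATURES, glszm_features
from .ngtdm import NGTDM_FEATURES, ngtdm_features
from .shape import SHAPE_FEATURES, shape_features

FEATURE_TABLE_COLUMNS = (
    "case_id",
    "family",
    "feature",
    "bin_exponent",
    "kernel",
    "angle",
    "value",
    "operable",
)

FAMILY_FEATURES = {
    "first_order": FIRST_ORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "shape": SHAPE_FEATURES,
}


@dataclass(frozen=True)
class ParamGrid:
    """The extraction sweep: which bin exponents, kernels and angles to use."""

    bin_exponents: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    kernels: tuple[int, ...] = (1, 2, 3, 4, 5)
    angles: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        if not all(1 <= b <= 8 for b in self.bin_exponents):
            raise ValueError("bin_exponents must lie in 1..8")
        if not all(1 <= k <= 5 for k in self.kernels):
            raise ValueError("kernels must lie in 1..5")
        if not set(self.angles) <= {0, 45, 90, 135}:
            raise ValueError("angles must be a subset of {0, 45, 90, 135}")

    def census(self) -> int:
        """Closed-form record count per case for this grid."""
        nb, nk, na = len(self.bin_exponents), len(self.kernels), len(self.angles)
        return (
            len(SHAPE_FEATURES)
            + len(FIRST_ORDER_FEATURES) * nb
            + len(GLCM_FEATURES) * nb * nk * na
            + len(GLRLM_FEATURES) * nb * na
            + len(GLSZM_FEATURES) * nb
            + len(GLDM_FEATURES) * nb * nk
            + len(NGTDM_FEATURES) * nb * nk
        )


DEFAULT_GRID = ParamGrid()


def _rows(case_id, family, values, b=None, k=None, a=None):
    return [
        {
            "case_id": case_id,
            "family": family,
            "feature": name,
            "bin_exponent": b,
            "kernel": k,
            "angle": a,
            "value": np.nan if v is None else float(v),
            "operable": v is not None,
        }
        for name, v in values.items()
    ]


def extract_all(
    volume: ImageVolume,
    mask: TumorMask,
    grid: ParamGrid = DEFAULT_GRID,
    surface_method: str = "mesh",
) -> pd.DataFrame:
    """Extract the full sweep for one case as a long-format table.

    The volume is min-max normalized before discretization.  Inoperable
    features are emitted with value NaN and ``operable=False``, never as a
    silent non-finite number.
    """
    check_aligned(volume, mask)
    norm = minmax_normalize(volume)
    rows: list[dict] = []

    rows += _rows(
        mask.case_id or volume.case_id,
        "shape",
        shape_features(mask, volume.spacing, surface_method=surface_method),
    )
    cid = mask.case_id or volume.case_id

    for b in grid.bin_exponents:
        disc = discretize(norm, mask, b)
        rows += _rows(cid, "first_order", first_order_features(norm, mask, b), b=b)
        rows += _rows(cid, "glszm", glszm_features(disc), b=b)
        for a in grid.angles:
            rows += _rows(cid, "glrlm", glrlm_features(disc, a), b=b, a=a)
            for k in grid.kernels:
                p = glcm_matrix(disc, distance=k, angle=a)
                if p is None:
                    vals = {name: None for name in GLCM_FEATURES}
                else:
                    vals = glcm_features(p)
                rows += _rows(cid, "glcm", vals, b=b, k=k, a=a)
        for k in grid.kernels:
            rows += _rows(cid, "gldm", gldm_features(disc, k), b=b, k=k)
            rows += _rows(cid, "ngtdm", ngtdm_features(disc, k), b=b, k=k)

    table = pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))
    order = ["case_id", "family", "feature", "bin_exponent", "kernel", "angle"]
    return table.sort_values(order, na_position="first").reset_index(drop=True)


def extract_cohort(
    volumes: list[ImageVolume],
    masks: list[TumorMask],
    grid: ParamGrid = DEFAULT_GRID,
    surface_method: str = "mesh",
) -> pd.DataFrame:
    """Concatenate :func:`extract_all` across a list of aligned cases."""
    if len(volumes) != len(masks):
        raise ValueError("volumes and masks differ in length")
    tables = [
        extract_all(v, m, grid=grid, surface_method=surface_method)
        for v, m in zip(volumes, masks)
    ]
    return pd.concat(tables, ignore_index=True)


def feature_id(row) -> str:
    """Stable feature identifier encoding family, name and parameters."""
    parts = [str(row["family"]), str(row["feature"])]
    for key, tag in (("bin_exponent", "b"), ("kernel", "k"), ("angle", "a")):
        v = row[key]
        if v is not None and not (isinstance(v, float) and np.isnan(v)):
            parts.append(f"{tag}{int(v)}")
    return "|".join(parts)
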