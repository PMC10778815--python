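"""Readers and writers for the pipeline's on-disk formats.

NIfTI volume/mask pairs (nibabel), gene-level counts TSV (genes x samples),
GMT gene-set collections, per-case stage label CSV (raw TNM stages accepted
and mapped), long-format feature CSV, and JSON truth/manifest files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .images import AlignmentError, ImageVolume, TumorMask

# TNM T-stage mapping: intra-vesical = confined within the bladder wall.
# N+/M+ always maps to extra-vesical.
TNM_TO_STAGE = {
    "TA": "intra",
    "TIS": "intra",
    "T1": "intra",
    "T2": "intra",
    "T3": "extra",
    "T4": "extra",
    "N+": "extra",
    "M+": "extra",
    "INTRA": "intra",
    "EXTRA": "extra",
}


class ValidationError(ValueError):
    """A file parsed but failed content validation."""


# ---------------------------------------------------------------------------
# NIfTI


def write_nifti_pair(
    volume: ImageVolume, mask: TumorMask, volume_path, mask_path
) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float64), affine), str(volume_path))
    nib.save(
        nib.Nifti1Image(mask.membership.astype(np.uint8), affine), str(mask_path)
    )


def read_nifti_pair(volume_path, mask_path) -> tuple[ImageVolume, TumorMask]:
    """Load an aligned volume/mask pair; the mask is binarized at > 0."""
    vimg = nib.load(str(volume_path))
    mimg = nib.load(str(mask_path))
    vdata = np.asarray(vimg.dataobj, dtype=np.float64)
    mdata = np.asarray(mimg.dataobj)
    if vdata.shape != mdata.shape:
        raise AlignmentError(
            f"volume grid {vdata.shape} ({volume_path}) does not match "
            f"mask grid {mdata.shape} ({mask_path})"
        )
    if not np.all(np.isfinite(vdata)):
        raise ValidationError(f"non-finite voxels in {volume_path}")
    spacing = tuple(float(z) for z in vimg.header.get_zooms()[:3])
    case_id = Path(volume_path).name.split(".")[0]
    return (
        ImageVolume(vdata, spacing=spacing, case_id=case_id),
        TumorMask(mdata > 0, case_id=case_id),
    )


# ---------------------------------------------------------------------------
# counts / labels / gene sets


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError(f"duplicate gene ids in {path}")
    if df.columns.duplicated().any():
        raise ValidationError(f"duplicate sample ids in {path}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"non-numeric counts in {path}")
    if (arr < 0).any():
        raise ValidationError(f"negative counts in {path}")
    return df


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("stage").to_csv(path, index_label="case_id")


def read_labels(path) -> pd.Series:
    """case_id,stage CSV; stage may be intra/extra or a raw TNM stage."""
    df = pd.read_csv(path)
    if not {"case_id", "stage"} <= set(df.columns):
        raise ValidationError(f"{path} must have case_id and stage columns")
    if df["case_id"].duplicated().any():
        raise ValidationError(f"duplicate case ids in {path}")
    mapped = []
    for raw in df["stage"].astype(str):
        key = raw.strip().upper()
        if key not in TNM_TO_STAGE:
            raise ValidationError(f"unknown stage label {raw!r} in {path}")
        mapped.append(TNM_TO_STAGE[key])
    return pd.Series(mapped, index=df["case_id"].astype(str), name="stage")


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{line_no}: GMT line needs name, description and >= 1 gene"
                )
            name, members = parts[0], [g for g in parts[2:] if g]
            if not members:
                raise ValidationError(f"{path}:{line_no}: empty gene set {name!r}")
            if name in sets:
                raise ValidationError(f"{path}:{line_no}: duplicate set {name!r}")
            sets[name] = members
    return sets


# ---------------------------------------------------------------------------
# tables and JSON


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["operable"] = df["operable"].astype(bool)
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
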