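"""Regional lesion quantification on a parcellation atlas.

A binary ischemic-lesion mask registered to a common atlas space is
intersected with an integer-labelled parcellation to yield, per region,
the regional extent of ischemic lesion (rEIL):

    rEIL_r = 100 * |lesion ∩ region_r| / |region_r|   (voxel counts)

Native-space lesion volume is the 1-voxel count times the native voxel
volume (the z dimension includes any inter-slice gap, e.g. a 5 mm slice
with a 2 mm gap contributes dz = 7 mm).

The nine occipital/medial-temporal regions analysed are listed in
``REGION_NAMES``; rEIL is computed on the ipsilesional hemisphere's
labels only, since the lesions are unilateral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GridError, SchemaError, SpaceError

#: The nine atlas regions of the posterior-cerebral-artery territory, in
#: the order results tables use.
REGION_NAMES = (
    "lingual",
    "calcarine",
    "fusiform",
    "cuneus",
    "inferior_occipital",
    "parahippocampal",
    "hippocampus",
    "superior_occipital",
    "middle_occipital",
)

HEMISPHERES = ("left", "right")


@dataclass
class LesionMask:
    """Binary lesion volume with voxel geometry and a space tag."""

    data: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    space: str  # "native" | "atlas"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise SchemaError("lesion mask values must be 0 or 1")
        self.data = data.astype(bool)
        dims = tuple(float(d) for d in self.voxel_dims_mm)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise SchemaError(f"voxel dims must be 3 positive numbers, got {dims}")
        self.voxel_dims_mm = dims
        if self.space not in ("native", "atlas"):
            raise SchemaError(f"space must be 'native' or 'atlas', got {self.space!r}")

    @classmethod
    def from_nifti(cls, path, space: str = "atlas") -> "LesionMask":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        return cls(
            data=data > 0.5,
            voxel_dims_mm=tuple(float(z) for z in img.header.get_zooms()[:3]),
            space=space,
        )

    def to_nifti(self, path) -> None:
        affine = np.diag((*self.voxel_dims_mm, 1.0))
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), str(path))


@dataclass
class Parcellation:
    """Integer label volume plus a region table.

    ``regions`` columns: region_id, region_name, hemisphere,
    voxel_count.  Every nonzero label in the volume must appear in the
    table and the stored voxel counts must equal the label tallies.
    """

    labels: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise SchemaError("parcellation labels must be integers")
        required = {"region_id", "region_name", "hemisphere"}
        if not required.issubset(self.regions.columns):
            raise SchemaError(f"region table needs columns {sorted(required)}")
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        tally = dict(zip(ids.tolist(), counts.tolist()))
        known = set(self.regions["region_id"].tolist())
        unknown = set(tally) - known
        if unknown:
            raise SchemaError(f"labels absent from region table: {sorted(unknown)}")
        self.regions = self.regions.copy()
        self.regions["voxel_count"] = [
            tally.get(rid, 0) for rid in self.regions["region_id"]
        ]

    def region_mask(self, region_name: str, hemisphere: str) -> np.ndarray:
        sel = self.regions[
            (self.regions["region_name"] == region_name)
            & (self.regions["hemisphere"] == hemisphere)
        ]
        if sel.empty:
            raise SchemaError(
                f"region {region_name!r} ({hemisphere}) not in parcellation"
            )
        rid = int(sel["region_id"].iloc[0])
        return self.labels == rid

    @classmethod
    def from_files(cls, label_path, region_table_path) -> "Parcellation":
        img = nib.load(str(label_path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        regions = pd.read_csv(region_table_path)
        return cls(labels=labels, regions=regions)

    def to_files(self, label_path, region_table_path) -> None:
        nib.save(
            nib.Nifti1Image(self.labels.astype(np.int16), np.eye(4)), str(label_path)
        )
        self.regions.loc[:, ["region_id", "region_name", "hemisphere"]].to_csv(
            region_table_path, index=False
        )


def lesion_volume_ml(mask: LesionMask) -> float:
    """Native-space lesion volume in mL (voxel count x voxel volume)."""
    if mask.space != "native":
        raise SpaceError(
            "lesion volume is a native-space quantity; mask is tagged "
            f"{mask.space!r}"
        )
    dx, dy, dz = mask.voxel_dims_mm
    return float(mask.data.sum()) * dx * dy * dz / 1000.0


def compute_reil(
    mask: LesionMask, parcellation: Parcellation, side: str
) -> pd.Series:
    """Per-region rEIL (%) on the lesioned hemisphere.

    Returns a Series indexed by ``REGION_NAMES``; each value is
    100 * (lesioned voxels inside the region) / (region voxels).
    """
    if side not in HEMISPHERES:
        raise ConfigurationError(f"side must be 'left' or 'right', got {side!r}")
    if mask.space != "atlas":
        raise SpaceError("rEIL requires an atlas-space mask")
    if mask.data.shape != parcellation.labels.shape:
        raise GridError(
            f"mask grid {mask.data.shape} != parcellation grid "
            f"{parcellation.labels.shape}"
        )
    out = {}
    for name in REGION_NAMES:
        region = parcellation.region_mask(name, side)
        n_region = int(region.sum())
        if n_region == 0:
            raise SchemaError(f"region {name!r} ({side}) has zero voxels")
        out[name] = 100.0 * float(np.count_nonzero(mask.data & region)) / n_region
    return pd.Series(out, name="reil_pct")


def reil_table(
    masks: Sequence[LesionMask],
    parcellation: Parcellation,
    sides: Sequence[str],
    patient_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wide rEIL table: one row per patient, one column per region."""
    if len(masks) != len(sides):
        raise SchemaError("need one lesion side per mask")
    rows = [compute_reil(m, parcellation, s) for m, s in zip(masks, sides)]
    idx = patient_ids if patient_ids is not None else range(len(masks))
    df = pd.DataFrame(rows, index=pd.Index(idx, name="patient_id"))
    return df.add_prefix("reil_")


def lesion_frequency_map(
    masks: Sequence[LesionMask],
    sides: Sequence[str] | None = None,
    flip_to_common_side: bool = True,
    flip_axis: int = 0,
) -> np.ndarray:
    """Per-voxel fraction of patients whose lesion covers the voxel.

    With ``flip_to_common_side`` (default), right-hemisphere lesions are
    mirrored onto the left along ``flip_axis`` before counting, so the
    map reads ipsilesional-left / contralesional-right.  ``sides`` is
    then required (one hemisphere per mask).
    """
    masks = list(masks)
    if not masks:
        raise SchemaError("empty group of lesion masks")
    shape = masks[0].data.shape
    if any(m.data.shape != shape for m in masks):
        raise GridError("lesion masks do not share a voxel grid")
    if flip_to_common_side:
        if sides is None or len(sides) != len(masks):
            raise SchemaError("flipping requires one lesion side per mask")
        arrays = [
            np.flip(m.data, axis=flip_axis) if s == "right" else m.data
            for m, s in zip(masks, sides)
        ]
    else:
        arrays = [m.data for m in masks]
    return np.mean(np.stack(arrays).astype(float), axis=0)
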