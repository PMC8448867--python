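"""Encode binary lesion masks against an atlas parcellation as lesion-load fractions.

Lesion load of a region is the fraction of its voxels overlapped by the
patient's lesion: ``|lesion ∩ region| / |region|``, a number in [0, 1]
(0 = region fully spared, 1 = region fully destroyed).  Atlas regions may come
from several atlases and may overlap; every region is kept as its own column.
Probabilistic atlas regions are binarised at a 50% threshold (inclusive)
before encoding.  Regions that no patient's lesion touches carry no
information and are pruned from the cohort matrix (recorded, not silently
dropped).

Masks and regions must already live on a common voxel grid (a shared template
space); resampling is out of scope and grid mismatches are rejected by
comparing ``space_tag``/shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LesionMask",
    "Region",
    "RegionSet",
    "LesionLoadMatrix",
    "binarize_probabilistic_region",
    "lesion_load",
    "encode_cohort",
    "load_mask_nifti",
    "load_region_set",
    "region_manifest_table",
]


@dataclass(frozen=True)
class LesionMask:
    """A single patient's binary lesion image on a common template grid.

    ``voxel_grid`` holds 1 where tissue is lesioned.  ``voxel_volume`` is the
    volume of one voxel in mm³ (8 for the usual 2 mm isotropic grid);
    ``space_tag`` identifies the template space and is checked against the
    atlas before encoding.
    """

    patient_id: str
    voxel_grid: np.ndarray
    voxel_volume: float = 8.0
    space_tag: str = "unspecified"

    def __post_init__(self) -> None:
        grid = np.asarray(self.voxel_grid)
        if grid.ndim != 3:
            raise ValueError(f"lesion mask for {self.patient_id!r} must be 3-D, got {grid.ndim}-D")
        vals = np.unique(grid)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(
                f"lesion mask for {self.patient_id!r} must be binary (0/1); found values {vals[:5]}"
            )
        object.__setattr__(self, "voxel_grid", grid.astype(bool))

    @property
    def n_lesioned(self) -> int:
        return int(self.voxel_grid.sum())

    @property
    def lesion_volume_mm3(self) -> float:
        return self.n_lesioned * self.voxel_volume


@dataclass(frozen=True)
class Region:
    """One named atlas region: a binary voxel-membership image plus provenance."""

    region_id: str
    atlas_id: str
    membership: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.membership).astype(bool)
        if m.ndim != 3:
            raise ValueError(f"region {self.region_id!r} membership must be 3-D")
        if not m.any():
            raise ValueError(f"region {self.region_id!r} has no member voxels")
        object.__setattr__(self, "membership", m)

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())


@dataclass(frozen=True)
class RegionSet:
    """An ordered collection of atlas regions sharing one voxel grid.

    Order is meaningful (atlas order, then region order within each atlas)
    and determines the column order of encoded matrices.  Regions from
    different atlases may overlap; no deduplication is performed.
    """

    regions: tuple[Region, ...]
    space_tag: str = "unspecified"

    def __post_init__(self) -> None:
        regions = tuple(self.regions)
        if not regions:
            raise ValueError("RegionSet needs at least one region")
        shapes = {r.membership.shape for r in regions}
        if len(shapes) > 1:
            raise ValueError(f"regions do not share one grid shape: {sorted(shapes)}")
        ids = [r.region_id for r in regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region_ids: {dupes}")
        object.__setattr__(self, "regions", regions)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.regions[0].membership.shape

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


@dataclass(frozen=True)
class LesionLoadMatrix:
    """Patients × regions matrix of lesion-load fractions in [0, 1]."""

    values: np.ndarray
    patient_ids: tuple[str, ...]
    region_ids: tuple[str, ...]
    dropped_region_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.patient_ids), len(self.region_ids)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.patient_ids)} patients × {len(self.region_ids)} regions"
            )
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("lesion loads must lie in [0, 1]")
        if set(self.dropped_region_ids) & set(self.region_ids):
            raise ValueError("dropped_region_ids overlap retained region_ids")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        object.__setattr__(self, "dropped_region_ids", tuple(self.dropped_region_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.patient_ids, name="patient_id"),
            columns=list(self.region_ids),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LesionLoadMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), tuple(df.index.astype(str)), tuple(df.columns))


def binarize_probabilistic_region(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarise a probabilistic region image: voxel = 1 iff probability ≥ threshold.

    The boundary is inclusive (a voxel exactly at the threshold is kept).
    """
    p = np.asarray(prob_map, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilistic map values must lie in [0, 1]")
    return (p >= threshold).astype(np.uint8)


def lesion_load(mask: LesionMask, region: np.ndarray) -> float:
    """Fraction of a region's voxels shared with the lesion.

    ``region`` is a binary membership image on the mask's grid.  An empty
    region is a configuration error (the ratio would be 0/0), not a zero.
    """
    reg = np.asarray(region).astype(bool)
    if reg.shape != mask.voxel_grid.shape:
        raise ValueError(
            f"grid mismatch: mask {mask.voxel_grid.shape} vs region {reg.shape}"
        )
    n_region = int(reg.sum())
    if n_region == 0:
        raise ValueError("region has no member voxels; cannot compute lesion load")
    return float(np.logical_and(mask.voxel_grid, reg).sum()) / n_region


def encode_cohort(
    masks: Sequence[LesionMask],
    regions: RegionSet,
    drop_zero_variance: bool = True,
) -> LesionLoadMatrix:
    """Encode a cohort of lesion masks as a patients × regions lesion-load matrix.

    Columns follow the RegionSet's order.  When ``drop_zero_variance``,
    columns that are exactly zero for every patient (regions untouched by any
    lesion) are removed and their ids recorded in ``dropped_region_ids``.
    All masks must share the RegionSet's space_tag and grid shape.
    """
    if not masks:
        raise ValueError("no lesion masks supplied")
    for m in masks:
        if m.space_tag != regions.space_tag:
            raise ValueError(
                f"patient {m.patient_id!r} is in space {m.space_tag!r}, "
                f"atlas expects {regions.space_tag!r}"
            )
        if m.voxel_grid.shape != regions.shape:
            raise ValueError(
                f"patient {m.patient_id!r} grid {m.voxel_grid.shape} "
                f"does not match atlas grid {regions.shape}"
            )
    # flatten regions once; loads for all patients via a single matrix product
    flat_regions = np.stack([r.membership.ravel() for r in regions]).astype(float)
    sizes = flat_regions.sum(axis=1)
    flat_masks = np.stack([m.voxel_grid.ravel() for m in masks]).astype(float)
    values = (flat_masks @ flat_regions.T) / sizes[None, :]

    region_ids = list(regions.region_ids)
    dropped: list[str] = []
    if drop_zero_variance:
        all_zero = ~(values > 0).any(axis=0)
        dropped = [rid for rid, z in zip(region_ids, all_zero) if z]
        values = values[:, ~all_zero]
        region_ids = [rid for rid, z in zip(region_ids, all_zero) if not z]
    return LesionLoadMatrix(
        values=values,
        patient_ids=tuple(m.patient_id for m in masks),
        region_ids=tuple(region_ids),
        dropped_region_ids=tuple(dropped),
    )


def region_manifest_table(regions: RegionSet) -> pd.DataFrame:
    """Region manifest (region_id, atlas_id, n_voxels) as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "atlas_id": [r.atlas_id for r in regions],
            "n_voxels": [r.n_voxels for r in regions],
        }
    )


# ---------------------------------------------------------------------------
# NIfTI IO


def load_mask_nifti(path: str | Path, patient_id: str | None = None,
                    space_tag: str = "unspecified") -> LesionMask:
    """Read a binary lesion mask from a NIfTI file.

    Voxel volume is taken from the image affine (zooms product); the patient
    id defaults to the file stem.
    """
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return LesionMask(
        patient_id=patient_id or stem,
        voxel_grid=(data > 0.5).astype(np.uint8),
        voxel_volume=float(np.prod(zooms)),
        space_tag=space_tag,
    )


def load_region_set(manifest: str | Path, threshold: float = 0.5,
                    space_tag: str = "unspecified") -> RegionSet:
    """Build a RegionSet from a TSV manifest with columns region_id, atlas_id, path.

    Paths are resolved relative to the manifest's directory.  Probabilistic
    images (values strictly between 0 and 1) are binarised at ``threshold``.
    """
    import nibabel as nib

    manifest = Path(manifest)
    table = pd.read_csv(manifest, sep="\t")
    required = {"region_id", "atlas_id", "path"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    regions = []
    for row in table.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest.parent / p
        data = np.asanyarray(nib.load(str(p)).dataobj).astype(float)
        membership = binarize_probabilistic_region(data, threshold)
        regions.append(Region(str(row.region_id), str(row.atlas_id), membership))
    return RegionSet(tuple(regions), space_tag=space_tag)
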