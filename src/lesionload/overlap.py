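"""Per-tract lesion-overlap percentages and aggregate CST lesion-load metrics.

The lesion load of a tract is the percentage of its voxels intersected by
the patient's lesion mask. Aggregates follow the summed-count convention:
the whole-CST load is ``100 * sum(overlapped voxels) / sum(tract voxels)``
over all six seed-region tracts of the affected hemisphere (equivalently a
voxel-weighted mean of the per-tract percentages), and the non-M1 load is
the same sum omitting the M1 tract only. Only the affected hemisphere's
tracts enter any metric, because left/right tract homologs differ slightly
in size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import LesionMask, lesion_volume
from .tracts import TractAtlas

__all__ = [
    "OverlapRecord",
    "tract_overlap",
    "hemisphere_overlap_records",
    "aggregate_overlap",
    "n_tracts_affected",
    "patient_overlap_row",
    "cohort_overlap_table",
]


@dataclass(frozen=True)
class OverlapRecord:
    """Lesion overlap of one tract for one patient."""

    patient_id: str
    region: str
    hemisphere: str
    tract_voxels: int
    overlapped_voxels: int

    def __post_init__(self) -> None:
        if not (0 <= self.overlapped_voxels <= self.tract_voxels):
            raise ValueError(
                f"{self.patient_id}/{self.region}: overlapped_voxels "
                f"{self.overlapped_voxels} outside [0, {self.tract_voxels}]"
            )

    @property
    def percent(self) -> float:
        return 100.0 * self.overlapped_voxels / self.tract_voxels


def tract_overlap(
    mask: LesionMask, atlas: TractAtlas, region: str, hemisphere: str
) -> OverlapRecord:
    """Overlap of one lesion with one named tract."""
    mask.grid.require_same_grid(atlas.grid, context=f"patient {mask.patient_id!r}")
    tract = atlas.get(region, hemisphere)
    overlapped = int(np.logical_and(mask.grid.values != 0, tract.mask).sum())
    return OverlapRecord(mask.patient_id, region, hemisphere, tract.n_voxels, overlapped)


def hemisphere_overlap_records(
    mask: LesionMask, atlas: TractAtlas, hemisphere: str | None = None
) -> list[OverlapRecord]:
    """Overlap records for every tract of one hemisphere (default: affected)."""
    hemi = hemisphere or mask.affected_hemisphere
    return [
        tract_overlap(mask, atlas, t.region, t.hemisphere)
        for t in atlas.hemisphere_tracts(hemi)
    ]


def aggregate_overlap(
    records: Sequence[OverlapRecord],
    include_regions: Iterable[str] | None = None,
    hemisphere: str | None = None,
) -> float:
    """Summed-count aggregate overlap percentage over a region set.

    ``100 * sum(overlapped) / sum(tract voxels)`` over the included regions.
    With all six regions this is the whole-CST load; excluding only M1 it
    is the non-M1 load. All records must come from one hemisphere.
    """
    records = list(records)
    if include_regions is not None:
        wanted = list(include_regions)
        if not wanted:
            raise ValueError("empty region set for aggregate overlap")
        records = [r for r in records if r.region in wanted]
        missing = set(wanted) - {r.region for r in records}
        if missing:
            raise ValueError(f"no records for regions {sorted(missing)}")
    if not records:
        raise ValueError("no overlap records to aggregate")
    hemis = {r.hemisphere for r in records}
    if len(hemis) > 1:
        raise ValueError(f"records mix hemispheres {sorted(hemis)}")
    if hemisphere is not None and hemis != {hemisphere}:
        raise ValueError(f"records are for hemisphere {hemis.pop()}, not {hemisphere}")
    total = sum(r.tract_voxels for r in records)
    hit = sum(r.overlapped_voxels for r in records)
    return 100.0 * hit / total


def n_tracts_affected(
    records: Sequence[OverlapRecord], threshold_voxels: int = 1
) -> int:
    """Number of tracts with at least ``threshold_voxels`` lesioned voxels."""
    return sum(r.overlapped_voxels >= threshold_voxels for r in records)


def patient_overlap_row(mask: LesionMask, atlas: TractAtlas) -> dict:
    """One CSV-ready row of all overlap metrics for a patient.

    Columns: ``patient_id``, ``hemisphere``, one ``<region>_percent`` per
    affected-hemisphere tract, ``cst_percent`` (all regions), ``non_m1_percent``
    (all but M1, when M1 is present), ``n_tracts_affected``, ``lesion_volume_mm3``.
    """
    records = hemisphere_overlap_records(mask, atlas)
    regions = [r.region for r in records]
    row: dict = {"patient_id": mask.patient_id, "hemisphere": mask.affected_hemisphere}
    for r in records:
        row[f"{r.region}_percent"] = r.percent
    row["cst_percent"] = aggregate_overlap(records)
    if "M1" in regions and len(regions) > 1:
        row["non_m1_percent"] = aggregate_overlap(
            records, include_regions=[r for r in regions if r != "M1"]
        )
    row["n_tracts_affected"] = n_tracts_affected(records)
    row["lesion_volume_mm3"] = lesion_volume(mask)
    return row


def cohort_overlap_table(
    masks: Sequence[LesionMask], atlas: TractAtlas
) -> pd.DataFrame:
    """Per-patient overlap metrics for a cohort, one row per patient."""
    rows = []
    for mask in masks:
        try:
            rows.append(patient_overlap_row(mask, atlas))
        except Exception as exc:
            raise type(exc)(f"patient {mask.patient_id!r}: {exc}") from exc
    return pd.DataFrame(rows)
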