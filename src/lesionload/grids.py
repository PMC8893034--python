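"""Voxel grids, binary lesion masks, and cohort lesion heat maps.

All overlap arithmetic in this package assumes every volume lives on one
shared voxel grid (the study design normalises everything to a single
template grid before any counting). Grids must therefore match exactly in
shape and voxel size; nothing here resamples. The first array axis is the
left-right axis with the midsagittal plane at ``nx / 2``, so hemisphere
flipping is a reversal of axis 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "LesionMask",
    "HeatMap",
    "GridMismatchError",
    "read_mask",
    "write_volume",
    "lesion_volume",
    "flip_to_left",
    "heat_map",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class VolumeGrid:
    """A 3-D voxel array with physical voxel dimensions.

    Parameters
    ----------
    values
        Non-negative integer array of shape ``(nx, ny, nz)``. Axis 0 is
        the left-right axis (low x = left hemisphere by convention).
    voxel_size
        Voxel edge lengths ``(dx, dy, dz)`` in millimetres.
    space_tag
        Free-text label for the coordinate space, e.g. ``"MNI152-2mm"``
        or ``"synthetic"``.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    space_tag: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume, got {self.values.ndim}-D "
                f"shape {self.values.shape}"
            )
        if min(self.values.shape) < 1:
            raise ValueError("all grid dimensions must be >= 1")
        if len(self.voxel_size) != 3 or any(d <= 0 for d in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if np.issubdtype(self.values.dtype, np.floating):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("grid values must be integers")
            self.values = self.values.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise ValueError("grid values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return float(dx * dy * dz)

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size
        )

    def require_same_grid(self, other: "VolumeGrid", context: str = "") -> None:
        prefix = f"{context}: " if context else ""
        if self.shape != other.shape:
            raise GridMismatchError(
                f"{prefix}grid shape mismatch {self.shape} vs {other.shape}"
            )
        if not np.allclose(self.voxel_size, other.voxel_size):
            raise GridMismatchError(
                f"{prefix}voxel size mismatch {self.voxel_size} vs {other.voxel_size}"
            )


@dataclass
class LesionMask:
    """A binary stroke lesion mask with its clinically affected hemisphere.

    ``affected_hemisphere`` is the hemisphere contralateral to the paretic
    upper limb; for bilateral strokes it is still a single side, and it is
    the side whose tracts enter every overlap metric.
    """

    grid: VolumeGrid
    affected_hemisphere: str
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.affected_hemisphere not in ("L", "R"):
            raise ValueError(
                f"affected_hemisphere must be 'L' or 'R', got {self.affected_hemisphere!r}"
            )
        vals = np.unique(self.grid.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("lesion mask values must be binary (0/1)")

    @property
    def n_lesion_voxels(self) -> int:
        return int(self.grid.values.sum())


@dataclass
class HeatMap:
    """Per-voxel count of patients with a lesion there (after flipping)."""

    grid: VolumeGrid
    n_patients: int
    percent_grid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("heat map needs at least one patient")
        if self.grid.values.max(initial=0) > self.n_patients:
            raise ValueError("heat map count exceeds number of patients")
        self.percent_grid = 100.0 * self.grid.values / self.n_patients

    @property
    def max_count(self) -> int:
        return int(self.grid.values.max(initial=0))


def _voxel_size_from_header(img: nib.spatialimages.SpatialImage) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def read_mask(
    path: str | Path,
    affected_hemisphere: str,
    patient_id: str | None = None,
    space_tag: str = "unspecified",
) -> LesionMask:
    """Read a binary lesion mask from a NIfTI file.

    Non-binary values (e.g. label values left over from segmentation) are
    binarised nonzero -> 1 with a warning. A 4-D input is an error; an
    all-zero volume is allowed but noted with a warning, since an empty
    lesion usually means the wrong file.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D mask, got shape {data.shape}")
    nonzero = data != 0
    uniq = np.unique(data)
    if not np.isin(uniq, (0, 1)).all():
        warnings.warn(
            f"{path.name}: non-binary mask values {uniq[:8]}...; binarising nonzero -> 1",
            stacklevel=2,
        )
    if not nonzero.any():
        warnings.warn(f"{path.name}: lesion mask is empty", stacklevel=2)
    grid = VolumeGrid(
        nonzero.astype(np.int64),
        voxel_size=_voxel_size_from_header(img),
        space_tag=space_tag,
    )
    return LesionMask(grid, affected_hemisphere, patient_id or path.stem.split(".")[0])


def write_volume(grid: VolumeGrid, path: str | Path, dtype=np.int16) -> None:
    """Write a VolumeGrid as NIfTI with a diagonal affine from its voxel size."""
    affine = np.diag(list(grid.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=dtype), affine)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))


def lesion_volume(mask: LesionMask) -> float:
    """Lesion volume in mm^3: voxel count times the voxel volume."""
    return mask.n_lesion_voxels * mask.grid.voxel_volume_mm3


def flip_to_left(mask: LesionMask) -> LesionMask:
    """Mirror a right-affected mask across the midsagittal plane.

    Voxel ``(x, y, z)`` maps to ``(nx - 1 - x, y, z)``; a left-affected
    mask is returned unchanged (same object contents, new instance).
    The lesion voxel count is conserved.
    """
    if mask.affected_hemisphere == "L":
        return LesionMask(
            VolumeGrid(mask.grid.values.copy(), mask.grid.voxel_size, mask.grid.space_tag),
            "L",
            mask.patient_id,
        )
    flipped = VolumeGrid(
        mask.grid.values[::-1, :, :].copy(),
        mask.grid.voxel_size,
        mask.grid.space_tag,
    )
    return LesionMask(flipped, "L", mask.patient_id)


def heat_map(masks: Sequence[LesionMask] | Iterable[LesionMask]) -> HeatMap:
    """Cohort lesion-overlap heat map with all lesions flipped onto the left.

    Each voxel counts the patients whose (flipped) lesion covers it; the
    percent grid expresses that count as a percentage of the cohort.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("heat_map needs at least one mask")
    ref = masks[0].grid
    counts = np.zeros(ref.shape, dtype=np.int64)
    for m in masks:
        ref.require_same_grid(m.grid, context=f"patient {m.patient_id!r}")
        counts += flip_to_left(m).grid.values
    grid = VolumeGrid(counts, ref.voxel_size, ref.space_tag)
    return HeatMap(grid, n_patients=len(masks))
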