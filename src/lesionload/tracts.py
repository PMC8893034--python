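"""Labeled white-matter tract atlases on a shared voxel grid.

An atlas names each descending corticospinal-tract (CST) contribution by
its cortical seed region (M1, PMd, PMv, SMA, preSMA, S1 for a sensorimotor
tract template; free labels for generic atlases) and hemisphere. Two input
dialects are supported, because published atlas distributions differ:

* one integer-labeled NIfTI plus a JSON sidecar mapping label -> tract, or
* one binary NIfTI per tract.

Tracts are expected to be pairwise disjoint in voxel space; overlap is
warned about but tolerated, since thresholded templates only minimise it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

from .grids import VolumeGrid

CST_REGIONS = ("M1", "PMd", "PMv", "SMA", "preSMA", "S1")
HEMISPHERES = ("L", "R")

__all__ = ["CST_REGIONS", "HEMISPHERES", "Tract", "TractAtlas", "read_atlas"]


@dataclass
class Tract:
    """One tract: a cortical seed region, a hemisphere, and its voxel set."""

    region: str
    hemisphere: str
    mask: np.ndarray  # boolean, on the atlas grid

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be L or R, got {self.hemisphere!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.n_voxels < 1:
            raise ValueError(f"tract {self.region}/{self.hemisphere} has no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def key(self) -> tuple[str, str]:
        return (self.region, self.hemisphere)


class TractAtlas:
    """A collection of named tracts sharing one voxel grid."""

    def __init__(self, tracts: Sequence[Tract], grid: VolumeGrid):
        if not tracts:
            raise ValueError("atlas needs at least one tract")
        keys = [t.key for t in tracts]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (region, hemisphere) pairs in atlas")
        for t in tracts:
            if t.mask.shape != grid.shape:
                raise ValueError(
                    f"tract {t.region}/{t.hemisphere} shape {t.mask.shape} "
                    f"does not match atlas grid {grid.shape}"
                )
        stacked = np.sum([t.mask for t in tracts], axis=0)
        if stacked.max(initial=0) > 1:
            warnings.warn(
                f"{int((stacked > 1).sum())} voxels belong to more than one tract; "
                "each tract is still counted independently",
                stacklevel=2,
            )
        self.tracts = list(tracts)
        self.grid = grid
        self._by_key = {t.key: t for t in tracts}

    def __len__(self) -> int:
        return len(self.tracts)

    def get(self, region: str, hemisphere: str) -> Tract:
        try:
            return self._by_key[(region, hemisphere)]
        except KeyError:
            raise KeyError(
                f"no tract {region!r}/{hemisphere!r}; atlas has "
                f"{sorted(self._by_key)}"
            ) from None

    def regions(self, hemisphere: str | None = None) -> list[str]:
        seen: list[str] = []
        for t in self.tracts:
            if hemisphere is not None and t.hemisphere != hemisphere:
                continue
            if t.region not in seen:
                seen.append(t.region)
        return seen

    def hemisphere_tracts(self, hemisphere: str) -> list[Tract]:
        return [t for t in self.tracts if t.hemisphere == hemisphere]

    def label_volume(self) -> tuple[VolumeGrid, dict[int, tuple[str, str]]]:
        """Flatten to one integer-labeled volume plus a label map.

        Labels are assigned 1..n in tract order; where tracts overlap the
        later tract wins (only relevant for non-disjoint atlases).
        """
        labels = np.zeros(self.grid.shape, dtype=np.int64)
        label_map: dict[int, tuple[str, str]] = {}
        for i, t in enumerate(self.tracts, start=1):
            labels[t.mask] = i
            label_map[i] = t.key
        return VolumeGrid(labels, self.grid.voxel_size, self.grid.space_tag), label_map


def _load_3d(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D atlas volume, got {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return data, (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def read_atlas(
    path: str | Path,
    labels: str | Path | Mapping[str, Sequence[str]] | None = None,
    space_tag: str = "unspecified",
) -> TractAtlas:
    """Read a tract atlas.

    ``path`` is either a labeled NIfTI (then ``labels`` is required: a JSON
    file or mapping ``{"<label int>": [region, hemisphere], ...}``), or a
    directory of per-tract binary NIfTIs named ``<region>_<hemisphere>.nii[.gz]``.
    """
    path = Path(path)
    if path.is_dir():
        tracts: list[Tract] = []
        vsize = None
        files = sorted(p for p in path.iterdir() if p.name.endswith((".nii", ".nii.gz")))
        if not files:
            raise ValueError(f"no NIfTI files in atlas directory {path}")
        for f in files:
            stem = f.name.removesuffix(".nii.gz").removesuffix(".nii")
            try:
                region, hemi = stem.rsplit("_", 1)
            except ValueError:
                raise ValueError(
                    f"{f.name}: per-tract files must be named <region>_<L|R>.nii[.gz]"
                ) from None
            data, vs = _load_3d(f)
            vsize = vsize or vs
            tracts.append(Tract(region, hemi, data != 0))
        grid = VolumeGrid(
            np.zeros(tracts[0].mask.shape, dtype=np.int64), vsize, space_tag
        )
        return TractAtlas(tracts, grid)

    if labels is None:
        raise ValueError("a labeled-NIfTI atlas requires a JSON label map")
    if isinstance(labels, (str, Path)):
        with open(labels) as fh:
            labels = json.load(fh)
    data, vsize = _load_3d(path)
    data = np.round(data).astype(np.int64)
    tracts = []
    for label_str, (region, hemi) in sorted(labels.items(), key=lambda kv: int(kv[0])):
        mask = data == int(label_str)
        if not mask.any():
            raise ValueError(f"label {label_str} ({region}/{hemi}) has no voxels")
        tracts.append(Tract(region, hemi, mask))
    grid = VolumeGrid(np.zeros(data.shape, dtype=np.int64), vsize, space_tag)
    return TractAtlas(tracts, grid)


def write_atlas(atlas: TractAtlas, nifti_path: str | Path, labels_path: str | Path) -> None:
    """Write an atlas as one labeled NIfTI plus its JSON label map."""
    from .grids import write_volume

    labeled, label_map = atlas.label_volume()
    write_volume(labeled, nifti_path)
    with open(labels_path, "w") as fh:
        json.dump({str(k): list(v) for k, v in label_map.items()}, fh, indent=1)
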