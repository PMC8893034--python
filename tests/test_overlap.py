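"""Per-tract overlap arithmetic against an exhaustive voxel-loop oracle."""

import numpy as np
import pytest

from lesionload import (
    LesionMask,
    Tract,
    TractAtlas,
    VolumeGrid,
    aggregate_overlap,
    cohort_overlap_table,
    hemisphere_overlap_records,
    n_tracts_affected,
    tract_overlap,
)
from lesionload.overlap import OverlapRecord
from tests.conftest import mask_from_voxels


def brute_force_overlap(lesion_vals, tract_mask):
    """Triple-loop voxel counter: the independent oracle."""
    nx, ny, nz = lesion_vals.shape
    tract_n = hit = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if tract_mask[x, y, z]:
                    tract_n += 1
                    if lesion_vals[x, y, z]:
                        hit += 1
    return tract_n, hit


def random_atlas_and_mask(rng, shape):
    """A random 2-4 tract single-hemisphere atlas and lesion on ``shape``."""
    n_tracts = rng.integers(2, 5)
    tracts = []
    for i in range(n_tracts):
        m = rng.random(shape) < rng.uniform(0.05, 0.4)
        if not m.any():
            m[tuple(rng.integers(0, s) for s in shape)] = True
        tracts.append(Tract(f"T{i}", "L", m))
    grid = VolumeGrid(np.zeros(shape, dtype=np.int64), (2.0, 2.0, 2.0), "rand")
    lesion = (rng.random(shape) < rng.uniform(0.0, 0.5)).astype(np.int64)
    mask = LesionMask(VolumeGrid(lesion, (2.0, 2.0, 2.0), "rand"), "L", "p")
    # random tracts may overlap; the atlas warns about that by design
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        atlas = TractAtlas(tracts, grid)
    return atlas, mask


class TestTractOverlap:
    def test_empty_lesion_zero_percent(self, small_atlas):
        mask = mask_from_voxels((6, 6, 6), [])
        assert tract_overlap(mask, small_atlas, "M1", "L").percent == 0.0

    def test_lesion_covering_tract_is_100(self, small_atlas):
        mask = LesionMask(
            VolumeGrid(np.ones((6, 6, 6), dtype=np.int64), (2.0, 2.0, 2.0), "toy"), "L"
        )
        assert tract_overlap(mask, small_atlas, "M1", "L").percent == 100.0

    def test_partial_overlap_25_percent(self, small_atlas):
        # M1 L occupies x 0:2, y 0:2, z 0:5 (20 voxels); lesion 5 of them
        voxels = [(0, 0, z) for z in range(5)]
        mask = mask_from_voxels((6, 6, 6), voxels)
        rec = tract_overlap(mask, small_atlas, "M1", "L")
        assert (rec.tract_voxels, rec.overlapped_voxels) == (20, 5)
        assert rec.percent == pytest.approx(25.0)

    def test_missing_tract_and_grid_mismatch(self, small_atlas):
        mask = mask_from_voxels((6, 6, 6), [])
        with pytest.raises(KeyError, match="SMA"):
            tract_overlap(mask, small_atlas, "SMA", "L")
        small = mask_from_voxels((5, 5, 5), [])
        with pytest.raises(Exception, match="mismatch"):
            tract_overlap(small, small_atlas, "M1", "L")

    @pytest.mark.parametrize("seed", range(50))
    def test_oracle_equivalence_on_random_fixtures(self, seed):
        """Counts and percents match the exhaustive voxel loop exactly."""
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 9, size=3))
        atlas, mask = random_atlas_and_mask(rng, shape)
        for t in atlas.tracts:
            rec = tract_overlap(mask, atlas, t.region, "L")
            tract_n, hit = brute_force_overlap(mask.grid.values, t.mask)
            assert (rec.tract_voxels, rec.overlapped_voxels) == (tract_n, hit)
            assert rec.percent == pytest.approx(100.0 * hit / tract_n)

    def test_monotone_in_lesion_voxels(self, small_atlas):
        rng = np.random.default_rng(5)
        vals = (rng.random((6, 6, 6)) < 0.2).astype(np.int64)
        base = LesionMask(VolumeGrid(vals, (2.0, 2.0, 2.0), "toy"), "L")
        grown_vals = vals.copy()
        grown_vals[(rng.random((6, 6, 6)) < 0.2)] = 1
        grown = LesionMask(VolumeGrid(grown_vals, (2.0, 2.0, 2.0), "toy"), "L")
        for region in ("M1", "PMv"):
            assert (
                tract_overlap(grown, small_atlas, region, "L").percent
                >= tract_overlap(base, small_atlas, region, "L").percent
            )


class TestAggregateOverlap:
    def rec(self, region, n, hit, hemi="L"):
        return OverlapRecord("p", region, hemi, n, hit)

    def test_summed_count_formula(self):
        records = [self.rec("M1", 10, 5), self.rec("PMv", 30, 6)]
        assert aggregate_overlap(records) == pytest.approx(100 * 11 / 40)

    def test_zero_and_single_region_cases(self):
        records = [self.rec("M1", 10, 0), self.rec("PMv", 30, 0)]
        assert aggregate_overlap(records) == 0.0
        single = [self.rec("PMv", 30, 6)]
        assert aggregate_overlap(single) == pytest.approx(single[0].percent)

    def test_empty_region_set_and_mixed_hemispheres_rejected(self):
        records = [self.rec("M1", 10, 5)]
        with pytest.raises(ValueError, match="empty region set"):
            aggregate_overlap(records, include_regions=[])
        mixed = [self.rec("M1", 10, 5), self.rec("PMv", 30, 6, hemi="R")]
        with pytest.raises(ValueError, match="hemispheres"):
            aggregate_overlap(mixed)

    @pytest.mark.parametrize("seed", range(10))
    def test_aggregate_is_voxel_weighted_mean_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            self.rec(f"T{i}", int(n), int(rng.integers(0, n + 1)))
            for i, n in enumerate(rng.integers(1, 50, size=6))
        ]
        agg = aggregate_overlap(records)
        weighted = sum(r.tract_voxels * r.percent for r in records) / sum(
            r.tract_voxels for r in records
        )
        assert agg == pytest.approx(weighted)
        assert min(r.percent for r in records) <= agg <= max(r.percent for r in records)


class TestNTractsAffected:
    @pytest.mark.parametrize(
        "hits,expected", [((0, 0, 0, 0, 0, 0), 0), ((1, 1, 1, 1, 1, 1), 6), ((3, 0, 1, 0, 0, 0), 2)]
    )
    def test_threshold_one_voxel(self, hits, expected):
        records = [
            OverlapRecord("p", f"T{i}", "L", 10, h) for i, h in enumerate(hits)
        ]
        assert n_tracts_affected(records) == expected


class TestCohortTable:
    def test_shape_and_columns(self, small_atlas):
        masks = [
            mask_from_voxels((6, 6, 6), [(0, 0, 0)], "L", "p1"),
            mask_from_voxels((6, 6, 6), [], "R", "p2"),
            mask_from_voxels((6, 6, 6), [(5, 4, 0)], "R", "p3"),
        ]
        table = cohort_overlap_table(masks, small_atlas)
        assert len(table) == 3
        for col in ("patient_id", "hemisphere", "M1_percent", "PMv_percent",
                    "cst_percent", "non_m1_percent", "n_tracts_affected",
                    "lesion_volume_mm3"):
            assert col in table.columns

    def test_empty_lesion_gives_all_zero_row(self, small_atlas):
        table = cohort_overlap_table(
            [mask_from_voxels((6, 6, 6), [], "L", "p0")], small_atlas
        )
        row = table.iloc[0]
        assert row["cst_percent"] == 0.0
        assert row["n_tracts_affected"] == 0
        assert row["lesion_volume_mm3"] == 0.0

    def test_grid_mismatch_names_patient(self, small_atlas):
        masks = [mask_from_voxels((5, 5, 5), [], "L", "bad_patient")]
        with pytest.raises(Exception, match="bad_patient"):
            cohort_overlap_table(masks, small_atlas)

    def test_matches_brute_force_recomputation(self, small_atlas):
        rng = np.random.default_rng(21)
        masks = []
        for i in range(3):
            vals = (rng.random((6, 6, 6)) < 0.3).astype(np.int64)
            masks.append(
                LesionMask(VolumeGrid(vals, (2.0, 2.0, 2.0), "toy"), "L", f"p{i}")
            )
        table = cohort_overlap_table(masks, small_atlas).set_index("patient_id")
        for m in masks:
            total_n = total_hit = 0
            for t in small_atlas.hemisphere_tracts("L"):
                tract_n, hit = brute_force_overlap(m.grid.values, t.mask)
                assert table.loc[m.patient_id, f"{t.region}_percent"] == pytest.approx(
                    100.0 * hit / tract_n
                )
                total_n += tract_n
                total_hit += hit
            assert table.loc[m.patient_id, "cst_percent"] == pytest.approx(
                100.0 * total_hit / total_n
            )
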