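import numpy as np
import pytest

from clearcount3d.detection import CandidateObject
from clearcount3d.quantify import (
    RegionReport,
    assign_regions,
    assign_regions_by_centroid,
    density_map,
    exclude_region,
    group_stats,
)
from clearcount3d.synthetic import make_toy_atlas

MESO = (3.0, 3.26, 3.26)  # µm


def make_cell(voxels, cid=1, spacing=MESO):
    voxels = np.asarray(voxels)
    return CandidateObject(
        id=cid,
        voxels=voxels,
        centroid=tuple(voxels.mean(axis=0)),
        volume_vox=len(voxels),
        volume_um3=float(len(voxels) * np.prod(spacing)),
        max_Id=2.0,
        mean_Id=1.5,
        label="cell",
    )


class TestDensityMap:
    def test_single_cell_in_one_coarse_voxel(self):
        # 20 voxels at 3.26 × 3.26 × 3 µm all land in coarse voxel (0,0,0)
        voxels = np.argwhere(np.ones((4, 5, 1), dtype=bool))
        dmap = density_map([make_cell(voxels)], MESO, fine_shape=(64, 64, 64), coarse_spacing=25.0)
        expected = 20 * 3.26 * 3.26 * 3.0
        assert dmap.grid[0, 0, 0] == pytest.approx(expected)
        assert dmap.total_volume_um3 == pytest.approx(expected)
        assert np.count_nonzero(dmap.grid) == 1

    def test_no_cells_all_zero(self):
        dmap = density_map([], MESO, fine_shape=(32, 32, 32))
        assert not dmap.grid.any()

    def test_exact_conservation(self, rng):
        cells = [
            make_cell(rng.integers(0, 64, size=(rng.integers(5, 40), 3)), cid=i) for i in range(10)
        ]
        dmap = density_map(cells, MESO, fine_shape=(64, 64, 64))
        assert dmap.total_volume_um3 == pytest.approx(sum(len(c.voxels) * np.prod(MESO) for c in cells))

    def test_out_of_grid_voxels_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            density_map([make_cell([[70, 0, 0]])], MESO, fine_shape=(64, 64, 64))

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError):
            density_map([], MESO, fine_shape=(8, 8, 8), coarse_spacing=0.0)


def five_box_atlas(shape=(10, 4, 4)):
    boxes = [(i + 1, (2 * i, 0, 0), (2, 4, 4)) for i in range(5)]
    atlas = make_toy_atlas(shape, (25.0, 25.0, 25.0), boxes)
    names = ["brainstem", "hippocampus", "hypothalamus", "cortex", "thalamus"]
    atlas.region_table = {i + 1: (names[i], names[i]) for i in range(5)}
    return atlas, names


class TestAssignRegions:
    def test_planted_counts_per_box(self):
        atlas, names = five_box_atlas()
        grid = np.zeros((10, 4, 4))
        for i in range(5):
            grid[2 * i, 0, 0] = (i + 1) * 10.0  # i+1 "cells" of volume 10
        from clearcount3d.quantify import DensityMap

        totals = assign_regions(DensityMap(grid, 25.0), atlas)
        for i, name in enumerate(names):
            assert totals[name] == pytest.approx((i + 1) * 10.0)
        assert totals["unassigned"] == 0.0

    def test_label_zero_goes_to_unassigned_conserved(self):
        atlas, _ = five_box_atlas()
        from clearcount3d.quantify import DensityMap

        grid = np.zeros((10, 4, 4))
        grid[0, 3, 3] = 5.0  # inside box 1
        atlas2 = atlas
        grid_outside = np.zeros((12, 4, 4))  # mismatched shape must fail
        with pytest.raises(ValueError, match="match"):
            assign_regions(DensityMap(grid_outside, 25.0), atlas2)
        # a voxel in label-0 territory
        atlas3, _ = five_box_atlas(shape=(12, 4, 4))
        atlas3.labels[10:, :, :] = 0
        grid3 = np.zeros((12, 4, 4))
        grid3[11, 0, 0] = 7.0
        totals = assign_regions(DensityMap(grid3, 25.0), atlas3)
        assert totals["unassigned"] == pytest.approx(7.0)
        assert sum(totals.values()) == pytest.approx(7.0)

    def test_label_permutation_permutes_totals(self, rng):
        atlas, names = five_box_atlas()
        from clearcount3d.quantify import DensityMap

        grid = rng.random((10, 4, 4))
        totals = assign_regions(DensityMap(grid, 25.0), atlas)
        perm = [3, 4, 5, 1, 2]
        permuted_labels = np.zeros_like(atlas.labels)
        for old, new in zip(range(1, 6), perm):
            permuted_labels[atlas.labels == old] = new
        atlas_perm, _ = five_box_atlas()
        atlas_perm.labels = permuted_labels
        totals_perm = assign_regions(DensityMap(grid, 25.0), atlas_perm)
        for old, new in zip(range(1, 6), perm):
            assert totals_perm[names[new - 1]] == pytest.approx(totals[names[old - 1]])

    def test_centroid_mode_conserves_volume(self, rng):
        atlas, _ = five_box_atlas()
        cells = [make_cell(rng.integers(0, 30, size=(8, 3)), cid=i, spacing=MESO) for i in range(6)]
        totals = assign_regions_by_centroid(cells, MESO, atlas)
        assert sum(totals.values()) == pytest.approx(sum(c.volume_um3 for c in cells))


class TestExcludeRegion:
    def _report(self):
        return RegionReport(samples={"s1": {"cortex": 10.0, "cerebellum": 3.0, "unassigned": 1.0}})

    def test_exclusion_removes_and_logs(self):
        report = exclude_region(self._report(), "cerebellum")
        assert "cerebellum" not in report.samples["s1"]
        assert report.excluded_regions == ["cerebellum"]

    def test_idempotent(self):
        report = exclude_region(exclude_region(self._report(), "cerebellum"), "cerebellum")
        assert report.excluded_regions == ["cerebellum"]

    def test_absent_region_warns(self):
        with pytest.warns(UserWarning, match="not present"):
            exclude_region(self._report(), "olfactory bulb")

    def test_excluding_all_regions_keeps_unassigned(self):
        report = exclude_region(exclude_region(self._report(), "cortex"), "cerebellum")
        assert report.samples["s1"] == {"unassigned": 1.0}

    def test_unassigned_cannot_be_excluded(self):
        with pytest.raises(ValueError):
            exclude_region(self._report(), "unassigned")


class TestGroupStats:
    def test_identical_samples_zero_sd(self):
        report = RegionReport(samples={"a": {"cortex": 5.0}, "b": {"cortex": 5.0}})
        stats = group_stats(report, {"a": "g", "b": "g"})
        row = stats.iloc[0]
        assert row["mean_um3"] == 5.0 and row["sd_um3"] == 0.0

    def test_two_sample_mean(self):
        report = RegionReport(samples={"a": {"cortex": 2.0}, "b": {"cortex": 8.0}})
        stats = group_stats(report, {"a": "g", "b": "g"})
        assert stats.iloc[0]["mean_um3"] == pytest.approx(5.0)

    def test_matches_brute_force_mean_sd(self, rng):
        values = rng.random(7) * 100
        samples = {f"s{i}": {"cortex": float(v)} for i, v in enumerate(values)}
        stats = group_stats(RegionReport(samples=samples), {f"s{i}": "g" for i in range(7)})
        assert stats.iloc[0]["mean_um3"] == pytest.approx(values.mean())
        assert stats.iloc[0]["sd_um3"] == pytest.approx(values.std(ddof=1))

    def test_single_sample_sd_flagged_not_fabricated(self):
        stats = group_stats(RegionReport(samples={"a": {"cortex": 5.0}}), {"a": "g"})
        assert stats.iloc[0]["n_samples"] == 1
        assert np.isnan(stats.iloc[0]["sd_um3"])

    def test_unassigned_sample_rejected(self):
        report = RegionReport(samples={"a": {"cortex": 1.0}})
        with pytest.raises(ValueError, match="without group"):
            group_stats(report, {})


def test_planted_region_ordering_is_recovered(rng):
    """Plant per-region densities ordered cortex > hippocampus > brainstem >
    hypothalamus > thalamus and verify the ranked totals reproduce it."""
    atlas, names = five_box_atlas()
    ordering = ["cortex", "hippocampus", "brainstem", "hypothalamus", "thalamus"]
    planted = {name: (5 - rank) * 1000.0 for rank, name in enumerate(ordering)}
    from clearcount3d.quantify import DensityMap

    grid = np.zeros((10, 4, 4))
    for label, (region, _) in atlas.region_table.items():
        grid[2 * (label - 1), 1, 1] = planted[region]
    totals = assign_regions(DensityMap(grid, 25.0), atlas)
    ranked = sorted(ordering, key=lambda r: -totals[r])
    assert ranked == ordering
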