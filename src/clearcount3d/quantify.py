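"""Regional quantification: density maps, atlas assignment, group statistics.

Classified cells are binned into a coarse density map holding the physical
volume (µm³) of detected cells per cubic voxel of side 25 µm (the atlas
resolution).  Each fine voxel contributes its full physical volume to the
coarse voxel containing its center, so total volume is conserved exactly
through the whole chain: Σ cell volumes = Σ density map = Σ region totals
(including the "unassigned" bucket).  An integer-labeled atlas grid congruent
with the coarse map assigns each coarse voxel's volume to a super-region;
per-group means and sample SDs (N−1) summarize samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clearcount3d.detection import CandidateObject
from clearcount3d.io import AtlasVolume

__all__ = [
    "DensityMap",
    "RegionReport",
    "density_map",
    "assign_regions",
    "assign_regions_by_centroid",
    "exclude_region",
    "group_stats",
]

UNASSIGNED = "unassigned"


@dataclass
class DensityMap:
    """Coarse 3D field of detected-cell volume (µm³) per coarse voxel."""

    grid: np.ndarray
    spacing: float = 25.0  # coarse voxel side, µm

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"coarse spacing must be > 0; got {self.spacing}")

    @property
    def total_volume_um3(self) -> float:
        return float(self.grid.sum())


@dataclass
class RegionReport:
    """Per-sample region → cell-volume totals (µm³) plus exclusions."""

    samples: dict[str, dict[str, float]]
    excluded_regions: list[str] = field(default_factory=list)


def density_map(
    cells: list[CandidateObject],
    fine_spacing: tuple[float, float, float],
    fine_shape: tuple[int, int, int],
    coarse_spacing: float = 25.0,
) -> DensityMap:
    """Bin classified cell voxels into a coarse volume-density grid.

    Each cell voxel's center at ``(index + 0.5) × fine_spacing`` µm lands in
    the coarse voxel ``floor(position / coarse_spacing)``; the voxel's full
    physical volume is added there (no partial-volume splitting), so the map
    total equals the summed cell volumes exactly.
    """
    if coarse_spacing <= 0 or any(s <= 0 for s in fine_spacing):
        raise ValueError("spacings must be strictly positive")
    fine_spacing = tuple(float(s) for s in fine_spacing)
    coarse_shape = tuple(
        int(np.ceil(n * s / coarse_spacing)) for n, s in zip(fine_shape, fine_spacing)
    )
    counts = np.zeros(coarse_shape, dtype=np.int64)
    voxel_volume = float(np.prod(fine_spacing))
    for obj in cells:
        coords = np.asarray(obj.voxels, dtype=np.float64)
        if np.any(coords < 0) or np.any(coords >= np.asarray(fine_shape)):
            raise ValueError(f"object {obj.id} has voxels outside the fine grid {fine_shape}")
        centers = (coords + 0.5) * np.asarray(fine_spacing)
        idx = np.floor(centers / coarse_spacing).astype(np.intp)
        idx = np.minimum(idx, np.asarray(coarse_shape) - 1)  # voxel exactly on the far face
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    # integer counts scaled once: conservation holds to 64-bit rounding
    return DensityMap(grid=counts * voxel_volume, spacing=coarse_spacing)


def assign_regions(dmap: DensityMap, atlas: AtlasVolume) -> dict[str, float]:
    """Per-voxel region assignment: sum each coarse voxel's volume into its label's super-region.

    The atlas grid must be congruent with the density map (same coarse shape);
    label 0 accrues to the "unassigned" bucket.
    """
    if atlas.labels.shape != dmap.grid.shape:
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match density map {dmap.grid.shape}; "
            "resample or supply a co-registered atlas"
        )
    flat_labels = atlas.labels.ravel()
    sums = np.bincount(flat_labels, weights=dmap.grid.ravel())
    totals: dict[str, float] = {}
    for label, value in enumerate(sums):
        if value == 0 and label != 0:
            continue
        region = UNASSIGNED if label == 0 else atlas.super_region_of(label)
        totals[region] = totals.get(region, 0.0) + float(value)
    # every table region appears, even at zero volume
    for label, (_, super_region) in atlas.region_table.items():
        totals.setdefault(super_region, 0.0)
    totals.setdefault(UNASSIGNED, 0.0)
    return totals


def assign_regions_by_centroid(
    cells: list[CandidateObject],
    fine_spacing: tuple[float, float, float],
    atlas: AtlasVolume,
) -> dict[str, float]:
    """Per-cell assignment: each cell's whole volume goes to the region under its centroid.

    Comparison mode to per-voxel assignment; also volume-conserving, but a
    cell straddling a boundary is not split.
    """
    totals: dict[str, float] = {UNASSIGNED: 0.0}
    for label, (_, super_region) in atlas.region_table.items():
        totals.setdefault(super_region, 0.0)
    fine = np.asarray(fine_spacing)
    for obj in cells:
        pos = (np.asarray(obj.centroid) + 0.5) * fine
        idx = np.floor(pos / np.asarray(atlas.spacing)).astype(np.intp)
        idx = np.minimum(np.maximum(idx, 0), np.asarray(atlas.labels.shape) - 1)
        label = int(atlas.labels[tuple(idx)])
        region = UNASSIGNED if label == 0 else atlas.super_region_of(label)
        totals[region] = totals.get(region, 0.0) + obj.volume_um3
    return totals


def exclude_region(report: RegionReport, region_name: str) -> RegionReport:
    """Drop a region (e.g. cerebellum, for its Purkinje-cell autofluorescence).

    Idempotent; a region absent everywhere is a warned no-op.  The
    "unassigned" bucket cannot be excluded.
    """
    if region_name == UNASSIGNED:
        raise ValueError("the unassigned bucket cannot be excluded")
    present = any(region_name in sample for sample in report.samples.values())
    if not present and region_name not in report.excluded_regions:
        warnings.warn(f"exclude_region: region {region_name!r} not present in any sample", stacklevel=2)
    samples = {
        name: {region: vol for region, vol in totals.items() if region != region_name}
        for name, totals in report.samples.items()
    }
    excluded = list(report.excluded_regions)
    if region_name not in excluded:
        excluded.append(region_name)
    return RegionReport(samples=samples, excluded_regions=excluded)


def group_stats(report: RegionReport, group_assignment: dict[str, str]) -> pd.DataFrame:
    """Group-wise mean and sample SD of per-region cell volume.

    Returns a tidy frame (group, region, mean_um3, sd_um3, n_samples); for a
    single-sample group the SD is NaN — flagged, not fabricated.
    """
    missing = set(report.samples) - set(group_assignment)
    if missing:
        raise ValueError(f"samples without group assignment: {sorted(missing)}")
    rows = []
    groups: dict[str, list[str]] = {}
    for sample, group in group_assignment.items():
        if sample in report.samples:
            groups.setdefault(group, []).append(sample)
    for group, members in sorted(groups.items()):
        if not members:
            raise ValueError(f"group {group!r} has no samples")
        regions = sorted({r for m in members for r in report.samples[m]})
        for region in regions:
            values = np.array([report.samples[m].get(region, 0.0) for m in members])
            rows.append(
                {
                    "group": group,
                    "region": region,
                    "mean_um3": float(values.mean()),
                    "sd_um3": float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
                    "n_samples": len(values),
                }
            )
    return pd.DataFrame(rows, columns=["group", "region", "mean_um3", "sd_um3", "n_samples"])
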