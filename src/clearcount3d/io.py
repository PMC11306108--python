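"""Volume and table I/O plus the shared 3D data model.

Volumes are plain multi-page grayscale TIFFs, one page per z-slice, with the
axis order fixed to ``(z, y, x)`` throughout the package.  Intensities are
kept in the camera's native scale — the restoration stage divides the raw
data by its own smoothed copy, so any global gain cancels and rescaling to
[0, 1] would be redundant.  Computation happens in float64; files are written
as float32.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Volume3D",
    "AtlasVolume",
    "read_volume",
    "write_volume",
    "read_region_table",
]


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data
        Array of shape ``(z, y, x)``; finite values.
    spacing
        Physical voxel size in µm per axis, ordered ``(z, y, x)``.
    name
        Free-text provenance label.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D (z, y, x); got shape {self.data.shape}")
        if self.data.size == 0:
            raise ValueError("volume data must be non-empty")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values (z, y, x); got {self.spacing}")
        self.spacing = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, name: str | None = None) -> "Volume3D":
        """New volume sharing this one's spacing (derived fields I_n, I_d, ...)."""
        return Volume3D(data=data, spacing=self.spacing, name=self.name if name is None else name)


@dataclass
class AtlasVolume:
    """An integer-labeled atlas grid (0 = unassigned) with a region lookup.

    ``region_table`` maps each nonzero label to ``(region, super_region)``;
    every label present in ``labels`` must appear in the table.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    region_table: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"atlas labels must be 3D; got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"atlas labels must be integer-typed; got {self.labels.dtype}")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError("atlas spacing must be strictly positive")
        self.spacing = spacing
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.region_table)
        if missing:
            raise ValueError(f"atlas labels missing from region table: {sorted(missing)}")

    def super_region_of(self, label: int) -> str:
        if label == 0:
            return "unassigned"
        return self.region_table[label][1]


def read_volume(path: str | os.PathLike, spacing: tuple[float, float, float]) -> Volume3D:
    """Read a grayscale multi-page TIFF as a ``Volume3D``.

    One page per z-slice; 8/16-bit integer or 32-bit float pages.  Integer
    intensities are converted to float64 without rescaling.

    Raises
    ------
    FileNotFoundError
        Missing file.
    ValueError
        Multi-channel/RGB pages or inconsistent page shapes.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
        (page_shape,) = shapes
        if len(page_shape) != 2:
            raise ValueError(
                f"pages of {path} are not single-channel grayscale (page shape {page_shape}); "
                "RGB/multi-channel volumes are not supported"
            )
        data = tif.asarray()
    if data.ndim == 2:  # single-page stack
        data = data[None, :, :]
    return Volume3D(data=np.asarray(data, dtype=np.float64), spacing=spacing, name=os.path.basename(path))


def write_volume(volume: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as a float32 multi-page TIFF, one page per z-slice.

    Voxel spacing is recorded in ImageJ-style metadata (x/y resolution in
    pixels-per-µm plus the z spacing).
    """
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    sz, sy, sx = volume.spacing
    tifffile.imwrite(
        path,
        np.asarray(volume.data, dtype=np.float32),
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


def write_mask(mask: np.ndarray, spacing: tuple[float, float, float], path: str | os.PathLike) -> None:
    """Write a boolean mask as a uint8 multi-page TIFF (1 = foreground)."""
    path = os.fspath(path)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8), imagej=True, metadata={"axes": "ZYX"})


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a uint8/boolean multi-page TIFF as a boolean (z, y, x) mask."""
    data = tifffile.imread(os.fspath(path))
    if data.ndim == 2:
        data = data[None, :, :]
    return data > 0


def read_labels(path: str | os.PathLike) -> np.ndarray:
    """Read an integer label TIFF as an int32 (z, y, x) grid."""
    data = tifffile.imread(os.fspath(path))
    if data.ndim == 2:
        data = data[None, :, :]
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"label volume {path} is not integer-typed ({data.dtype})")
    return data.astype(np.int32)


def read_region_table(path: str | os.PathLike) -> dict[int, tuple[str, str]]:
    """Read a TSV region table with columns ``label``, ``region``, ``super_region``.

    Returns a mapping ``label -> (region, super_region)``.  An empty file is a
    valid empty table.  Duplicate or non-integer labels are errors.
    """
    path = os.fspath(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return {}
    if df.empty and df.columns.size == 0:
        return {}
    required = {"label", "region", "super_region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table {path} missing columns: {sorted(missing)}")
    labels = df["label"]
    try:
        int_labels = labels.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"region table {path} has non-integer labels") from exc
    if not np.array_equal(int_labels.astype(float), labels.astype(float)):
        raise ValueError(f"region table {path} has non-integer labels")
    if int_labels.duplicated().any():
        dupes = sorted(int_labels[int_labels.duplicated()].unique().tolist())
        raise ValueError(f"region table {path} has duplicate labels: {dupes}")
    return {
        int(lbl): (str(region), str(super_region))
        for lbl, region, super_region in zip(int_labels, df["region"], df["super_region"])
    }


def write_region_table(table: dict[int, tuple[str, str]], path: str | os.PathLike) -> None:
    """Write a region table as TSV (label, region, super_region)."""
    rows = [
        {"label": lbl, "region": region, "super_region": super_region}
        for lbl, (region, super_region) in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["label", "region", "super_region"]).to_csv(
        os.fspath(path), sep="\t", index=False
    )
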