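"""Candidate-cell detection via the negative Laplacian (LoG) of the denoised volume.

I_LoG = -∇²I_d is positive inside compact bright structures, negative between
them and zero on the bounding edge, so thresholding at a small α > 0 carves
out closed candidate regions.  Candidates are connected components of
``I_LoG > α``; each carries its voxel set and intensity summaries on I_d.  A
minimum max-intensity filter (I_d,min, default 1.1) then removes dim artifacts
that the restoration stage left near the background level of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from clearcount3d.io import Volume3D

__all__ = [
    "DetectionParams",
    "CandidateObject",
    "log_response",
    "extract_candidates",
    "filter_by_intensity",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # voxel neighborhood -> skimage connectivity rank


@dataclass
class DetectionParams:
    """Detection thresholds and component rules.

    alpha
        LoG threshold, 0 < α ≪ 1; small enough to keep unit-contrast blobs,
        large enough to reject float-level ripple on flat background.
    i_d_min
        Minimum per-object maximum of I_d for a candidate to survive
        (background sits at 1; default 1.1).
    connectivity
        Voxel neighborhood for components: 6, 18 or 26 (default 26).
    min_voxels
        Smallest component kept; single voxels have a degenerate (all-zero)
        gyration tensor, so the default is 2.
    """

    alpha: float = 1e-3
    i_d_min: float = 1.1
    connectivity: int = 26
    min_voxels: int = 2

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0; got {self.alpha}")
        if self.i_d_min < 0:
            raise ValueError(f"i_d_min must be >= 0; got {self.i_d_min}")
        if self.connectivity not in _CONNECTIVITY:
            raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}; got {self.connectivity}")
        if self.min_voxels < 1:
            raise ValueError(f"min_voxels must be >= 1; got {self.min_voxels}")


@dataclass
class CandidateObject:
    """A connected set of voxels with intensity summaries on I_d."""

    id: int
    voxels: np.ndarray  # (N, 3) int array of (z, y, x) indices
    centroid: tuple[float, float, float]
    volume_vox: int
    volume_um3: float
    max_Id: float
    mean_Id: float
    label: str | None = field(default=None)  # filled by the classifier


def log_response(volume: Volume3D, spacing_mode: str = "voxel") -> Volume3D:
    """Negative Laplacian of I_d by 3D central finite differences.

    Interior voxels get -Σ_axis (f(+1) - 2 f(0) + f(-1)) / h², with h = 1
    voxel per axis by default (``spacing_mode="physical"`` uses the µm
    spacing instead).  Boundary voxels replicate the nearest interior value,
    avoiding spurious threshold crossings at the faces.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if any(n < 3 for n in data.shape):
        raise ValueError(f"each axis must have length >= 3 for central differences; got {data.shape}")
    if spacing_mode == "voxel":
        h = (1.0, 1.0, 1.0)
    elif spacing_mode == "physical":
        h = volume.spacing
    else:
        raise ValueError(f"spacing_mode must be 'voxel' or 'physical'; got {spacing_mode!r}")

    c = data[1:-1, 1:-1, 1:-1]
    lap = (
        (data[2:, 1:-1, 1:-1] - 2.0 * c + data[:-2, 1:-1, 1:-1]) / h[0] ** 2
        + (data[1:-1, 2:, 1:-1] - 2.0 * c + data[1:-1, :-2, 1:-1]) / h[1] ** 2
        + (data[1:-1, 1:-1, 2:] - 2.0 * c + data[1:-1, 1:-1, :-2]) / h[2] ** 2
    )
    out = np.pad(-lap, 1, mode="edge")
    return volume.with_data(out, name=f"{volume.name}|I_LoG")


def extract_candidates(
    log_volume: Volume3D,
    denoised: Volume3D,
    params: DetectionParams | None = None,
) -> list[CandidateObject]:
    """Connected components of ``I_LoG > α``, annotated from I_d.

    Components smaller than ``min_voxels`` are dropped.  Ids are assigned in
    lexicographic order of each component's minimum (z, y, x) voxel, so the
    output is deterministic regardless of labelling internals.
    """
    params = params or DetectionParams()
    if log_volume.shape != denoised.shape:
        raise ValueError(f"grid mismatch: I_LoG {log_volume.shape} vs I_d {denoised.shape}")
    mask = log_volume.data > params.alpha
    labeled = measure.label(mask, connectivity=_CONNECTIVITY[params.connectivity])
    n_labels = int(labeled.max())
    if n_labels == 0:
        return []

    voxel_volume = denoised.voxel_volume_um3
    id_data = np.asarray(denoised.data, dtype=np.float64)
    raw: list[tuple[tuple[int, int, int], CandidateObject]] = []
    for region in measure.regionprops(labeled):
        if region.num_pixels < params.min_voxels:
            continue
        coords = np.asarray(region.coords, dtype=np.intp)
        # lexicographic minimum voxel as the deterministic sort key
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
        coords = coords[order]
        intensities = id_data[coords[:, 0], coords[:, 1], coords[:, 2]]
        obj = CandidateObject(
            id=0,
            voxels=coords,
            centroid=tuple(float(c) for c in coords.mean(axis=0)),
            volume_vox=int(coords.shape[0]),
            volume_um3=float(coords.shape[0] * voxel_volume),
            max_Id=float(intensities.max()),
            mean_Id=float(intensities.mean()),
        )
        raw.append((tuple(int(v) for v in coords[0]), obj))

    raw.sort(key=lambda item: item[0])
    out = []
    for new_id, (_, obj) in enumerate(raw, start=1):
        obj.id = new_id
        out.append(obj)
    return out


def filter_by_intensity(
    candidates: list[CandidateObject],
    params: DetectionParams | None = None,
) -> tuple[list[CandidateObject], dict[str, int]]:
    """Keep candidates with ``max_Id >= i_d_min``; order preserved.

    Returns the kept list and a filter ledger ``{"n_in": ..., "n_kept": ...}``.
    """
    params = params or DetectionParams()
    kept = [obj for obj in candidates if obj.max_Id >= params.i_d_min]
    return kept, {"n_in": len(candidates), "n_kept": len(kept)}


def candidates_mask(candidates: list[CandidateObject], shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean mask of all candidate voxels on the given grid."""
    mask = np.zeros(shape, dtype=bool)
    for obj in candidates:
        mask[obj.voxels[:, 0], obj.voxels[:, 1], obj.voxels[:, 2]] = True
    return mask
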