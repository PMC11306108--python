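"""Image restoration: background estimation, division normalization, denoising.

Autofluorescence in cleared tissue varies on length scales much larger than a
cell, so the background is modelled as the raw volume convolved with a wide
Gaussian (scale ``sigma_bg``, truncated to a cube of side ``2w + 1`` and
renormalized so the discrete kernel sums to exactly 1).  Dividing the raw
data by this estimate yields the normalized volume I_n, in which background
voxels sit near 1 and bright structures well above 1 regardless of the
camera's gain or offset trends.  A second, narrow Gaussian convolution
suppresses per-voxel digitization noise, giving the denoised volume I_d used
by the detector.

The cubic kernel is separable — exp(-(i²+j²+k²)/2σ²) factorizes into three
1D Gaussians, and normalizing each 1D factor to unit sum is identical to
dividing the cube by its total — so both convolutions run as three 1D passes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from clearcount3d.io import Volume3D

__all__ = [
    "RestorationParams",
    "gaussian_kernel",
    "estimate_background",
    "normalize",
    "denoise",
]

# scipy.ndimage boundary-mode names for each supported padding rule.
# "reflect" mirrors without repeating the edge sample (scipy's "mirror");
# "symmetric" repeats it; "periodic" wraps; "nearest" replicates the edge.
_PADDING_MODES = {
    "reflect": "reflect",
    "mirror": "mirror",
    "periodic": "wrap",
    "nearest": "nearest",
}

# Fraction of the volume mean below which the background estimate is treated
# as empty space: dividing by it would be 0/0, so I_n is set to 1 there.
DIVISION_FLOOR_FRACTION = 1e-12


@dataclass
class RestorationParams:
    """Parameters of the restoration stage.

    sigma_bg
        Scale (voxels) of the background-estimation Gaussian; larger than a
        cell radius, smaller than an autofluorescent patch.  Default 10.
    w
        Kernel half-width in voxels (cube side ``2w + 1``).  ``None`` means
        ``ceil(3 * sigma_bg)``, capturing >99.7% of the Gaussian mass per axis.
    sigma_denoise
        Scale (voxels) of the denoising Gaussian applied to I_n; 0 disables.
        Default 1 voxel: wide enough to kill single-voxel noise, narrow
        enough not to blur 4–8 voxel cells.
    padding
        Boundary rule: "reflect" (default), "mirror", "periodic" or "nearest".
    """

    sigma_bg: float = 10.0
    w: int | None = None
    sigma_denoise: float = 1.0
    padding: str = "reflect"

    def __post_init__(self) -> None:
        if self.sigma_bg <= 0:
            raise ValueError(f"sigma_bg must be > 0; got {self.sigma_bg}")
        if self.w is not None and self.w < 1:
            raise ValueError(f"kernel half-width w must be >= 1; got {self.w}")
        if self.sigma_denoise < 0:
            raise ValueError(f"sigma_denoise must be >= 0; got {self.sigma_denoise}")
        if self.padding not in _PADDING_MODES:
            raise ValueError(f"padding must be one of {sorted(_PADDING_MODES)}; got {self.padding!r}")

    @property
    def effective_w(self) -> int:
        return self.w if self.w is not None else math.ceil(3.0 * self.sigma_bg)


def _kernel_1d(sigma: float, w: int) -> np.ndarray:
    """Unnormalized 1D Gaussian samples exp(-i²/2σ²) for i in [-w, w]."""
    i = np.arange(-w, w + 1, dtype=np.float64)
    return np.exp(-(i**2) / (2.0 * sigma**2))


def gaussian_kernel(sigma: float, w: int) -> np.ndarray:
    """The discrete 3D Gaussian kernel on a cube of side ``2w + 1``.

    Weights are proportional to exp(-(i²+j²+k²)/2σ²) for i, j, k in [-w, w],
    scaled so their sum over the cube is exactly 1.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0; got {sigma}")
    if w < 1:
        raise ValueError(f"w must be >= 1; got {w}")
    k1 = _kernel_1d(sigma, w)
    cube = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    return cube / cube.sum()


def _separable_convolve(data: np.ndarray, sigma: float, w: int, mode: str) -> np.ndarray:
    k1 = _kernel_1d(sigma, w)
    k1 = k1 / k1.sum()  # per-axis unit sum == cube normalization B
    out = np.asarray(data, dtype=np.float64)
    for axis in range(3):
        out = ndimage.convolve1d(out, k1, axis=axis, mode=mode)
    return out


def estimate_background(volume: Volume3D, params: RestorationParams | None = None) -> Volume3D:
    """Estimate the smooth background I_σ by wide Gaussian convolution."""
    params = params or RestorationParams()
    data = np.asarray(volume.data, dtype=np.float64)
    if not np.any(data):
        warnings.warn(
            "estimate_background: volume is all zero; downstream division would be 0/0",
            RuntimeWarning,
            stacklevel=2,
        )
    smoothed = _separable_convolve(data, params.sigma_bg, params.effective_w, _PADDING_MODES[params.padding])
    return volume.with_data(smoothed, name=f"{volume.name}|I_sigma")


def normalize(volume: Volume3D, background: Volume3D) -> Volume3D:
    """Division normalization: I_n = I / I_σ.

    Voxels where the background estimate falls below a tiny fraction of the
    volume mean are pure empty space and are set to 1 (background level).
    """
    if volume.shape != background.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape} vs background {background.shape}")
    bg = np.asarray(background.data, dtype=np.float64)
    floor = DIVISION_FLOOR_FRACTION * float(bg.mean())
    safe = bg > max(floor, 0.0)
    out = np.ones_like(bg)
    np.divide(np.asarray(volume.data, dtype=np.float64), bg, out=out, where=safe)
    return volume.with_data(out, name=f"{volume.name}|I_n")


def denoise(volume: Volume3D, params: RestorationParams | None = None) -> Volume3D:
    """Suppress digitization noise: narrow Gaussian convolution of I_n → I_d.

    ``sigma_denoise = 0`` returns the input data unchanged.
    """
    params = params or RestorationParams()
    if params.sigma_denoise == 0:
        return volume.with_data(np.asarray(volume.data, dtype=np.float64).copy(), name=f"{volume.name}|I_d")
    w = math.ceil(3.0 * params.sigma_denoise)
    out = _separable_convolve(volume.data, params.sigma_denoise, w, _PADDING_MODES[params.padding])
    return volume.with_data(out, name=f"{volume.name}|I_d")


def restore(volume: Volume3D, params: RestorationParams | None = None) -> tuple[Volume3D, Volume3D]:
    """Full restoration: returns ``(I_n, I_d)``."""
    params = params or RestorationParams()
    bg = estimate_background(volume, params)
    normalized = normalize(volume, bg)
    return normalized, denoise(normalized, params)
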