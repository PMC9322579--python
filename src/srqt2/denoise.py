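"""Spatially adaptive non-local-means denoising.

The filter replaces each voxel by a weighted average of the voxels in a
search window, with weights driven by patch similarity and scaled by a
*local* noise estimate, so regions with different noise levels (or
different signal levels under magnitude detection) are smoothed
proportionately.  The noise map comes from pseudo-residuals: the
difference between each voxel and the mean of its six face neighbors,
scaled by sqrt(6/7) so its SD equals the noise SD for i.i.d. Gaussian
noise, then robustly summarized by a local median filter.

The weights are Gaussian in the patch distance,

    w(x, y) = exp( -||P(x) - P(y)||^2 / (h * sigma(x)^2 * N_patch) ),

with the self-weight set to the maximum weight among neighbors.  Rician
bias is not corrected; the filter reduces variance only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.ndimage import median_filter, uniform_filter

from .volumes import ImageVolume

# |pseudo-residual| -> SD for Gaussian noise (1 / Phi^-1(0.75))
_MAD_SCALE = 1.482602218505602


@dataclass(frozen=True)
class DenoiseParams:
    """Non-local-means operating point.

    patch_radius 1 compares 3^3 patches; search_radius 3 scans a 7^3
    window; h_factor scales the squared local noise SD in the weight
    kernel (1.0 = nominal selectivity).
    """

    patch_radius: int = 1
    search_radius: int = 3
    h_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.patch_radius < 1 or self.search_radius < 1:
            raise ValueError("patch_radius and search_radius must be >= 1")
        if self.h_factor <= 0:
            raise ValueError("h_factor must be positive")


def estimate_noise_map(vol: ImageVolume) -> ImageVolume:
    """Voxelwise noise-SD estimate from six-neighbor pseudo-residuals.

    Exact-zero for constant and (interior of) linear-ramp images; for
    added Gaussian noise of SD sigma the map's spatial median converges
    to sigma.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if any(n < 5 for n in data.shape):
        raise ValueError(f"volume must be at least 5^3 voxels, got {data.shape}")
    neigh = np.zeros_like(data)
    for axis in range(3):
        neigh += np.roll(data, 1, axis=axis) + np.roll(data, -1, axis=axis)
    neigh /= 6.0
    resid = np.sqrt(6.0 / 7.0) * (data - neigh)
    # roll wraps at faces; copy the first interior residual outward instead
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_lo[axis] = 0
        src_lo = [slice(None)] * 3
        src_lo[axis] = 1
        resid[tuple(sl_lo)] = resid[tuple(src_lo)]
        sl_hi = [slice(None)] * 3
        sl_hi[axis] = -1
        src_hi = [slice(None)] * 3
        src_hi[axis] = -2
        resid[tuple(sl_hi)] = resid[tuple(src_hi)]
    sd = _MAD_SCALE * median_filter(np.abs(resid), size=5, mode="nearest")
    return vol.copy_with(sd)


def adaptive_nlm(vol: ImageVolume, params: DenoiseParams | None = None,
                 noise_map: ImageVolume | None = None) -> ImageVolume:
    """Adaptive non-local-means filter of one volume.

    ``noise_map`` defaults to :func:`estimate_noise_map`.  The output is a
    convex combination of input intensities, hence bounded by the input
    range and non-negative for magnitude images.
    """
    params = params or DenoiseParams()
    if noise_map is None:
        noise_map = estimate_noise_map(vol)
    if noise_map.data.shape != vol.data.shape:
        raise ValueError(
            f"noise map grid {noise_map.data.shape} does not match "
            f"volume grid {vol.data.shape}")

    data = np.asarray(vol.data, dtype=np.float32)
    sigma2 = np.square(np.asarray(noise_map.data, dtype=np.float32))
    scale = float(np.max(np.abs(data)))
    sigma2 = np.maximum(sigma2, np.float32((1e-6 * max(scale, 1.0)) ** 2))

    pr, sr = params.patch_radius, params.search_radius
    inv_h = np.float32(1.0) / (np.float32(params.h_factor) * sigma2)
    # N_patch cancels: the weight uses the patch *mean* squared difference

    pad = sr
    padded = np.pad(data, pad, mode="reflect")
    shape = data.shape

    num = np.zeros(shape, dtype=np.float32)
    den = np.zeros(shape, dtype=np.float32)
    wmax = np.zeros(shape, dtype=np.float32)

    def shifted(arr, d, p):
        return arr[p + d[0]: p + d[0] + shape[0],
                   p + d[1]: p + d[1] + shape[1],
                   p + d[2]: p + d[2] + shape[2]]

    # the patch distance is symmetric: D_d(x) = dist(x, x+d) also serves
    # voxel x+d against its neighbor at -d, halving the filtering work
    offsets = [d for d in product(range(-sr, sr + 1), repeat=3) if d > (0, 0, 0)]
    for d in offsets:
        neighbor = shifted(padded, d, pad)
        mean_d2 = uniform_filter((data - neighbor) ** 2, size=2 * pr + 1,
                                 mode="reflect")
        w = np.exp(-mean_d2 * inv_h)
        num += w * neighbor
        den += w
        np.maximum(wmax, w, out=wmax)

        md2_pad = np.pad(mean_d2, pad, mode="reflect")
        md2_back = shifted(md2_pad, tuple(-c for c in d), pad)
        back = shifted(padded, tuple(-c for c in d), pad)
        wb = np.exp(-md2_back * inv_h)
        num += wb * back
        den += wb
        np.maximum(wmax, wb, out=wmax)

    # self-weight = max neighbor weight; floor keeps voxels with no similar
    # neighbor (all w -> 0 in the noiseless limit) equal to their input
    w_self = np.maximum(wmax, np.float32(1e-12))
    out = (num + w_self * data) / (den + w_self)
    return vol.copy_with(np.maximum(out, 0.0).astype(np.float64))


def denoise_stack(volumes: list[ImageVolume],
                  params: DenoiseParams | None = None) -> list[ImageVolume]:
    """Denoise each multi-TE volume independently with its own noise map.

    Noise levels differ between echo images because the signal decays
    while the thermal noise floor does not, so per-image adaptation is
    essential.
    """
    return [adaptive_nlm(v, params=params) for v in volumes]
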