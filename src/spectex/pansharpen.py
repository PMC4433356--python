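"""Principal-component-substitution pansharpening.

Fuses a coarse multispectral (MS) stack with a fine panchromatic band into
a high-resolution multispectral (HMS) stack:

1. upsample the MS bands to the pan grid (bilinear by default);
2. rotate into principal components (covariance PCT over valid pixels);
3. replace the first component by the pan band, linearly stretched so its
   extrema match the PC1 extrema:

       H = pc1_min + (Pan - pan_min) * (pc1_max - pc1_min) / (pan_max - pan_min)

4. rotate back.

The stretch is affine and monotone, so the spatial ordering of pan values
is preserved in the substituted component; because the rotation is
orthonormal, substituting PC1 with itself reproduces the upsampled MS
exactly.  PC1 sign is fixed so the sum of its loadings is positive, making
the component orientation deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster_io import RasterStack

__all__ = ["FusionTransform", "upsample", "pct_fuse"]


@dataclass
class FusionTransform:
    """The fitted rotation and stretch of one fusion run."""

    loadings: np.ndarray  # B x B, columns = components
    band_means: np.ndarray
    pc1_min: float
    pc1_max: float
    pan_min: float
    pan_max: float


def upsample(ms: RasterStack, factor: int, method: str = "bilinear") -> RasterStack:
    """Upsample each band by an integer factor onto the fine grid."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("resolution ratio must be a positive integer")
    if method == "nearest":
        data = np.kron(ms.data, np.ones((factor, factor, 1)))
        mask = np.kron(ms.nodata_mask, np.ones((factor, factor), dtype=bool))
    elif method == "bilinear":
        bands = [
            ndimage.zoom(ms.data[:, :, b], factor, order=1, mode="nearest",
                         grid_mode=True)
            for b in range(ms.n_bands)
        ]
        data = np.stack(bands, axis=2)
        mask = np.kron(ms.nodata_mask, np.ones((factor, factor), dtype=bool))
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return RasterStack(data, ms.band_names, mask, ms.pixel_size / factor)


def _fit_pct(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the covariance of valid pixels (rows of x)."""
    means = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    # deterministic orientation: PC1 loadings sum positive
    for j in range(evecs.shape[1]):
        if evecs[:, j].sum() < 0:
            evecs[:, j] = -evecs[:, j]
    return means, evecs


def pct_fuse(
    ms: RasterStack,
    pan: RasterStack,
    method: str = "bilinear",
    return_transform: bool = False,
):
    """Fuse an MS stack with a single-band pan raster on the pan grid.

    The pan pixel size must divide the MS pixel size by an integer factor
    (e.g. 0.6 m pan against 2.4 m MS, factor 4).  Extrema for the stretch
    are computed over valid (non-nodata) pixels only.
    """
    if pan.n_bands != 1:
        raise ValueError("pan raster must have exactly one band")
    ratio = ms.pixel_size / pan.pixel_size
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-6:
        raise ValueError(
            f"pan pixel size must divide MS pixel size (ratio {ratio:.3f})"
        )
    up = upsample(ms, factor, method=method)
    if up.shape != pan.shape:
        raise ValueError(
            f"upsampled MS shape {up.shape} != pan shape {pan.shape}"
        )
    mask = up.nodata_mask | pan.nodata_mask
    valid = ~mask
    x = up.data[valid]
    means, loadings = _fit_pct(x)
    pcs = (up.data.reshape(-1, up.n_bands) - means) @ loadings
    pc1 = pcs[:, 0].reshape(up.shape)

    pan_vals = pan.data[:, :, 0]
    pan_min = float(pan_vals[valid].min())
    pan_max = float(pan_vals[valid].max())
    if pan_max == pan_min:
        raise ValueError("flat panchromatic band: no spatial detail to inject")
    pc1_min = float(pc1[valid].min())
    pc1_max = float(pc1[valid].max())

    h = pc1_min + (pan_vals - pan_min) * (pc1_max - pc1_min) / (pan_max - pan_min)
    pcs[:, 0] = h.ravel()
    fused = (pcs @ loadings.T + means).reshape(up.data.shape)
    out = RasterStack(fused, ms.band_names, mask, pan.pixel_size)
    if return_transform:
        tf = FusionTransform(loadings, means, pc1_min, pc1_max, pan_min, pan_max)
        return out, tf
    return out
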