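"""Lee-sigma spectral-spatial texture filtering.

The Lee-sigma filter is a standard-deviation-based focal filter: within a
moving window centered on value ``DN_c``, the local standard deviation
``sigma_local`` is estimated from the (unmasked) window values, and the
output is the mean of the window values falling inside the acceptance
range ``DN_c +/- k * sigma_local`` (the center always qualifies).  Unlike a
plain low-pass filter this suppresses noise while preserving edges: pixels
across a step edge fall outside the range and are excluded from the mean.

Windows are truncated at image borders (no invented padding values) and
masked pixels are excluded from every window and stay masked in the
output.  When no neighbor is in range the center value is kept unchanged,
preserving spikes rather than fabricating data.

Applying the filter to every band of an L-band image yields the L-band
spectral-spatial texture ("SpecTex") image used as a classification
dataset in its own right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import RasterStack

__all__ = ["LeeSigmaParams", "lee_sigma_band", "build_spectex"]


@dataclass(frozen=True)
class LeeSigmaParams:
    """window: odd side length; sigma_multiplier: k in DN_c +/- k*sigma."""

    window: int = 7
    sigma_multiplier: float = 2.0
    min_in_range: int = 1

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.sigma_multiplier <= 0:
            raise ValueError("sigma_multiplier must be positive")


def lee_sigma_band(
    band: np.ndarray,
    p: LeeSigmaParams = LeeSigmaParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Filter one 2-D band; ``mask`` marks pixels to exclude (nodata).

    sigma_local is the sample standard deviation (n-1 denominator) of the
    unmasked window values.  Vectorized with a sliding-window view over a
    NaN-padded copy, so border windows are naturally truncated.
    """
    band = np.asarray(band, dtype=float)
    if band.ndim != 2:
        raise ValueError("band must be 2-D")
    w, half = p.window, p.window // 2
    if w > band.shape[0] or w > band.shape[1]:
        raise ValueError(f"window {w} exceeds image shape {band.shape}")
    work = band.copy()
    if mask is not None:
        work[mask] = np.nan

    padded = np.pad(work, half, mode="constant", constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (w, w))
    win = win.reshape(band.shape[0], band.shape[1], w * w)

    count = np.sum(~np.isnan(win), axis=2)
    with np.errstate(invalid="ignore"):
        sigma = np.where(
            count > 1, np.nanstd(win, axis=2, ddof=1), 0.0
        )
        lo = work - p.sigma_multiplier * sigma
        hi = work + p.sigma_multiplier * sigma
        in_range = (win >= lo[:, :, None]) & (win <= hi[:, :, None])
        n_in = in_range.sum(axis=2)
        total = np.nansum(np.where(in_range, win, 0.0), axis=2)
        mean_in = np.where(n_in > 0, total / np.maximum(n_in, 1), work)
    out = np.where(n_in >= p.min_in_range, mean_in, work)
    if mask is not None:
        out[mask] = band[mask]
    return out


def build_spectex(
    stack: RasterStack, p: LeeSigmaParams = LeeSigmaParams()
) -> RasterStack:
    """Lee-sigma filter every band; band names gain a ``_tex`` suffix."""
    data = np.stack(
        [
            lee_sigma_band(stack.data[:, :, b], p, mask=stack.nodata_mask)
            for b in range(stack.n_bands)
        ],
        axis=2,
    )
    names = [f"{n}_tex" for n in stack.band_names]
    return stack.with_data(data, names)
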