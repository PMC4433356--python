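"""Vegetation-index layers computed from a 4-band reflectance stack.

Five indices expand the spectral information of a blue/green/red/NIR
reflectance image:

    NDVI = (rho_nir - rho_red) / (rho_nir + rho_red)
    SAVI = (rho_nir - rho_red) / (rho_nir + rho_red + L) * (1 + L)
    ARVI = (rho_nir - rho_rb) / (rho_nir + rho_rb),
           rho_rb = rho_red - gamma * (rho_blue - rho_red)
    VARI = (rho_green - rho_red) / (rho_green + rho_red - rho_blue)
    EVI  = G * (rho_nir - rho_red) / (rho_nir + C1*rho_red - C2*rho_blue + L)

Defaults: SAVI soil-adjustment L = 0.5 (moderate green cover), ARVI
gamma = 1 (aerosol model unknown a priori), EVI G = 2.5, C1 = 6, C2 = 7.5,
L = 1.  Denominators within ``eps`` of zero produce nodata pixels rather
than infinities.  :func:`build_hms5vi` assembles the fixed-order 5-band
index stack [NDVI, SAVI, EVI, ARVI, VARI] with the union of the per-index
masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import RasterStack

__all__ = ["VIParams", "ndvi", "savi", "arvi", "vari", "evi", "build_hms5vi",
           "HMS5VI_ORDER"]

HMS5VI_ORDER = ("ndvi", "savi", "evi", "arvi", "vari")


@dataclass(frozen=True)
class VIParams:
    savi_L: float = 0.5
    arvi_gamma: float = 1.0
    evi_G: float = 2.5
    evi_C1: float = 6.0
    evi_C2: float = 7.5
    evi_L: float = 1.0
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.savi_L < 0 or self.evi_G <= 0 or self.eps <= 0:
            raise ValueError("invalid vegetation-index parameters")


def _require(stack: RasterStack, names: tuple[str, ...]) -> None:
    for n in names:
        if n not in stack.band_names:
            raise KeyError(f"band {n!r} required but not in stack")


def _ratio(
    stack: RasterStack, num: np.ndarray, den: np.ndarray, eps: float, name: str
) -> RasterStack:
    bad = np.abs(den) < eps
    out = np.where(bad, 0.0, num) / np.where(bad, 1.0, den)
    return stack.with_data(out[:, :, None], [name], extra_mask=bad)


def ndvi(stack: RasterStack, p: VIParams = VIParams()) -> RasterStack:
    """Normalized difference vegetation index; in [-1, 1] where defined."""
    _require(stack, ("red", "nir"))
    r, n = stack.band("red"), stack.band("nir")
    return _ratio(stack, n - r, n + r, p.eps, "ndvi")


def savi(stack: RasterStack, p: VIParams = VIParams()) -> RasterStack:
    """Soil-adjusted vegetation index (reduces soil-brightness bias)."""
    _require(stack, ("red", "nir"))
    r, n = stack.band("red"), stack.band("nir")
    return _ratio(stack, (n - r) * (1 + p.savi_L), n + r + p.savi_L, p.eps, "savi")


def arvi(stack: RasterStack, p: VIParams = VIParams()) -> RasterStack:
    """Atmospherically resistant VI; blue band corrects the red band."""
    _require(stack, ("blue", "red", "nir"))
    b, r, n = stack.band("blue"), stack.band("red"), stack.band("nir")
    rb = r - p.arvi_gamma * (b - r)
    return _ratio(stack, n - rb, n + rb, p.eps, "arvi")


def vari(stack: RasterStack, p: VIParams = VIParams()) -> RasterStack:
    """Visible atmospherically resistant index (green/red/blue only)."""
    _require(stack, ("blue", "green", "red"))
    b, g, r = stack.band("blue"), stack.band("green"), stack.band("red")
    return _ratio(stack, g - r, g + r - b, p.eps, "vari")


def evi(stack: RasterStack, p: VIParams = VIParams()) -> RasterStack:
    """Enhanced vegetation index (gain G, aerosol terms C1/C2, background L)."""
    _require(stack, ("blue", "red", "nir"))
    b, r, n = stack.band("blue"), stack.band("red"), stack.band("nir")
    den = n + p.evi_C1 * r - p.evi_C2 * b + p.evi_L
    return _ratio(stack, p.evi_G * (n - r), den, p.eps, "evi")


def build_hms5vi(stack: RasterStack, p: VIParams = VIParams()) -> RasterStack:
    """Assemble the 5-band index stack [NDVI, SAVI, EVI, ARVI, VARI]."""
    funcs = {"ndvi": ndvi, "savi": savi, "evi": evi, "arvi": arvi, "vari": vari}
    layers = [funcs[name](stack, p) for name in HMS5VI_ORDER]
    return layers[0].concat(*layers[1:])
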