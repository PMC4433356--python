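"""Radiometric calibration: DN -> at-sensor radiance -> surface reflectance.

The sensor records raw digital numbers (DN).  Absolute calibration converts
band *i* to at-sensor spectral radiance

    L_i = a_i * k_i * DN_i / delta_lambda_i        [W m-2 um-1 sr-1]

where ``a_i`` is the calibration gain, ``k_i`` a revised (TDI-dependent)
factor and ``delta_lambda_i`` the nominal bandpass width in micrometers.
The shipped defaults are the published absolute-calibration coefficients
for 16-bit QuickBird imagery at 10 TDI levels.

Surface reflectance then comes from a dark-object-subtraction atmospheric
correction: the darkest scene DN per band estimates additive path radiance,
and

    rho = pi * (L - L_path) * d^2 / (ESUN * cos(theta_z))

with ``d`` the Earth-Sun distance in AU, ``theta_z`` the solar zenith angle
and ``ESUN`` the band's exoatmospheric solar irradiance.  Output is clipped
to [0, 1]; negative post-subtraction values are clipped to 0 rather than
masked so that dark crown pixels stay usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .raster_io import RasterStack

__all__ = [
    "BandCalibration",
    "CalibrationTable",
    "ReflectanceParams",
    "QUICKBIRD_CALIBRATION",
    "QUICKBIRD_ESUN",
    "dn_to_radiance",
    "radiance_to_reflectance",
]


@dataclass(frozen=True)
class BandCalibration:
    """Absolute-calibration row for one band.

    k : revised factor, W m-2 sr-1 count-1 (TDI-level dependent)
    a : calibration gain, W m-2 sr-1 count-1
    delta_lambda : nominal bandpass width, micrometers
    """

    k: float
    a: float
    delta_lambda: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.a <= 0 or self.delta_lambda <= 0:
            raise ValueError("calibration coefficients must be positive")


CalibrationTable = Mapping[str, BandCalibration]

# 16-bit QuickBird absolute-calibration coefficients (10 TDI levels);
# bandpass widths converted from nm to um so radiance is W m-2 um-1 sr-1.
QUICKBIRD_CALIBRATION: CalibrationTable = {
    "pan": BandCalibration(k=0.0838188, a=0.06269, delta_lambda=0.455),
    "blue": BandCalibration(k=0.0160412, a=0.01431, delta_lambda=0.070),
    "green": BandCalibration(k=0.0143847, a=0.01045, delta_lambda=0.080),
    "red": BandCalibration(k=0.0126735, a=0.00968, delta_lambda=0.060),
    "nir": BandCalibration(k=0.0154242, a=0.01568, delta_lambda=0.140),
}

# Band-averaged exoatmospheric solar irradiance, W m-2 um-1 (QuickBird).
QUICKBIRD_ESUN: Mapping[str, float] = {
    "pan": 1381.79,
    "blue": 1924.59,
    "green": 1843.08,
    "red": 1574.77,
    "nir": 1113.71,
}


@dataclass
class ReflectanceParams:
    """Geometry and irradiance inputs for the reflectance conversion."""

    esun: Mapping[str, float] = field(default_factory=lambda: dict(QUICKBIRD_ESUN))
    sun_elevation: float = 60.0
    earth_sun_distance: float = 1.0
    dark_object_dn: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.sun_elevation <= 90.0:
            raise ValueError("sun_elevation must be in (0, 90] degrees")
        if not 0.983 <= self.earth_sun_distance <= 1.017:
            raise ValueError("earth_sun_distance must be a plausible AU value")


def dn_to_radiance(dn_stack: RasterStack, cal: CalibrationTable) -> RasterStack:
    """Convert digital numbers to at-sensor radiance, band by band.

    Radiance is linear in DN with slope ``a*k/delta_lambda``; the nodata
    mask is preserved unchanged.
    """
    out = np.empty_like(dn_stack.data)
    for b, name in enumerate(dn_stack.band_names):
        if name not in cal:
            raise KeyError(f"no calibration row for band {name!r}")
        dn = dn_stack.data[:, :, b]
        if np.any(dn[~dn_stack.nodata_mask] < 0):
            raise ValueError(f"negative DN in band {name!r}")
        c = cal[name]
        out[:, :, b] = c.a * c.k * dn / c.delta_lambda
    return dn_stack.with_data(out)


def _path_radiance(name: str, cal: CalibrationTable, dark_dn: float) -> float:
    c = cal[name]
    return c.a * c.k * dark_dn / c.delta_lambda


def radiance_to_reflectance(
    rad_stack: RasterStack,
    params: ReflectanceParams,
    cal: CalibrationTable | None = None,
) -> RasterStack:
    """Dark-object-subtraction conversion of radiance to surface reflectance.

    The per-band path radiance is the calibrated radiance of
    ``params.dark_object_dn`` (0 when unspecified, i.e. no correction).
    Output is clipped to [0, 1].
    """
    cal = cal if cal is not None else QUICKBIRD_CALIBRATION
    zenith = np.deg2rad(90.0 - params.sun_elevation)
    denom_geom = np.cos(zenith)
    d2 = params.earth_sun_distance**2
    out = np.empty_like(rad_stack.data)
    for b, name in enumerate(rad_stack.band_names):
        if name not in params.esun:
            raise KeyError(f"no ESUN value for band {name!r}")
        l_path = _path_radiance(name, cal, params.dark_object_dn.get(name, 0.0))
        rho = (
            np.pi
            * (rad_stack.data[:, :, b] - l_path)
            * d2
            / (params.esun[name] * denom_geom)
        )
        out[:, :, b] = np.clip(rho, 0.0, 1.0)
    return rad_stack.with_data(out)
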