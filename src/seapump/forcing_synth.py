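"""Synthetic seasonal surface shortwave forcing.

Clear-sky daily-integrated insolation on the idealized 360-day calendar.
Day 0 is 1 January and the solar declination is ``-obliquity *
cos(2 pi day / 360)``, which puts the Southern-Hemisphere radiation maximum
exactly at the day 0/360 boundary (the December solstice of this calendar).
Only the phase and shape matter downstream - the forcing exists to time the
phytoplankton bloom against the seasonal attenuation cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = ["ForcingParams", "surface_radiation", "light_at_depth", "forcing_to_dataset"]


@dataclass(frozen=True)
class ForcingParams:
    solar_constant: float = 1361.0  # W m^-2
    obliquity: float = 23.44        # degrees
    attenuation_water: float = 0.04  # m^-1
    parfrac: float = 0.4            # photosynthetically usable fraction

    def __post_init__(self) -> None:
        if self.solar_constant <= 0 or self.obliquity <= 0:
            raise ValueError("solar_constant and obliquity must be positive")
        if self.attenuation_water < 0:
            raise ValueError("attenuation_water must be >= 0")
        if not 0 < self.parfrac <= 1:
            raise ValueError("parfrac must be in (0, 1]")


def surface_radiation(day, lat, params: ForcingParams = ForcingParams()):
    """Daily-mean shortwave radiation at the surface (W m^-2).

    Standard daily-integrated astronomical insolation with a fixed
    sun-Earth distance: ``Q = (S0/pi) (h0 sin(phi) sin(delta) +
    cos(phi) cos(delta) sin(h0))`` with sunrise hour angle ``h0``.
    """
    day = np.asarray(day, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude must be within [-90, 90]")
    decl = -np.deg2rad(params.obliquity) * np.cos(2.0 * np.pi * day / 360.0)
    phi = np.deg2rad(lat)
    cos_h0 = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    h0 = np.arccos(cos_h0)
    q = (params.solar_constant / np.pi) * (
        h0 * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(h0)
    )
    out = np.maximum(q, 0.0)
    return out if out.ndim else float(out)


def light_at_depth(I0, z, params: ForcingParams = ForcingParams()):
    """Photosynthetically available light at depth ``z`` (W m^-2)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be >= 0")
    out = np.asarray(I0, dtype=float) * params.parfrac * np.exp(-params.attenuation_water * z)
    return out if out.ndim else float(out)


def forcing_to_dataset(lats, params: ForcingParams = ForcingParams(),
                       days=None) -> xr.Dataset:
    """Radiation table on (day, lat) for inspection / fixture output."""
    if days is None:
        days = np.arange(360.0)
    days = np.asarray(days, dtype=float)
    lats = np.asarray(lats, dtype=float)
    rad = surface_radiation(days[:, None], lats[None, :], params)
    return xr.Dataset(
        {"swrad": (("day", "lat"), rad, {"units": "W m-2"})},
        coords={"day": days, "lat": ("lat", lats, {"units": "degrees_north"})},
    )
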