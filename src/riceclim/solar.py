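"""Solar radiation from sunshine duration (Angstrom-Prescott, FAO-56 forms).

Extraterrestrial radiation Ra and daylength N follow the FAO-56 daily
formulation (inverse relative Earth-Sun distance, solar declination, sunset
hour angle).  Surface solar radiation is then SR = (a + b * n/N) * Ra, with
the FAO-recommended default coefficients a=0.25, b=0.50 when no local
calibration is available.  Ra is computed in MJ m-2 day-1 and converted to
the package's storage unit, cal cm-2 day-1.
"""

from __future__ import annotations

import warnings

import numpy as np

#: 1 MJ m-2 = 23.884 cal cm-2 (single conversion point for the package).
CAL_PER_MJ = 23.884

#: Solar constant, MJ m-2 min-1.
_GSC = 0.0820

#: Polar day/night is not handled; latitudes beyond this are rejected.
MAX_ABS_LATITUDE = 66.5


def _check_inputs(latitude_deg, day_of_year):
    lat = np.asarray(latitude_deg, dtype=float)
    doy = np.asarray(day_of_year, dtype=int)
    if np.any(np.abs(lat) > MAX_ABS_LATITUDE):
        raise ValueError(
            f"|latitude| > {MAX_ABS_LATITUDE} deg unsupported (polar day/night)")
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day_of_year must be in [1, 366]")
    return lat, doy


def _sunset_hour_angle(lat_rad, decl):
    x = -np.tan(lat_rad) * np.tan(decl)
    return np.arccos(np.clip(x, -1.0, 1.0))


def extraterrestrial_radiation_mj(latitude_deg, day_of_year):
    """Daily extraterrestrial radiation Ra in MJ m-2 day-1."""
    lat, doy = _check_inputs(latitude_deg, day_of_year)
    phi = np.deg2rad(lat)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = _sunset_hour_angle(phi, decl)
    ra = (24.0 * 60.0 / np.pi) * _GSC * dr * (
        ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws)
    )
    return ra


def extraterrestrial_radiation(latitude_deg, day_of_year):
    """Daily extraterrestrial radiation Ra in cal cm-2 day-1."""
    return extraterrestrial_radiation_mj(latitude_deg, day_of_year) * CAL_PER_MJ


def daylength_hours(latitude_deg, day_of_year):
    """Maximum possible sunshine duration N in hours."""
    lat, doy = _check_inputs(latitude_deg, day_of_year)
    phi = np.deg2rad(lat)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    return 24.0 / np.pi * _sunset_hour_angle(phi, decl)


def solar_from_sunshine(sunshine_hours, latitude_deg, day_of_year,
                        a: float = 0.25, b: float = 0.50):
    """Surface solar radiation (cal cm-2 day-1) from daily sunshine hours.

    SR = (a + b * n/N) * Ra.  Sunshine durations exceeding the astronomical
    daylength are clipped to N with a warning (typically instrument error).
    """
    n = np.asarray(sunshine_hours, dtype=float)
    if np.any(n < 0):
        raise ValueError("sunshine_hours must be non-negative")
    N = daylength_hours(latitude_deg, day_of_year)
    if np.any(n > N + 1e-9):
        warnings.warn("sunshine duration exceeds daylength; clipping to N",
                      stacklevel=2)
        n = np.minimum(n, N)
    ra = extraterrestrial_radiation(latitude_deg, day_of_year)
    return (a + b * n / N) * ra
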