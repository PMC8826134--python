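"""Solar geometry for the daylight filter.

Implements the NOAA "general solar position calculations": fractional year,
equation of time and solar declination from truncated Fourier series, then
geometric solar elevation from the local hour angle. Accuracy is a few
minutes of time, ample for a sunrise-to-sunset filter; atmospheric
refraction is ignored (geometric horizon).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["solar_elevation", "is_daylight"]


def _fractional_year(times: pd.DatetimeIndex) -> np.ndarray:
    """Fractional year gamma in radians, including the time of day."""
    doy = times.dayofyear.to_numpy()
    hour = times.hour.to_numpy() + times.minute.to_numpy() / 60.0 + times.second.to_numpy() / 3600.0
    return 2.0 * np.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)


def solar_elevation(times, lat_deg, lon_deg) -> np.ndarray:
    """Geometric solar elevation angle in degrees.

    Parameters
    ----------
    times
        Timestamps in UTC (anything ``pd.DatetimeIndex`` accepts).
    lat_deg, lon_deg
        Geographic latitude / longitude in degrees (east positive); scalars
        or arrays broadcastable against ``times``.
    """
    times = pd.DatetimeIndex(times)
    if times.tz is not None:
        times = times.tz_convert("UTC").tz_localize(None)
    g = _fractional_year(times)

    # equation of time (minutes) and declination (radians), NOAA series
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )

    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    lon = np.asarray(lon_deg, dtype=float)
    minutes_utc = (
        times.hour.to_numpy() * 60.0 + times.minute.to_numpy() + times.second.to_numpy() / 60.0
    )
    # true solar time in minutes; 4 minutes per degree of longitude
    tst = minutes_utc + eqtime + 4.0 * lon
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle

    sin_el = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    return np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def is_daylight(times, lat_deg, lon_deg) -> np.ndarray:
    """True where the sun is at or above the geometric horizon."""
    return solar_elevation(times, lat_deg, lon_deg) >= 0.0
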