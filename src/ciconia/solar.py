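"""Sunrise, sunset and daylength from standard NOAA solar geometry.

Daylength for a migration day is the time between sunrise at the day's
first location and sunset at the day's last location, with the sun centre
at -0.833 degrees altitude (refraction plus solar radius). All times UTC.
"""

from __future__ import annotations

import datetime as dt
import math

ZENITH_DEG = 90.833  # official sunrise/sunset zenith


class PolarLightError(ValueError):
    """Raised when the sun does not rise or set on the given date/latitude."""


def _solar_params(date: dt.date):
    doy = date.timetuple().tm_yday
    # fractional year at solar noon, radians
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + 0.5)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    return eqtime, decl


def _hour_angle_deg(lat_deg: float, decl: float) -> float:
    lat = math.radians(lat_deg)
    cos_ha = (
        math.cos(math.radians(ZENITH_DEG)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    if cos_ha < -1.0 or cos_ha > 1.0:
        raise PolarLightError(
            f"no sunrise/sunset at latitude {lat_deg:.2f} (cos ha = {cos_ha:.3f})"
        )
    return math.degrees(math.acos(cos_ha))


def sunrise_utc(date: dt.date, lat: float, lon: float) -> float:
    """Sunrise time in UTC hours (may be negative / >24 far from Greenwich)."""
    eqtime, decl = _solar_params(date)
    ha = _hour_angle_deg(lat, decl)
    return (720.0 - 4.0 * (lon + ha) - eqtime) / 60.0


def sunset_utc(date: dt.date, lat: float, lon: float) -> float:
    """Sunset time in UTC hours."""
    eqtime, decl = _solar_params(date)
    ha = _hour_angle_deg(lat, decl)
    return (720.0 - 4.0 * (lon - ha) - eqtime) / 60.0


def daylength_hours(date: dt.date, lat1: float, lon1: float,
                    lat2: float | None = None, lon2: float | None = None) -> float:
    """Hours between sunrise at (lat1, lon1) and sunset at (lat2, lon2).

    With a single location this is the ordinary daylength. For a migration
    day pass the first location of the day for sunrise and the last for
    sunset. Raises :class:`PolarLightError` under polar day/night.
    """
    if lat2 is None:
        lat2, lon2 = lat1, lon1
    return sunset_utc(date, lat2, lon2) - sunrise_utc(date, lat1, lon1)
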