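"""Great-circle geometry and solar day/night classification.

Distances use the haversine formula on a sphere of radius 6371.0088 km
(the IUGG mean Earth radius). Sunrise and sunset come from the NOAA
solar-position algorithm with the conventional zenith of 90.833 degrees
(atmospheric refraction plus the solar half-diameter), which is the same
convention used by the common ecology sunrise/sunset utilities.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta, timezone

import numpy as np

from .types import Fix, SolarMarker, SunEvents

EARTH_RADIUS_KM = 6371.0088
#: solar zenith angle (degrees) defining sunrise/sunset
SUNRISE_SUNSET_ZENITH_DEG = 90.833


def gc_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points ``a``, ``b``.

    Haversine on the mean sphere; symmetric and non-negative.
    """
    lat1, lon1 = math.radians(a[0]), math.radians(a[1])
    lat2, lon2 = math.radians(b[0]), math.radians(b[1])
    for lat in (a[0], b[0]):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def gc_bearing(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Initial great-circle bearing from ``a`` to ``b``, degrees in [0, 360).

    0 = north, 90 = east (clockwise). Raises for coincident points, whose
    bearing is undefined.
    """
    if a[0] == b[0] and ((a[1] - b[1]) % 360.0) == 0.0:
        raise ValueError("bearing undefined for coincident points")
    lat1, lat2 = math.radians(a[0]), math.radians(b[0])
    dlon = math.radians(b[1] - a[1])
    x = math.sin(dlon) * math.cos(lat2)
    y = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    return math.degrees(math.atan2(x, y)) % 360.0


def _solar_terms(day_of_year: int, hours_utc: float, leap: bool):
    """NOAA fractional-year terms: equation of time (min) and declination (rad)."""
    year_len = 366.0 if leap else 365.0
    gamma = 2.0 * math.pi / year_len * (day_of_year - 1 + (hours_utc - 12.0) / 24.0)
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


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def sun_events(lat: float, lon: float, day: date) -> SunEvents:
    """Sunrise and sunset (UTC) at (lat, lon) on civil date ``day``.

    Returns POLAR_DAY / POLAR_NIGHT markers when the sun never sets or
    never rises. The hour-angle equation is evaluated twice, refining the
    equation of time and declination at the event time, which keeps events
    within about a minute of the reference NOAA spreadsheet.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    doy = day.timetuple().tm_yday
    leap = _is_leap(day.year)
    phi = math.radians(lat)

    def event_minutes(rising: bool) -> float | SolarMarker:
        # start from solar noon, then refine at the event's own UTC time
        t_guess = 12.0 - lon / 15.0
        minutes = None
        for _ in range(2):
            eqtime, decl = _solar_terms(doy, t_guess, leap)
            cos_ha = (
                math.cos(math.radians(SUNRISE_SUNSET_ZENITH_DEG))
                / (math.cos(phi) * math.cos(decl))
                - math.tan(phi) * math.tan(decl)
            )
            if cos_ha > 1.0:
                return SolarMarker.POLAR_NIGHT
            if cos_ha < -1.0:
                return SolarMarker.POLAR_DAY
            ha_deg = math.degrees(math.acos(cos_ha))
            if not rising:
                ha_deg = -ha_deg
            minutes = 720.0 - 4.0 * (lon + ha_deg) - eqtime
            t_guess = minutes / 60.0
        return minutes

    rise = event_minutes(rising=True)
    sett = event_minutes(rising=False)
    if isinstance(rise, SolarMarker) or isinstance(sett, SolarMarker):
        marker = rise if isinstance(rise, SolarMarker) else sett
        return SunEvents(date=day, sunrise=None, sunset=None, marker=marker)
    midnight = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    return SunEvents(
        date=day,
        sunrise=midnight + timedelta(minutes=rise),
        sunset=midnight + timedelta(minutes=sett),
    )


def is_diurnal(fix: Fix) -> bool:
    """True iff the fix falls between sunrise (inclusive) and sunset
    (exclusive) at its own coordinates and UTC date.

    Polar day -> True, polar night -> False.
    """
    ev = sun_events(fix.lat, fix.lon, fix.timestamp.date())
    if ev.marker is SolarMarker.POLAR_DAY:
        return True
    if ev.marker is SolarMarker.POLAR_NIGHT:
        return False
    return ev.sunrise <= fix.timestamp < ev.sunset


def day_length_hours(ev: SunEvents) -> float:
    """Day length in hours; 24 for polar day, 0 for polar night."""
    if ev.marker is SolarMarker.POLAR_DAY:
        return 24.0
    if ev.marker is SolarMarker.POLAR_NIGHT:
        return 0.0
    return (ev.sunset - ev.sunrise).total_seconds() / 3600.0
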