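"""Great-circle geometry and solar-event computations.

Solar oracles here are written independently of the package: sunrise
from the NOAA spreadsheet formulation via Julian centuries, and day
length from the closed-form hour-angle equation with a Fourier-series
declination.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest

from migtrack import Fix, gc_bearing, gc_distance, is_diurnal, sun_events
from migtrack.geosolar import EARTH_RADIUS_KM, day_length_hours
from migtrack.types import SolarMarker

# ---------------------------------------------------------------- geometry


def _law_of_cosines_km(a, b):
    """Independent high-precision spherical law of cosines (longdouble)."""
    lat1, lon1, lat2, lon2 = (np.longdouble(np.radians(x)) for x in (*a, *b))
    c = np.sin(lat1) * np.sin(lat2) + np.cos(lat1) * np.cos(lat2) * np.cos(lon2 - lon1)
    return float(np.arccos(np.clip(c, -1, 1)) * np.longdouble(EARTH_RADIUS_KM))


def test_distance_identity_and_antipodes():
    assert gc_distance((12.3, 45.6), (12.3, 45.6)) == 0.0
    assert gc_distance((90, 0), (-90, 0)) == pytest.approx(
        math.pi * EARTH_RADIUS_KM, rel=1e-12
    )


def test_distance_matches_law_of_cosines_oracle():
    d = gc_distance((0, 0), (0, 1))
    assert d == pytest.approx(_law_of_cosines_km((0, 0), (0, 1)), rel=1e-4)
    rng = np.random.default_rng(3)
    for _ in range(50):
        a = (rng.uniform(-80, 80), rng.uniform(-180, 180))
        b = (rng.uniform(-80, 80), rng.uniform(-180, 180))
        if gc_distance(a, b) > 1.0:  # law of cosines is ill-conditioned near 0
            assert gc_distance(a, b) == pytest.approx(
                _law_of_cosines_km(a, b), rel=1e-4
            )


def test_distance_triangle_inequality():
    rng = np.random.default_rng(11)
    for _ in range(300):
        p = [(rng.uniform(-90, 90), rng.uniform(-180, 180)) for _ in range(3)]
        ab, bc, ac = (
            gc_distance(p[0], p[1]),
            gc_distance(p[1], p[2]),
            gc_distance(p[0], p[2]),
        )
        assert ac <= ab + bc + 1e-9


@pytest.mark.parametrize(
    "a,b,expected",
    [((0, 0), (1, 0), 0.0), ((0, 0), (0, 1), 90.0), ((10, 10), (9, 10), 180.0)],
)
def test_bearing_cardinal_directions(a, b, expected):
    assert gc_bearing(a, b) == pytest.approx(expected, abs=1e-9)


def test_bearing_undefined_for_coincident_points():
    with pytest.raises(ValueError):
        gc_bearing((10.0, 20.0), (10.0, 20.0))


# ------------------------------------------------------------------- solar


def _noaa_spreadsheet_sunrise(lat, lon, day):
    """NOAA solar-calculator sunrise via Julian centuries (independent path)."""
    # Julian day at 0h UT
    a = (14 - day.month) // 12
    y = day.year + 4800 - a
    m = day.month + 12 * a - 3
    jdn = (
        day.day
        + (153 * m + 2) // 5
        + 365 * y
        + y // 4
        - y // 100
        + y // 400
        - 32045
    )
    jd = jdn - 0.5
    minutes = 720.0
    for _ in range(3):  # iterate to the event time
        t = (jd + minutes / 1440.0 - 2451545.0) / 36525.0
        l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360
        man = 357.52911 + t * (35999.05029 - 0.0001537 * t)
        ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
        mrad = math.radians(man)
        ceq = (
            math.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
            + math.sin(2 * mrad) * (0.019993 - 0.000101 * t)
            + math.sin(3 * mrad) * 0.000289
        )
        truelong = l0 + ceq
        omega = 125.04 - 1934.136 * t
        app = truelong - 0.00569 - 0.00478 * math.sin(math.radians(omega))
        e0 = 23 + (26 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60) / 60
        ec = e0 + 0.00256 * math.cos(math.radians(omega))
        decl = math.degrees(
            math.asin(math.sin(math.radians(ec)) * math.sin(math.radians(app)))
        )
        vary = math.tan(math.radians(ec / 2)) ** 2
        eqtime = 4 * math.degrees(
            vary * math.sin(2 * math.radians(l0))
            - 2 * ecc * math.sin(mrad)
            + 4 * ecc * vary * math.sin(mrad) * math.cos(2 * math.radians(l0))
            - 0.5 * vary * vary * math.sin(4 * math.radians(l0))
            - 1.25 * ecc * ecc * math.sin(2 * mrad)
        )
        cos_ha = math.cos(math.radians(90.833)) / (
            math.cos(math.radians(lat)) * math.cos(math.radians(decl))
        ) - math.tan(math.radians(lat)) * math.tan(math.radians(decl))
        ha = math.degrees(math.acos(cos_ha))
        minutes = 720.0 - 4.0 * (lon + ha) - eqtime
    return datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(
        minutes=minutes
    )


@pytest.mark.parametrize(
    "lat,lon,day",
    [
        (0.0, 0.0, date(2019, 3, 20)),
        (37.0, -6.0, date(2019, 9, 15)),
        (45.0, 10.0, date(2018, 12, 1)),
    ],
)
def test_sunrise_matches_noaa_spreadsheet_oracle(lat, lon, day):
    ev = sun_events(lat, lon, day)
    oracle = _noaa_spreadsheet_sunrise(lat, lon, day)
    assert abs((ev.sunrise - oracle).total_seconds()) < 600  # within 10 min


def test_polar_markers():
    assert sun_events(80, 0, date(2019, 12, 21)).marker is SolarMarker.POLAR_NIGHT
    assert sun_events(80, 0, date(2019, 6, 21)).marker is SolarMarker.POLAR_DAY


def _declination_deg(day_of_year: int) -> float:
    """Independent Fourier declination (accurate to ~0.2 deg)."""
    g = math.radians(0.98565 * (day_of_year - 2))
    lam = math.radians(0.98565 * (day_of_year + 10)) + math.radians(1.914) * math.sin(g)
    return -math.degrees(math.asin(0.39779 * math.cos(lam)))


def test_day_length_matches_closed_form():
    """The hour-angle day-length equation predicts day length within 15 min.

    cos(omega) = (cos z - sin(phi) sin(delta)) / (cos(phi) cos(delta)),
    which reduces to cos(omega) = -tan(phi) tan(delta) at z = 90; the same
    zenith convention as the implementation is used so the comparison
    checks the solar geometry, not the refraction constant.
    """
    rng = np.random.default_rng(42)
    z = math.radians(90.833)
    for _ in range(1000):
        lat = rng.uniform(-60, 60)
        day = date(2019, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        delta = math.radians(_declination_deg(day.timetuple().tm_yday))
        phi = math.radians(lat)
        x = (math.cos(z) - math.sin(phi) * math.sin(delta)) / (
            math.cos(phi) * math.cos(delta)
        )
        if abs(x) >= 1:
            continue
        closed_form_h = 2 * math.degrees(math.acos(x)) / 15.0
        ev = sun_events(lat, rng.uniform(-180, 180), day)
        assert ev.marker is None
        assert abs(day_length_hours(ev) - closed_form_h) < 0.25


def test_diurnal_boundary_is_sunrise_inclusive_sunset_exclusive():
    lat, lon, day = 37.0, -6.0, date(2019, 9, 10)
    ev = sun_events(lat, lon, day)
    at_sunrise = Fix("b", ev.sunrise, lat, lon)
    before = Fix("b", ev.sunrise - timedelta(seconds=1), lat, lon)
    at_sunset = Fix("b", ev.sunset, lat, lon)
    assert is_diurnal(at_sunrise) is True
    assert is_diurnal(before) is False
    assert is_diurnal(at_sunset) is False


def test_local_noon_is_diurnal():
    # solar noon at (37, -6) is ~12:24 UTC; midway between the day's events
    ev = sun_events(37.0, -6.0, date(2019, 9, 10))
    noon = ev.sunrise + (ev.sunset - ev.sunrise) / 2
    assert is_diurnal(Fix("b", noon, 37.0, -6.0)) is True


def test_is_diurnal_consistent_with_sun_events():
    rng = np.random.default_rng(5)
    for _ in range(200):
        lat = float(rng.uniform(-55, 55))
        lon = float(rng.uniform(-170, 170))
        t = datetime(2019, 1, 1, tzinfo=timezone.utc) + timedelta(
            minutes=float(rng.uniform(0, 525000))
        )
        fix = Fix("b", t, lat, lon)
        ev = sun_events(lat, lon, t.date())
        expected = ev.sunrise <= fix.timestamp < ev.sunset
        assert is_diurnal(fix) is expected
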