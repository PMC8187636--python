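"""Environmental annotation: geography class, wind support, and BLH.

Wind is interpolated from the gridded field (bilinear in lat/lon, linear
in time) and projected onto each segment's realised travel direction to
give a tailwind component (positive = supportive) and an absolute
crosswind component, both converted to km/h so they share units with
ground speed. Boundary-layer height (BLH) is a proxy for the availability
and strength of thermal uplift.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import Point

from .types import Fix, GeographyMap, HourlySegment, WindField, WindVector

MS_TO_KMH = 3.6


def label_geography(point: tuple[float, float], geography: GeographyMap) -> str:
    """Geography class at a (lat, lon) point.

    The first listed polygon covering the point wins (boundary counts as
    inside); points covered by no polygon default to non-barrier.
    """
    p = Point(point[1], point[0])  # shapely is (x=lon, y=lat)
    for cls, _geom, prepared in geography._prepared:
        if prepared.covers(p):
            return cls
    return "non-barrier"


def _axis_weights(grid: np.ndarray, x: np.ndarray, name: str):
    """Indices and weights for 1-D linear interpolation along one axis."""
    if np.any(x < grid[0]) or np.any(x > grid[-1]):
        raise ValueError(f"position outside wind-field coverage on {name} axis")
    hi = np.clip(np.searchsorted(grid, x, side="left"), 1, len(grid) - 1)
    lo = hi - 1
    denom = grid[hi] - grid[lo]
    w = np.where(denom > 0, (x - grid[lo]) / np.where(denom > 0, denom, 1), 0.0)
    return lo, hi, w


def interpolate_wind_batch(field: WindField, times, lats, lons):
    """Vectorised (u, v, blh) at arbitrary points inside the field.

    Separable linear interpolation: bilinear in lat/lon and linear in
    time, independently for each variable. Raises when any point falls
    outside the grid, naming the offending axis.
    """
    t = np.asarray(times, dtype="datetime64[s]").astype(float)
    grid_t = field.times.astype(float)
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    t = np.atleast_1d(t)
    if len(field.times) < 2:
        raise ValueError("wind field needs >= 2 time steps for interpolation")
    it0, it1, wt = _axis_weights(grid_t, t, "time")
    iy0, iy1, wy = _axis_weights(field.lats, lats, "lat")
    ix0, ix1, wx = _axis_weights(field.lons, lons, "lon")

    def interp(arr):
        out = np.zeros_like(wt)
        for it, ct in ((it0, 1 - wt), (it1, wt)):
            for iy, cy in ((iy0, 1 - wy), (iy1, wy)):
                for ix, cx in ((ix0, 1 - wx), (ix1, wx)):
                    out += ct * cy * cx * arr[it, iy, ix]
        return out

    return interp(field.u), interp(field.v), interp(field.blh)


def interpolate_wind(field: WindField, fix: Fix) -> tuple[WindVector, float]:
    """Wind vector and BLH at one fix's position and time."""
    u, v, blh = interpolate_wind_batch(
        field, [np.datetime64(fix.timestamp.replace(tzinfo=None), "s")],
        [fix.lat], [fix.lon],
    )
    return WindVector(u=float(u[0]), v=float(v[0])), float(blh[0])


def wind_components(wind: WindVector, travel_bearing_deg: float) -> tuple[float, float]:
    """(tailwind, |crosswind|) in km/h for a given travel bearing.

    tailwind = 3.6 * (u sin(theta) + v cos(theta)); crosswind is the
    perpendicular component's absolute value, so
    tailwind^2 + crosswind^2 = (3.6 |w|)^2.
    """
    if travel_bearing_deg is None:
        raise ValueError("travel bearing undefined (stationary segment)")
    theta = math.radians(travel_bearing_deg)
    tail = MS_TO_KMH * (wind.u * math.sin(theta) + wind.v * math.cos(theta))
    cross = MS_TO_KMH * abs(wind.u * math.cos(theta) - wind.v * math.sin(theta))
    return tail, cross


def annotate_segments(
    segments: list[HourlySegment],
    geography: GeographyMap | None = None,
    wind: WindField | None = None,
) -> list[HourlySegment]:
    """Attach geography, tailwind/crosswind and BLH to segments in place.

    All annotations are anchored at the segment's start fix. Segments
    with undefined bearing keep wind components unset.
    """
    if geography is not None:
        for s in segments:
            s.geography = label_geography((s.start_fix.lat, s.start_fix.lon), geography)
    if wind is not None:
        times = np.array(
            [np.datetime64(s.start_fix.timestamp.replace(tzinfo=None), "s") for s in segments]
        )
        lats = [s.start_fix.lat for s in segments]
        lons = [s.start_fix.lon for s in segments]
        if segments:
            u, v, blh = interpolate_wind_batch(wind, times, lats, lons)
            for s, ui, vi, bi in zip(segments, u, v, blh):
                s.blh_m = float(bi)
                if s.bearing_deg is not None:
                    tail, cross = wind_components(WindVector(float(ui), float(vi)), s.bearing_deg)
                    s.tailwind_kmh = tail
                    s.crosswind_abs_kmh = cross
    return segments
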