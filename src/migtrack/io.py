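"""Readers and writers for tracks, gridded weather, geography and the
pipeline's output tables.

Tracks arrive as Movebank-style CSV (individual_id, timestamp, lat, lon,
UTC). Gridded wind/BLH is NetCDF with dims (time, lat, lon) or an
equivalent long-format CSV; geography is a GeoJSON FeatureCollection
whose features carry a "class" property in {sea, desert, non-barrier}.
Output tables (segments, days, trips) are plain CSV with a stable column
order and round-trip their values exactly.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from .types import (
    DayUnit,
    Fix,
    FormatError,
    GeographyMap,
    HourlySegment,
    Track,
    TripSummary,
    WindField,
)

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ("individual_id", "timestamp", "lat", "lon")

SEGMENT_COLUMNS = (
    "individual_id",
    "start_time",
    "end_time",
    "start_lat",
    "start_lon",
    "end_lat",
    "end_lon",
    "duration_h",
    "distance_km",
    "ground_speed_kmh",
    "bearing_deg",
    "is_travel",
    "is_diurnal",
    "geography",
    "tailwind_kmh",
    "crosswind_abs_kmh",
    "blh_m",
)

DAY_COLUMNS = (
    "individual_id",
    "day_start",
    "day_end",
    "n_segments",
    "coverage",
    "straight_line_km",
    "travel_duration_h",
    "travel_speed_kmh",
    "diurnal_travel_h",
    "nocturnal_travel_h",
    "nocturnal_travel_fraction",
    "geography_day",
    "mean_tailwind_kmh",
    "mean_crosswind_abs_kmh",
    "mean_blh_m",
    "is_travelling_day",
)

TRIP_COLUMNS = (
    "individual_id",
    "start_date",
    "end_date",
    "duration_days",
    "straight_line_km",
    "cumulative_km",
    "straightness",
    "n_non_travel_days",
    "travel_speed_km_per_day",
)


def read_tracks(path) -> list[Track]:
    """Read a Movebank-style track CSV into one Track per individual.

    Fixes are sorted by time; exact duplicate timestamps collapse to the
    first occurrence with a warning. Unparseable timestamps and
    out-of-range coordinates raise with the offending line number
    (header = line 1).
    """
    df = pd.read_csv(path, dtype={"individual_id": str})
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"track file missing column {col!r}")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    bad = np.nonzero(ts.isna().to_numpy())[0]
    if len(bad):
        raise FormatError(
            f"unparseable timestamp on line {bad[0] + 2}: "
            f"{df['timestamp'].iloc[bad[0]]!r}"
        )
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    bad_lat = np.nonzero((lat.isna() | (lat < -90) | (lat > 90)).to_numpy())[0]
    if len(bad_lat):
        raise FormatError(
            f"invalid latitude on line {bad_lat[0] + 2}: {df['lat'].iloc[bad_lat[0]]!r}"
        )
    bad_lon = np.nonzero((lon.isna() | (lon < -180) | (lon > 180)).to_numpy())[0]
    if len(bad_lon):
        raise FormatError(
            f"invalid longitude on line {bad_lon[0] + 2}: {df['lon'].iloc[bad_lon[0]]!r}"
        )
    df = df.assign(timestamp=ts, lat=lat, lon=lon)
    tracks = []
    for ind, g in df.groupby("individual_id", sort=True):
        g = g.sort_values("timestamp", kind="stable")
        dup = g["timestamp"].duplicated()
        if dup.any():
            logger.warning(
                "individual %s: %d duplicate timestamp(s) dropped (kept first)",
                ind,
                int(dup.sum()),
            )
            g = g[~dup]
        fixes = [
            Fix(str(ind), t.to_pydatetime(), float(la), float(lo))
            for t, la, lo in zip(g["timestamp"], g["lat"], g["lon"])
        ]
        tracks.append(Track(str(ind), fixes))
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks back to Movebank-style CSV."""
    rows = [
        (t.individual_id, f.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"), f.lat, f.lon)
        for t in tracks
        for f in t.fixes
    ]
    pd.DataFrame(rows, columns=list(TRACK_COLUMNS)).to_csv(path, index=False)


def read_wind_grid(path) -> WindField:
    """Read gridded u/v/blh from NetCDF or long-format CSV.

    NetCDF needs dims (time, lat, lon) and variables u, v, blh; the long
    CSV needs columns time, lat, lon, u, v, blh forming a complete grid.
    Descending coordinate axes are normalised to ascending.
    """
    path = Path(path)
    if path.suffix.lower() in (".nc", ".nc3", ".cdf", ".netcdf"):
        ds = xr.open_dataset(path, engine="scipy")
    else:
        df = pd.read_csv(path)
        for col in ("time", "lat", "lon", "u", "v", "blh"):
            if col not in df.columns:
                raise FormatError(f"missing variable {col}")
        df["time"] = pd.to_datetime(df["time"], utc=True).dt.tz_localize(None)
        ds = df.set_index(["time", "lat", "lon"]).to_xarray()
    for dim in ("time", "lat", "lon"):
        if dim not in ds.dims:
            raise FormatError(f"wind grid missing dimension {dim!r}")
    for var in ("u", "v", "blh"):
        if var not in ds.data_vars:
            raise FormatError(f"missing variable {var}")
    for dim in ("lat", "lon"):
        vals = ds[dim].values
        if len(vals) > 1 and vals[0] > vals[-1]:
            ds = ds.sortby(dim)
        elif not np.all(np.diff(vals) > 0) and len(vals) > 1:
            ds = ds.sortby(dim)
    ds = ds.sortby("time")
    arr = ds.transpose("time", "lat", "lon")
    if arr["u"].isnull().any() or arr["v"].isnull().any() or arr["blh"].isnull().any():
        raise FormatError("wind grid has missing node values (incomplete grid)")
    return WindField(
        arr["time"].values,
        arr["lat"].values,
        arr["lon"].values,
        arr["u"].values,
        arr["v"].values,
        arr["blh"].values,
    )


def write_wind_grid(field: WindField, path) -> None:
    """Write a WindField to NetCDF (classic format) or long CSV by suffix."""
    path = Path(path)
    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), field.u),
            "v": (("time", "lat", "lon"), field.v),
            "blh": (("time", "lat", "lon"), field.blh),
        },
        coords={"time": field.times, "lat": field.lats, "lon": field.lons},
    )
    if path.suffix.lower() in (".nc", ".nc3", ".cdf", ".netcdf"):
        ds.to_netcdf(path, engine="scipy")
    else:
        ds.to_dataframe().reset_index().to_csv(path, index=False)


def read_geography(path) -> GeographyMap:
    """Read a GeoJSON FeatureCollection of class-labelled polygons."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    if not feats:
        raise FormatError("no polygons")
    polygons = []
    for i, feat in enumerate(feats):
        cls = (feat.get("properties") or {}).get("class")
        if cls not in ("sea", "desert", "non-barrier"):
            raise FormatError(f"feature {i} has invalid class {cls!r}")
        polygons.append((cls, shape(feat["geometry"])))
    return GeographyMap(polygons)


def write_geography(geography: GeographyMap, path) -> None:
    """Write a GeographyMap as a GeoJSON FeatureCollection."""
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"class": cls},
                "geometry": mapping(geom),
            }
            for cls, geom in geography.polygons
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def _fmt_time(t: datetime) -> str:
    return t.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def segments_to_frame(segments: list[HourlySegment]) -> pd.DataFrame:
    rows = [
        (
            s.individual_id,
            _fmt_time(s.start_fix.timestamp),
            _fmt_time(s.end_fix.timestamp),
            s.start_fix.lat,
            s.start_fix.lon,
            s.end_fix.lat,
            s.end_fix.lon,
            s.duration_h,
            s.distance_km,
            s.ground_speed_kmh,
            s.bearing_deg,
            s.is_travel,
            s.is_diurnal,
            s.geography,
            s.tailwind_kmh,
            s.crosswind_abs_kmh,
            s.blh_m,
        )
        for s in segments
    ]
    return pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS))


def days_to_frame(days: list[DayUnit]) -> pd.DataFrame:
    rows = [
        (
            d.individual_id,
            _fmt_time(d.day_start),
            _fmt_time(d.day_end),
            len(d.segments),
            d.coverage,
            d.straight_line_km,
            d.travel_duration_h,
            d.travel_speed_kmh,
            d.diurnal_travel_h,
            d.nocturnal_travel_h,
            d.nocturnal_travel_fraction,
            d.geography_day,
            d.mean_tailwind_kmh,
            d.mean_crosswind_abs_kmh,
            d.mean_blh_m,
            d.is_travelling_day,
        )
        for d in days
    ]
    return pd.DataFrame(rows, columns=list(DAY_COLUMNS))


def trips_to_frame(trips: list[TripSummary]) -> pd.DataFrame:
    rows = [
        (
            t.individual_id,
            t.start_date.isoformat(),
            t.end_date.isoformat(),
            t.duration_days,
            t.straight_line_km,
            t.cumulative_km,
            t.straightness,
            t.n_non_travel_days,
            t.travel_speed_km_per_day,
        )
        for t in trips
    ]
    return pd.DataFrame(rows, columns=list(TRIP_COLUMNS))


_FRAME_BUILDERS = {
    HourlySegment: segments_to_frame,
    DayUnit: days_to_frame,
    TripSummary: trips_to_frame,
}


def write_table(records, path) -> None:
    """Write homogeneous segment / day / trip records to CSV.

    The column order is the module-level *_COLUMNS constant of the
    record kind; values round-trip through :func:`read_table` exactly.
    An empty list writes a header-only segment table.
    """
    records = list(records)
    if not records:
        pd.DataFrame(columns=list(SEGMENT_COLUMNS)).to_csv(path, index=False)
        return
    kinds = {type(r) for r in records}
    if len(kinds) > 1 or next(iter(kinds)) not in _FRAME_BUILDERS:
        raise FormatError(f"mixed or unknown record kinds: {sorted(k.__name__ for k in kinds)}")
    _FRAME_BUILDERS[next(iter(kinds))](records).to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a pipeline output table back into a DataFrame."""
    return pd.read_csv(path)
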