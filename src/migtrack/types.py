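"""Core domain containers shared across the pipeline.

A :class:`Track` is an individual's time-ordered GPS fix sequence; hourly
resampling turns it into :class:`HourlySegment` steps, which are grouped
into sunrise-to-sunrise :class:`DayUnit` windows; trip detection produces
:class:`TripSummary` records. Gridded weather and labelled geography are
held in :class:`WindField` and :class:`GeographyMap`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime, timezone

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

GEOGRAPHY_CLASSES = ("sea", "desert", "non-barrier")


class FormatError(ValueError):
    """A file or table does not match the expected layout."""


@dataclass(frozen=True)
class Fix:
    """One GPS location of one individual, timestamped in UTC."""

    individual_id: str
    timestamp: datetime
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not np.isfinite(self.lon):
            raise ValueError(f"longitude {self.lon} not finite")
        # normalise longitude to [-180, 180)
        lon = ((self.lon + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "lon", float(lon))
        ts = self.timestamp
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        else:
            ts = ts.astimezone(timezone.utc)
        object.__setattr__(self, "timestamp", ts)


@dataclass
class Track:
    """Time-ordered fixes of one individual (may span several trips)."""

    individual_id: str
    fixes: list[Fix]

    def __post_init__(self) -> None:
        for f in self.fixes:
            if f.individual_id != self.individual_id:
                raise ValueError(
                    f"fix individual {f.individual_id!r} != track "
                    f"{self.individual_id!r}"
                )
        times = [f.timestamp for f in self.fixes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("fix timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)


class SolarMarker(enum.Enum):
    """Degenerate solar days at high latitude."""

    POLAR_DAY = "polar_day"
    POLAR_NIGHT = "polar_night"


@dataclass(frozen=True)
class SunEvents:
    """Sunrise/sunset UTC instants for one civil date at one location.

    Either both instants are set, or ``marker`` flags a polar day/night.
    """

    date: date
    sunrise: datetime | None
    sunset: datetime | None
    marker: SolarMarker | None = None

    def __post_init__(self) -> None:
        if self.marker is None:
            if self.sunrise is None or self.sunset is None:
                raise ValueError("finite events require sunrise and sunset")
            if self.sunrise >= self.sunset:
                raise ValueError("sunrise must precede sunset")


@dataclass
class HourlySegment:
    """One resampled ~1-hour step with its travel and environment labels.

    ``is_diurnal``, ``geography`` and the wind fields refer to the start
    fix — one consistent anchoring convention for all annotations.
    """

    individual_id: str
    start_fix: Fix
    end_fix: Fix
    duration_h: float
    distance_km: float
    ground_speed_kmh: float
    bearing_deg: float | None
    is_travel: bool
    is_diurnal: bool | None = None
    geography: str | None = None
    tailwind_kmh: float | None = None
    crosswind_abs_kmh: float | None = None
    blh_m: float | None = None


@dataclass
class DailyDistance:
    """Summed consecutive-fix distance for one UTC calendar day."""

    date: date
    dist_km: float
    n_fixes: int

    def __post_init__(self) -> None:
        if self.dist_km < 0:
            raise ValueError("daily distance must be non-negative")


@dataclass
class TripSummary:
    """Trip-scale migration metrics between detected onset and end dates."""

    individual_id: str
    start_date: date
    end_date: date
    duration_days: int
    straight_line_km: float
    cumulative_km: float
    straightness: float
    n_non_travel_days: int
    travel_speed_km_per_day: float


@dataclass
class DayUnit:
    """A sunrise-to-sunrise window with its segments and daily metrics."""

    individual_id: str
    day_start: datetime
    day_end: datetime
    segments: list[HourlySegment] = field(default_factory=list)
    coverage: float | None = None
    straight_line_km: float | None = None
    travel_duration_h: float | None = None
    travel_speed_kmh: float | None = None
    diurnal_travel_h: float | None = None
    nocturnal_travel_h: float | None = None
    nocturnal_travel_fraction: float | None = None
    geography_day: str | None = None
    mean_tailwind_kmh: float | None = None
    mean_crosswind_abs_kmh: float | None = None
    mean_blh_m: float | None = None
    is_travelling_day: bool | None = None


@dataclass(frozen=True)
class WindVector:
    """Eastward (u) / northward (v) wind components, m/s."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("wind components must be finite")


class WindField:
    """Gridded u/v wind and boundary-layer height on (time, lat, lon).

    ``times`` are UTC datetime64 values (nominally 6-hourly), lat/lon are
    strictly ascending 1-D grids (nominally 0.75 degrees); u and v are in
    m/s, blh in metres.
    """

    def __init__(self, times, lats, lons, u, v, blh):
        self.times = np.asarray(times, dtype="datetime64[s]")
        self.lats = np.asarray(lats, dtype=float)
        self.lons = np.asarray(lons, dtype=float)
        self.u = np.asarray(u, dtype=float)
        self.v = np.asarray(v, dtype=float)
        self.blh = np.asarray(blh, dtype=float)
        for name, ax in (("time", self.times), ("lat", self.lats), ("lon", self.lons)):
            if ax.ndim != 1 or len(ax) < 1:
                raise FormatError(f"{name} axis must be 1-D and non-empty")
            if len(ax) > 1 and not np.all(np.diff(ax) > (0 if name != "time" else np.timedelta64(0, "s"))):
                raise FormatError(f"{name} axis must be strictly increasing")
        shape = (len(self.times), len(self.lats), len(self.lons))
        for name, arr in (("u", self.u), ("v", self.v), ("blh", self.blh)):
            if arr.shape != shape:
                raise FormatError(
                    f"variable {name} has shape {arr.shape}, expected {shape}"
                )
        if np.any(self.blh < 0):
            raise FormatError("blh must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.times), len(self.lats), len(self.lons))


class GeographyMap:
    """Labelled polygons (sea / desert / non-barrier) for barrier lookup.

    Polygon order matters: the first polygon containing a point wins, so
    shared boundaries resolve to the earlier-listed class.
    """

    def __init__(self, polygons: list[tuple[str, BaseGeometry]]):
        if not polygons:
            raise FormatError("no polygons")
        for cls, geom in polygons:
            if cls not in GEOGRAPHY_CLASSES:
                raise FormatError(
                    f"geography class {cls!r} not in {GEOGRAPHY_CLASSES}"
                )
            if geom.is_empty:
                raise FormatError("empty polygon geometry")
        self.polygons = list(polygons)
        # prepared geometries answer covers() much faster on long tracks
        self._prepared = [(cls, geom, prep(geom)) for cls, geom in self.polygons]

    def __len__(self) -> int:
        return len(self.polygons)
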