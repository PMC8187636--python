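"""End-to-end orchestration: raw tracks to trip, day and segment tables.

For each track the pipeline computes the daily-distance series, detects
migration onset/end, restricts to the trip, resamples to hourly cadence,
builds and annotates segments, partitions sunrise-to-sunrise day units,
and summarises the trip. Each stage stays usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import io
from .annotation import annotate_segments
from .daily import compute_day_units
from .geosolar import gc_bearing
from .resampling import build_segments, resample_hourly
from .trips import (
    MIN_SERIES_DAYS,
    daily_distance_series,
    detect_trip,
    trip_summary,
)
from .types import (
    DayUnit,
    GeographyMap,
    HourlySegment,
    Track,
    TripSummary,
    WindField,
)


@dataclass
class TripAnalysis:
    """Everything the pipeline derives from one track."""

    track: Track
    trip: tuple | None = None  # (start_date, end_date) or None
    summary: TripSummary | None = None
    segments: list[HourlySegment] = field(default_factory=list)
    day_units: list[DayUnit] = field(default_factory=list)


def analyse_track(
    track: Track,
    wind: WindField | None = None,
    geography: GeographyMap | None = None,
    direction: str = "post",
) -> TripAnalysis:
    """Run the full pipeline on one track.

    Returns an empty analysis (trip None) when the series is too short
    or no onset/end pair qualifies.
    """
    daily = daily_distance_series(track)
    if len(daily) < MIN_SERIES_DAYS:
        return TripAnalysis(track=track)
    trip = detect_trip(daily, direction)
    if trip is None:
        return TripAnalysis(track=track)
    start, end = trip
    trip_fixes = [f for f in track.fixes if start <= f.timestamp.date() <= end]
    trip_track = Track(track.individual_id, trip_fixes)
    segments = build_segments(resample_hourly(trip_track))
    annotate_segments(segments, geography=geography, wind=wind)
    first, last = trip_fixes[0], trip_fixes[-1]
    try:
        axis = gc_bearing((first.lat, first.lon), (last.lat, last.lon))
    except ValueError:
        axis = None
    if axis is not None:
        day_units = compute_day_units(segments, trip_track, axis)
    else:
        day_units = []
    summary = trip_summary(track, start, end, daily)
    return TripAnalysis(
        track=track,
        trip=trip,
        summary=summary,
        segments=segments,
        day_units=day_units,
    )


def analyse_tracks(
    tracks: list[Track],
    wind: WindField | None = None,
    geography: GeographyMap | None = None,
    direction: str = "post",
) -> list[TripAnalysis]:
    return [analyse_track(t, wind, geography, direction) for t in tracks]


def segment_table(analyses: list[TripAnalysis]) -> pd.DataFrame:
    return io.segments_to_frame([s for a in analyses for s in a.segments])


def day_table(analyses: list[TripAnalysis]) -> pd.DataFrame:
    return io.days_to_frame([d for a in analyses for d in a.day_units])


def trip_table(analyses: list[TripAnalysis]) -> pd.DataFrame:
    return io.trips_to_frame([a.summary for a in analyses if a.summary])


def hourly_schedule(analyses: list[TripAnalysis]) -> pd.DataFrame:
    """Travel / non-travel segment counts per UTC hour of day."""
    rows = []
    for a in analyses:
        for s in a.segments:
            rows.append((s.start_fix.timestamp.hour, s.is_travel))
    df = pd.DataFrame(rows, columns=["hour", "is_travel"])
    if df.empty:
        return pd.DataFrame(columns=["hour", "n_travel", "n_non_travel"])
    counts = (
        df.groupby("hour")["is_travel"]
        .agg(n_travel="sum", n_total="count")
        .reset_index()
    )
    counts["n_travel"] = counts["n_travel"].astype(int)
    counts["n_non_travel"] = counts["n_total"] - counts["n_travel"]
    return counts[["hour", "n_travel", "n_non_travel"]]


def travel_counts(segments: list[HourlySegment]) -> tuple[int, int]:
    """(travel, non-travel) segment counts for schedule contingency tables."""
    n_travel = sum(1 for s in segments if s.is_travel)
    return n_travel, len(segments) - n_travel
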