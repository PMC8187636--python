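"""Sunrise-to-sunrise day units and daily-scale travel metrics.

A migration day runs from one sunrise to the next, capturing a complete
day-night cycle (these birds frequently travel at night). Days with less
than 75% coverage are dropped to avoid gap bias; travelling days are
those displacing >= 50 km along the migration axis; a day's geography is
the class occupying >= 60% of its segment time, else "mixed".
"""

from __future__ import annotations

import logging
import math
from datetime import timedelta

from .geosolar import gc_bearing, gc_distance, sun_events
from .types import DayUnit, HourlySegment, SunEvents, Track

logger = logging.getLogger(__name__)

COVERAGE_MIN = 0.75
TRAVELLING_DAY_KM = 50.0
GEOGRAPHY_DAY_FRACTION = 0.60


def _sunrise_near(track: Track, when) -> SunEvents:
    """Sun events for the date of ``when`` at the track position nearest it."""
    fix = min(track.fixes, key=lambda f: abs(f.timestamp - when))
    ev = sun_events(fix.lat, fix.lon, when.date())
    if ev.marker is not None:
        raise ValueError(
            "sunrise-to-sunrise day units undefined during polar day/night"
        )
    return ev


def partition_days(segments: list[HourlySegment], track: Track) -> list[DayUnit]:
    """Group segments into sunrise-to-sunrise day units.

    Day d is [sunrise_d, sunrise_{d+1}), each sunrise evaluated at the
    bird's position nearest that instant; a segment belongs to the day
    containing its start fix.
    """
    if not segments:
        return []
    segments = sorted(segments, key=lambda s: s.start_fix.timestamp)
    t0 = segments[0].start_fix.timestamp
    t_last = segments[-1].start_fix.timestamp
    sr = _sunrise_near(track, t0).sunrise
    if t0 < sr:
        sr = _sunrise_near(track, t0 - timedelta(days=1)).sunrise
    boundaries = [sr]
    while boundaries[-1] <= t_last:
        nxt = _sunrise_near(track, boundaries[-1] + timedelta(days=1)).sunrise
        boundaries.append(nxt)
    units = [
        DayUnit(
            individual_id=track.individual_id,
            day_start=a,
            day_end=b,
        )
        for a, b in zip(boundaries, boundaries[1:])
    ]
    for seg in segments:
        t = seg.start_fix.timestamp
        for unit in units:
            if unit.day_start <= t < unit.day_end:
                unit.segments.append(seg)
                break
    return [u for u in units if u.segments]


def day_coverage(day: DayUnit) -> float:
    """Fraction of the day's 24 clock hours holding >= 1 segment start."""
    hours = {
        s.start_fix.timestamp.replace(minute=0, second=0, microsecond=0)
        for s in day.segments
    }
    # a sunrise-to-sunrise unit can touch 25 clock-hour buckets; cap at 1
    return min(1.0, len(hours) / 24.0)


def coverage_filter(day: DayUnit) -> bool:
    """Retain the day iff coverage >= 75% (threshold inclusive)."""
    if day.coverage is None:
        day.coverage = day_coverage(day)
    return day.coverage >= COVERAGE_MIN


def _day_endpoints(day: DayUnit):
    first = day.segments[0].start_fix
    last = day.segments[-1].end_fix
    return first, last


def classify_travelling_day(day: DayUnit, migration_axis_bearing: float) -> bool:
    """Travelling day iff displacement along the migration axis >= 50 km.

    The axis is the trip's start-to-end great-circle bearing; the day's
    displacement vector is projected onto it with the cosine of the
    bearing difference. Days with < 2 distinct positions are
    non-travelling by convention.
    """
    if not day.segments:
        return False
    first, last = _day_endpoints(day)
    dist = gc_distance((first.lat, first.lon), (last.lat, last.lon))
    if dist == 0.0:
        return False
    bearing = gc_bearing((first.lat, first.lon), (last.lat, last.lon))
    component = dist * math.cos(math.radians(bearing - migration_axis_bearing))
    return component >= TRAVELLING_DAY_KM


def classify_day_geography(day: DayUnit) -> str:
    """Dominant geography class (>= 60% of segment time), else "mixed".

    Sea and desert stay separate here; pooling into a barrier factor
    happens in the models.
    """
    totals: dict[str, float] = {}
    total_h = 0.0
    for s in day.segments:
        if s.geography is None:
            continue
        totals[s.geography] = totals.get(s.geography, 0.0) + s.duration_h
        total_h += s.duration_h
    if total_h == 0.0:
        return "mixed"
    cls, best = max(totals.items(), key=lambda kv: kv[1])
    return cls if best / total_h >= GEOGRAPHY_DAY_FRACTION else "mixed"


def day_metrics(day: DayUnit, migration_axis_bearing: float | None = None) -> DayUnit:
    """Fill a day unit's daily metrics in place and return it.

    Straight-line distance runs from the day's first to last position;
    travel duration sums travel segments only (excluding foraging and
    resting); travel speed is straight-line distance over travel
    duration; weather means average over travel segments only.
    """
    if day.coverage is None:
        day.coverage = day_coverage(day)
    first, last = _day_endpoints(day)
    day.straight_line_km = gc_distance((first.lat, first.lon), (last.lat, last.lon))
    travel = [s for s in day.segments if s.is_travel]
    day.travel_duration_h = sum(s.duration_h for s in travel)
    day.diurnal_travel_h = sum(s.duration_h for s in travel if s.is_diurnal)
    day.nocturnal_travel_h = day.travel_duration_h - day.diurnal_travel_h
    if day.travel_duration_h > 0:
        day.travel_speed_kmh = day.straight_line_km / day.travel_duration_h
        day.nocturnal_travel_fraction = day.nocturnal_travel_h / day.travel_duration_h
    else:
        logger.debug("day %s: no travel segments; speed undefined", day.day_start)
        day.travel_speed_kmh = None
        day.nocturnal_travel_fraction = None
    day.geography_day = classify_day_geography(day)

    def mean_over(attr: str) -> float | None:
        vals = [getattr(s, attr) for s in travel if getattr(s, attr) is not None]
        return sum(vals) / len(vals) if vals else None

    day.mean_tailwind_kmh = mean_over("tailwind_kmh")
    day.mean_crosswind_abs_kmh = mean_over("crosswind_abs_kmh")
    day.mean_blh_m = mean_over("blh_m")
    if migration_axis_bearing is not None:
        day.is_travelling_day = classify_travelling_day(day, migration_axis_bearing)
    return day


def compute_day_units(
    segments: list[HourlySegment],
    track: Track,
    migration_axis_bearing: float,
    apply_coverage_filter: bool = True,
) -> list[DayUnit]:
    """Partition, filter by coverage, and fill daily metrics for a trip."""
    units = partition_days(segments, track)
    for u in units:
        u.coverage = day_coverage(u)
    if apply_coverage_filter:
        units = [u for u in units if coverage_filter(u)]
    return [day_metrics(u, migration_axis_bearing) for u in units]
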