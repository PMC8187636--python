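"""Migration onset/end detection and trip-scale travel metrics.

Onset and end are found from the daily-distance series as marked shifts:
the trip starts on the first day of the earliest 3-day window averaging
>= 150 km/day that directly follows a stationary phase (5 consecutive
days averaging < 70 km/day), and ends on the last day of the latest such
window directly followed by a stationary phase. Trip metrics follow the
standard movement-ecology definitions: straight-line (orthodromic)
distance, cumulative distance, straightness index, non-travelling days
(< 50 km/day) and travel speed excluding non-travelling days.
"""

from __future__ import annotations

import logging
from datetime import date, timedelta

from .geosolar import gc_distance
from .types import DailyDistance, Track, TripSummary

logger = logging.getLogger(__name__)

#: mean daily distance (km) a 3-day window must reach to count as migration
ONSET_WINDOW_KM = 150.0
ONSET_WINDOW_DAYS = 3
#: mean daily distance (km) below which a 5-day phase counts as stationary
STATIONARY_KM = 70.0
STATIONARY_DAYS = 5
#: daily distance (km) below which a trip day is non-travelling
NON_TRAVEL_DAY_KM = 50.0

MIN_SERIES_DAYS = 2 * STATIONARY_DAYS + ONSET_WINDOW_DAYS


def daily_distance_series(track: Track) -> list[DailyDistance]:
    """Per-UTC-calendar-day sums of consecutive fix-to-fix distances.

    Each step's distance is assigned to the day of its *end* fix, so steps
    spanning midnight count toward the day the bird arrives in. Days
    within the track's date range with no ending step get 0 km.
    """
    if not track.fixes:
        return []
    first_day = track.fixes[0].timestamp.date()
    last_day = track.fixes[-1].timestamp.date()
    n_days = (last_day - first_day).days + 1
    dist = {first_day + timedelta(days=k): 0.0 for k in range(n_days)}
    n_fixes = {d: 0 for d in dist}
    for f in track.fixes:
        n_fixes[f.timestamp.date()] += 1
    for a, b in zip(track.fixes, track.fixes[1:]):
        dist[b.timestamp.date()] += gc_distance((a.lat, a.lon), (b.lat, b.lon))
    return [
        DailyDistance(date=d, dist_km=dist[d], n_fixes=n_fixes[d])
        for d in sorted(dist)
    ]


def detect_trip(
    series: list[DailyDistance], direction: str = "post"
) -> tuple[date, date] | None:
    """Detect migration onset and end dates from a daily-distance series.

    ``direction`` labels the season (post- or pre-breeding); the detection
    rule is identical for both. Returns None when no onset/end pair with
    onset < end exists. The series must be contiguous in date and cover
    at least 13 days (two stationary phases plus one travel window).
    """
    if direction not in ("post", "pre"):
        raise ValueError("direction must be 'post' or 'pre'")
    if len(series) < MIN_SERIES_DAYS:
        raise ValueError(
            f"series covers {len(series)} days; need >= {MIN_SERIES_DAYS}"
        )
    dates = [s.date for s in series]
    if any((b - a).days != 1 for a, b in zip(dates, dates[1:])):
        raise ValueError("series dates must be contiguous")
    d = [s.dist_km for s in series]
    n = len(d)

    def win_mean(i: int, k: int) -> float:
        return sum(d[i : i + k]) / k

    # The stationary phase must END where the onset window begins: the
    # window's first (onset) or last (end) day may not itself be a
    # stationary day, otherwise averaging one huge travel day with two
    # stationary days would pull the onset into the residence phase.
    start_idx = None
    for i in range(STATIONARY_DAYS, n - ONSET_WINDOW_DAYS + 1):
        if (
            win_mean(i, ONSET_WINDOW_DAYS) >= ONSET_WINDOW_KM
            and d[i] >= STATIONARY_KM
            and win_mean(i - STATIONARY_DAYS, STATIONARY_DAYS) < STATIONARY_KM
        ):
            start_idx = i
            break
    end_idx = None
    for i in range(n - ONSET_WINDOW_DAYS - STATIONARY_DAYS, -1, -1):
        if (
            win_mean(i, ONSET_WINDOW_DAYS) >= ONSET_WINDOW_KM
            and d[i + ONSET_WINDOW_DAYS - 1] >= STATIONARY_KM
            and win_mean(i + ONSET_WINDOW_DAYS, STATIONARY_DAYS) < STATIONARY_KM
        ):
            end_idx = i + ONSET_WINDOW_DAYS - 1
            break
    if start_idx is None or end_idx is None:
        return None
    if start_idx >= end_idx:
        logger.info(
            "trip rejected: onset %s not before end %s",
            dates[start_idx],
            dates[end_idx],
        )
        return None
    return dates[start_idx], dates[end_idx]


def trip_summary(
    track: Track,
    start_date: date,
    end_date: date,
    daily: list[DailyDistance] | None = None,
) -> TripSummary:
    """Trip-scale metrics for a detected trip.

    Straight-line distance runs from the first fix on the start date to
    the last fix on the end date; cumulative distance sums the daily
    distances over the trip; travel speed is straight-line distance per
    travelling day (days with >= 50 km total daily distance).
    """
    if daily is None:
        daily = daily_distance_series(track)
    trip_fixes = [
        f for f in track.fixes if start_date <= f.timestamp.date() <= end_date
    ]
    if not trip_fixes or trip_fixes[0].timestamp.date() != start_date:
        raise ValueError(f"no fixes on trip start date {start_date}")
    if trip_fixes[-1].timestamp.date() != end_date:
        raise ValueError(f"no fixes on trip end date {end_date}")
    first, last = trip_fixes[0], trip_fixes[-1]
    straight = gc_distance((first.lat, first.lon), (last.lat, last.lon))
    trip_daily = [s for s in daily if start_date <= s.date <= end_date]
    cumulative = sum(s.dist_km for s in trip_daily)
    duration = (end_date - start_date).days + 1
    n_non_travel = sum(1 for s in trip_daily if s.dist_km < NON_TRAVEL_DAY_KM)
    travelling_days = duration - n_non_travel
    if travelling_days == 0:
        raise ValueError("all trip days non-travelling; travel speed undefined")
    return TripSummary(
        individual_id=track.individual_id,
        start_date=start_date,
        end_date=end_date,
        duration_days=duration,
        straight_line_km=straight,
        cumulative_km=cumulative,
        straightness=straight / cumulative if cumulative > 0 else 1.0,
        n_non_travel_days=n_non_travel,
        travel_speed_km_per_day=straight / travelling_days,
    )
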