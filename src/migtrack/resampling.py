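"""Hourly regularisation of tracks and travel/non-travel classification.

Tracks are resampled to a nominal 1-hour cadence allowing deviations of
up to 20 minutes, by greedy forward selection over the recorded fixes (no
interpolation — every retained fix is an observed fix). Consecutive
retained fixes spaced 40-80 min apart form hourly segments; larger gaps
produce no segment. Segments moving at >= 5 km/h over ground are
classified as travel.
"""

from __future__ import annotations

import logging
from datetime import timedelta

from .geosolar import gc_bearing, gc_distance, is_diurnal
from .types import Fix, HourlySegment, Track

logger = logging.getLogger(__name__)

#: tolerated deviation around the 1-h cadence
MIN_SPACING = timedelta(minutes=40)
MAX_SPACING = timedelta(minutes=80)
#: ground-speed threshold (km/h) separating travel from fly-forage/rest
TRAVEL_SPEED_KMH = 5.0


def resample_hourly(track: Track) -> Track:
    """Thin a track to ~1-h cadence by greedy earliest-in-window selection.

    Keep the first fix; from each kept fix at time t, keep the earliest
    fix in [t+40 min, t+80 min]. When the window is empty, jump to the
    first fix after t+80 min (a gap) and continue from it. Fixes closer
    than 40 min to the last kept fix are dropped. The output is always a
    subsequence of the input and the operation is idempotent.
    """
    fixes = track.fixes
    if len(fixes) < 2:
        logger.warning(
            "track %s has %d fix(es); resampling returns it unchanged",
            track.individual_id,
            len(fixes),
        )
        return Track(track.individual_id, list(fixes))
    kept = [fixes[0]]
    i = 1
    n = len(fixes)
    while i < n:
        t = kept[-1].timestamp
        lo, hi = t + MIN_SPACING, t + MAX_SPACING
        # advance past fixes too close to the last kept fix
        while i < n and fixes[i].timestamp < lo:
            i += 1
        if i < n and fixes[i].timestamp <= hi:
            kept.append(fixes[i])  # earliest fix inside the window
        elif i < n:
            kept.append(fixes[i])  # gap: restart from the next available fix
        i += 1
    return Track(track.individual_id, kept)


def build_segments(track: Track) -> list[HourlySegment]:
    """Build hourly segments from a resampled track.

    One segment per consecutive fix pair spaced 40-80 min apart; pairs
    spanning a gap produce none. The diurnal flag is evaluated at the
    start fix; bearing is undefined (None) for zero-displacement steps.
    """
    segments: list[HourlySegment] = []
    for a, b in zip(track.fixes, track.fixes[1:]):
        dt = b.timestamp - a.timestamp
        if not MIN_SPACING <= dt <= MAX_SPACING:
            continue
        duration_h = dt.total_seconds() / 3600.0
        dist = gc_distance((a.lat, a.lon), (b.lat, b.lon))
        speed = dist / duration_h
        try:
            bearing = gc_bearing((a.lat, a.lon), (b.lat, b.lon))
        except ValueError:
            bearing = None
        segments.append(
            HourlySegment(
                individual_id=track.individual_id,
                start_fix=a,
                end_fix=b,
                duration_h=duration_h,
                distance_km=dist,
                ground_speed_kmh=speed,
                bearing_deg=bearing,
                is_travel=classify_travel_speed(speed),
                is_diurnal=is_diurnal(a),
            )
        )
    return segments


def classify_travel_speed(ground_speed_kmh: float) -> bool:
    """Travel iff ground speed >= 5 km/h (threshold inclusive)."""
    return ground_speed_kmh >= TRAVEL_SPEED_KMH


def classify_travel(segment: HourlySegment) -> bool:
    """Travel/non-travel classification of an hourly segment."""
    return classify_travel_speed(segment.ground_speed_kmh)
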