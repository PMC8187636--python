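"""Shared fixtures: small synthetic datasets and track builders."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from migtrack import SimConfig, Track, simulate_dataset
from migtrack.types import Fix


def make_track(
    minutes,
    individual_id: str = "b1",
    lat0: float = 37.0,
    lon0: float = -5.0,
    dlat_per_fix: float = 0.0,
    t0: datetime | None = None,
) -> Track:
    """Track with fixes at the given minute offsets, optionally moving north."""
    if t0 is None:
        t0 = datetime(2019, 9, 1, 0, 0, tzinfo=timezone.utc)
    fixes = [
        Fix(individual_id, t0 + timedelta(minutes=m), lat0 + k * dlat_per_fix, lon0)
        for k, m in enumerate(minutes)
    ]
    return Track(individual_id, fixes)


@pytest.fixture(scope="session")
def small_dataset():
    """Three simulated birds with wind and geography (no dropout)."""
    return simulate_dataset(SimConfig(seed=11, n_birds=3))


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_birds=3)
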