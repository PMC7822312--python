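"""Shared fixtures: small synthetic cohorts run through QC once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cpforage import io_qc
from cpforage.io_qc import QcParams
from cpforage.synthetic_data import PEAK_HATCH, SimConfig, simulate_cohort
from cpforage.trip_metrics import metrics_table


@pytest.fixture(scope="session")
def qc_params() -> QcParams:
    return QcParams()


@pytest.fixture(scope="session")
def peak_hatch_ts() -> dict[str, pd.Timestamp]:
    return {s: pd.Timestamp(str(d), tz="UTC") for s, d in PEAK_HATCH.items()}


@pytest.fixture(scope="session")
def small_cohort():
    """20-bird faithful cohort: (sim, retained trips after full QC)."""
    cfg = SimConfig(n_birds=20, seed=101)
    sim = simulate_cohort(cfg)
    trips = io_qc.qc_cohort(sim.tracks, sim.nest_checks)
    return sim, trips


@pytest.fixture(scope="session")
def small_trips(small_cohort):
    return small_cohort[1]


@pytest.fixture(scope="session")
def small_metrics(small_cohort, peak_hatch_ts, qc_params) -> pd.DataFrame:
    return metrics_table(small_cohort[1], peak_hatch_ts, qc_params.colony)


def straight_trip(
    speed_kmh: float = 4.0,
    n_fixes: int = 31,
    step_min: float = 20.0,
    bearing_deg: float = 0.0,
    colony=(140.01, -66.66),
    bird_id: str = "tb",
    season: str = "2015-16",
    trip_index: int = 1,
):
    """Out-and-back constant-speed trip along one bearing (planar construction)."""
    from cpforage.geo import from_local_km
    from cpforage.io_qc import Trip

    dt_h = step_min / 60.0
    half = n_fixes // 2
    dist = speed_kmh * dt_h * np.concatenate(
        [np.arange(half + 1), np.arange(half - 1, -1, -1)]
    )[:n_fixes]
    theta = np.radians(bearing_deg)
    x, y = dist * np.sin(theta), dist * np.cos(theta)
    lon, lat = from_local_km(x, y, colony[0], colony[1])
    t0 = pd.Timestamp("2016-01-05T00:00:00Z")
    ts = t0 + pd.to_timedelta(step_min * np.arange(n_fixes), unit="m")
    fixes = pd.DataFrame({"timestamp": ts, "lon": lon, "lat": lat})
    return Trip(
        bird_id=bird_id,
        season=season,
        trip_index=trip_index,
        fixes=fixes,
        departure=ts[0],
        return_time=ts[-1],
    )
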