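"""Per-trip foraging-effort metrics and per-segment kinematics.

The four effort parameters are the total trip duration (h), total path
distance (km), maximal distance from the colony (km) and the bearing from
the colony to the most distal fix (degrees, positive eastward). The bearing
is additionally folded to [0, 180] for variance-component analyses, where
the sign convention would otherwise split a narrow angular corridor across
zero. The within-season timing covariate is days since the season's peak
hatching date (negative if the trip departed before it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo import cumulative_path_km, great_circle_km, initial_bearing_deg
from .io_qc import Trip

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TripMetrics:
    bird_id: str
    season: str
    trip_index: int
    total_duration: float  # hours
    total_distance: float  # km, cumulative over consecutive fixes
    max_distance: float  # km, colony to most distal fix
    bearing: float  # degrees in (-180, 180], positive east
    bearing_folded: float  # degrees in [0, 180]
    days_since_peak_hatch: float
    mean_speed: float  # km/h


@dataclass(frozen=True)
class SegmentKinematics:
    distance: float  # km
    mean_speed: float  # km/h
    sinuosity: float | None  # >= 1; None when straight-line displacement is 0


def compute_metrics(t: Trip, peak_hatch: pd.Timestamp, colony: tuple[float, float]) -> TripMetrics:
    """Compute all effort metrics for one resampled trip.

    The most distal fix breaks ties by earliest timestamp (logged); the
    bearing is evaluated at that fix.
    """
    lon = t.fixes["lon"].to_numpy()
    lat = t.fixes["lat"].to_numpy()
    d_col = np.atleast_1d(great_circle_km(np.array(colony), np.column_stack([lon, lat])))
    i_max = int(np.argmax(d_col))
    if np.sum(np.isclose(d_col, d_col[i_max])) > 1:
        logger.info("%s trip %d: tie for most distal fix; earliest kept", t.bird_id, t.trip_index)
    duration = t.duration_hours
    total = cumulative_path_km(lon, lat)
    bearing = initial_bearing_deg(np.array(colony), np.array([lon[i_max], lat[i_max]]))
    peak_hatch = pd.Timestamp(peak_hatch)
    if peak_hatch.tzinfo is None:
        peak_hatch = peak_hatch.tz_localize("UTC")
    return TripMetrics(
        bird_id=t.bird_id,
        season=t.season,
        trip_index=t.trip_index,
        total_duration=duration,
        total_distance=total,
        max_distance=float(d_col[i_max]),
        bearing=float(bearing),
        bearing_folded=float(abs(bearing)),
        days_since_peak_hatch=(t.departure - peak_hatch).total_seconds() / 86400.0,
        mean_speed=total / duration,
    )


def metrics_table(
    trips, peak_hatch_by_season: dict[str, pd.Timestamp], colony: tuple[float, float]
) -> pd.DataFrame:
    """One row of TripMetrics per trip, keyed by (bird_id, season, trip_index)."""
    rows = [compute_metrics(t, peak_hatch_by_season[t.season], colony) for t in trips]
    return pd.DataFrame([vars(m) for m in rows])


def bearing_span_pct(bearings) -> int:
    """Fraction of the full degree circle covered by a set of bearings.

    ``(max - min) / 360 * 100`` rounded to the nearest integer — the summary
    used to justify treating bearing as a linear rather than circular trait.
    """
    b = np.asarray(bearings, dtype=float)
    if b.size < 2:
        raise ValueError("need at least two bearings")
    return int(round((b.max() - b.min()) / 360.0 * 100.0))


def segment_kinematics(fixes: pd.DataFrame) -> SegmentKinematics:
    """Distance, mean speed and sinuosity of an ordered fix segment.

    Sinuosity = path length / straight-line first-to-last distance (≥ 1);
    a closed segment (zero displacement) has undefined sinuosity (None).
    """
    if len(fixes) < 2:
        raise ValueError("segment needs at least two fixes")
    lon = fixes["lon"].to_numpy()
    lat = fixes["lat"].to_numpy()
    elapsed_h = (
        fixes["timestamp"].iloc[-1] - fixes["timestamp"].iloc[0]
    ).total_seconds() / 3600.0
    if elapsed_h <= 0:
        raise ValueError("segment has zero elapsed time")
    dist = cumulative_path_km(lon, lat)
    straight = great_circle_km((lon[0], lat[0]), (lon[-1], lat[-1]))
    sinuosity = dist / straight if straight > 1e-9 else None
    if sinuosity is None:
        logger.info("closed segment: sinuosity undefined")
    return SegmentKinematics(distance=dist, mean_speed=dist / elapsed_h, sinuosity=sinuosity)


def compare_phase_kinematics(per_phase: dict[str, list[SegmentKinematics]]) -> pd.DataFrame:
    """Wilcoxon rank-sum comparisons of central vs transit phase kinematics.

    ``per_phase`` maps phase name ('outbound'/'central'/'inbound') to per-trip
    kinematics. Returns one row per (variable, transit phase) with medians,
    the rank-sum p-value and the effect direction (sign of the central-minus-
    transit median difference). With fewer than two trips per group the test
    is skipped (descriptive only, p = NaN).
    """
    rows = []
    for var in ("distance", "mean_speed", "sinuosity"):
        central = np.array(
            [getattr(k, var) for k in per_phase.get("central", []) if getattr(k, var) is not None]
        )
        for other in ("outbound", "inbound"):
            vals = np.array(
                [getattr(k, var) for k in per_phase.get(other, []) if getattr(k, var) is not None]
            )
            if len(central) < 2 or len(vals) < 2:
                logger.warning("phase comparison %s vs %s: too few trips, descriptive only", var, other)
                p = np.nan
            elif np.ptp(np.concatenate([central, vals])) == 0:
                p = 1.0  # identical constant groups: no evidence of difference
            else:
                p = float(stats.ranksums(central, vals).pvalue)
            diff = float(np.median(central) - np.median(vals)) if len(central) and len(vals) else np.nan
            rows.append(
                {
                    "variable": var,
                    "transit_phase": other,
                    "median_central": float(np.median(central)) if len(central) else np.nan,
                    "median_transit": float(np.median(vals)) if len(vals) else np.nan,
                    "direction": int(np.sign(diff)) if np.isfinite(diff) and diff != 0 else 0,
                    "pvalue": p,
                }
            )
    return pd.DataFrame(rows)
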