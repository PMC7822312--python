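"""Track ingestion, cleaning, trip splitting and resampling.

Raw deployments are CSV tracks (bird id, season, UTC timestamp, lon, lat)
accompanied by nest-check logs giving the observed return time of each trip.
Cleaning follows standard biologging QC: drop malformed rows, Northern
Hemisphere fixes and duplicates, then a forward-pass speed filter at
10 km/h (penguins swim at ~2 m/s = 7.2 km/h, so faster apparent movement is
positional error). Deployments are split into colony-to-colony trips by a
colony radius; truncated recordings covering > 70% of the nest-check trip
duration are completed with a virtual colony fix, shorter ones discarded;
retained trips are resampled to a regular 20-min step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geo import great_circle_km

logger = logging.getLogger(__name__)

#: Colony reference location (lon, lat): Pointe Géologie archipelago, Terre Adélie.
COLONY_LONLAT = (140.01, -66.66)

FIX_COLUMNS = ["timestamp", "lon", "lat"]


@dataclass(frozen=True)
class QcParams:
    """Cleaning / splitting / resampling parameters.

    speed_threshold : km/h, forward-pass speed filter cutoff (default 10).
    resample_step : minutes, regular resampling step (default 20).
    min_recorded_fraction : retain truncated trips only if strictly more than
        this fraction of the nest-check trip duration was recorded (default 0.70).
    colony_radius : km, fixes within this distance of the colony count as
        "at the colony" for trip splitting (default 0.2).
    colony : (lon, lat) of the colony.
    """

    speed_threshold: float = 10.0
    resample_step: float = 20.0
    min_recorded_fraction: float = 0.70
    colony_radius: float = 0.2
    colony: tuple[float, float] = COLONY_LONLAT

    def __post_init__(self):
        if self.speed_threshold <= 0 or self.resample_step <= 0 or self.colony_radius <= 0:
            raise ValueError("QcParams values must be strictly positive")
        if not 0.0 < self.min_recorded_fraction < 1.0:
            raise ValueError("min_recorded_fraction must be in (0, 1)")


@dataclass
class Deployment:
    """One bird-season of raw or cleaned fixes plus its nest-check returns."""

    bird_id: str
    season: str
    fixes: pd.DataFrame
    nest_checks: dict[int, pd.Timestamp] = field(default_factory=dict)


@dataclass
class Trip:
    """One colony-to-colony excursion after QC."""

    bird_id: str
    season: str
    trip_index: int
    fixes: pd.DataFrame
    departure: pd.Timestamp
    return_time: pd.Timestamp | None
    completed_virtually: bool = False
    recorded_fraction: float = 1.0
    resample_flagged: bool = False

    @property
    def duration_hours(self) -> float:
        if self.return_time is None:
            raise ValueError("trip has no return time yet")
        return (self.return_time - self.departure).total_seconds() / 3600.0


def _parse_fix_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    ok = (
        ts.notna()
        & lon.between(-180.0, 180.0)
        & lat.between(-90.0, 90.0)
        & lon.notna()
        & lat.notna()
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d malformed row(s)", source, n_bad)
    out = pd.DataFrame({"timestamp": ts[ok], "lon": lon[ok], "lat": lat[ok]})
    return out.reset_index(drop=True)


def read_tracks(path: str | Path) -> list[Deployment]:
    """Read a track CSV (columns bird_id, season, timestamp, lon, lat).

    Returns one :class:`Deployment` per (bird_id, season), rows in file order.
    Malformed rows (unparseable timestamp, out-of-range coordinates) are
    dropped with a logged warning; an empty file is an error.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype={"bird_id": str, "season": str})
    if raw.empty:
        raise ValueError(f"{path}: no track rows")
    missing = {"bird_id", "season", *FIX_COLUMNS} - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    deployments = []
    for (bird, season), grp in raw.groupby(["bird_id", "season"], sort=False):
        fixes = _parse_fix_frame(grp, f"{path}:{bird}/{season}")
        deployments.append(Deployment(bird_id=bird, season=season, fixes=fixes))
    return deployments


def deployments_from_frame(
    tracks: pd.DataFrame, nest_checks: pd.DataFrame | None = None
) -> list[Deployment]:
    """Build Deployments from in-memory track (and optional nest-check) frames."""
    checks: dict[tuple[str, str], dict[int, pd.Timestamp]] = {}
    if nest_checks is not None:
        nc = nest_checks.copy()
        nc["observed_return"] = pd.to_datetime(nc["observed_return"], utc=True)
        for row in nc.itertuples(index=False):
            checks.setdefault((row.bird_id, row.season), {})[int(row.trip_index)] = row.observed_return
    deployments = []
    for (bird, season), grp in tracks.groupby(["bird_id", "season"], sort=False):
        fixes = _parse_fix_frame(grp, f"{bird}/{season}")
        deployments.append(
            Deployment(bird_id=bird, season=season, fixes=fixes, nest_checks=checks.get((bird, season), {}))
        )
    return deployments


def qc_cohort(
    tracks: pd.DataFrame,
    nest_checks: pd.DataFrame | None = None,
    p: QcParams | None = None,
    resample: bool = True,
) -> list[Trip]:
    """QC every deployment of a cohort frame; returns all retained trips."""
    trips: list[Trip] = []
    for dep in deployments_from_frame(tracks, nest_checks):
        trips.extend(qc_deployment(dep, p, resample=resample))
    return trips


def read_nest_checks(path: str | Path) -> dict[tuple[str, str], dict[int, pd.Timestamp]]:
    """Read a nest-check CSV (bird_id, season, trip_index, observed_return)."""
    raw = pd.read_csv(path, dtype={"bird_id": str, "season": str})
    raw["observed_return"] = pd.to_datetime(raw["observed_return"], utc=True)
    out: dict[tuple[str, str], dict[int, pd.Timestamp]] = {}
    for row in raw.itertuples(index=False):
        out.setdefault((row.bird_id, row.season), {})[int(row.trip_index)] = row.observed_return
    return out


def clean_fixes(dep: Deployment, p: QcParams) -> Deployment:
    """Apply the deployment-level cleaning rules.

    Removes fixes with missing timestamps or in the Northern Hemisphere,
    exact (timestamp, lon, lat) duplicates, same-timestamp conflicts (first
    kept, logged), then a forward speed filter: iterating in time order, a
    fix is dropped when the great-circle speed from the last *retained* fix
    exceeds ``p.speed_threshold``.
    """
    f = dep.fixes
    if f.empty:
        raise ValueError(f"{dep.bird_id}/{dep.season}: deployment has no fixes")
    f = f[f["timestamp"].notna() & (f["lat"] <= 0.0)]
    f = f.drop_duplicates(subset=FIX_COLUMNS)
    f = f.sort_values("timestamp", kind="stable").reset_index(drop=True)
    dup_t = f["timestamp"].duplicated(keep="first")
    if dup_t.any():
        logger.warning(
            "%s/%s: %d fixes share a timestamp with differing positions; kept first",
            dep.bird_id,
            dep.season,
            int(dup_t.sum()),
        )
        f = f[~dup_t].reset_index(drop=True)
    if f.empty:
        raise ValueError(f"{dep.bird_id}/{dep.season}: deployment fully filtered")

    t = f["timestamp"].astype("int64").to_numpy() / 1e9
    pts = f[["lon", "lat"]].to_numpy()
    keep = np.zeros(len(f), dtype=bool)
    keep[0] = True
    last = 0
    for i in range(1, len(f)):
        dt_h = (t[i] - t[last]) / 3600.0
        if dt_h <= 0:
            continue
        speed = great_circle_km(pts[last], pts[i]) / dt_h
        if speed <= p.speed_threshold:
            keep[i] = True
            last = i
    f = f[keep].reset_index(drop=True)
    if f.empty:
        raise ValueError(f"{dep.bird_id}/{dep.season}: deployment fully filtered")
    return replace(dep, fixes=f)


def split_trips(dep: Deployment, p: QcParams) -> list[Trip]:
    """Partition a cleaned deployment into colony-to-colony trips.

    Maximal runs of fixes outside ``colony_radius`` become trips; each run is
    bracketed by the last at-colony fix before it (departure) and the first
    at-colony fix after it (return). A run that reaches the end of the record
    without returning is kept as an open trip (``return_time=None``) for
    virtual completion against the nest checks.
    """
    f = dep.fixes
    d_col = great_circle_km(np.array(p.colony), f[["lon", "lat"]].to_numpy())
    outside = np.atleast_1d(d_col) > p.colony_radius
    if not outside.any():
        logger.info("%s/%s: no fix ever leaves the colony radius", dep.bird_id, dep.season)
        return []

    trips: list[Trip] = []
    n = len(f)
    i = 0
    idx = 1
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j < n and outside[j]:
            j += 1
        start = i - 1 if i > 0 and not outside[i - 1] else i
        stop = j if j < n else n - 1  # index of first-inside fix, if any
        seg = f.iloc[start : stop + 1].reset_index(drop=True)
        returned = j < n
        trips.append(
            Trip(
                bird_id=dep.bird_id,
                season=dep.season,
                trip_index=idx,
                fixes=seg,
                departure=seg["timestamp"].iloc[0],
                return_time=seg["timestamp"].iloc[-1] if returned else None,
            )
        )
        idx += 1
        i = j
    return trips


def complete_or_discard(t: Trip, observed_return: pd.Timestamp | None, p: QcParams) -> Trip | None:
    """Resolve a possibly truncated trip against its nest-check return time.

    A trip that already closed at the colony is returned unchanged. An open
    trip is completed with a virtual colony fix at ``observed_return`` when
    strictly more than ``min_recorded_fraction`` of the nest-check duration
    was recorded; otherwise ``None`` (discarded).
    """
    if t.return_time is not None:
        t.recorded_fraction = 1.0
        return t
    if observed_return is None:
        logger.warning("%s trip %d: open trip with no nest check; discarded", t.bird_id, t.trip_index)
        return None
    if observed_return < t.departure:
        raise ValueError("observed return precedes trip departure")
    total = (observed_return - t.departure).total_seconds()
    if total <= 0:
        raise ValueError("nest-check duration is zero")
    recorded = (t.fixes["timestamp"].iloc[-1] - t.departure).total_seconds()
    frac = recorded / total
    if frac <= p.min_recorded_fraction:
        logger.info(
            "%s trip %d: only %.0f%% of trip recorded; discarded", t.bird_id, t.trip_index, 100 * frac
        )
        return None
    virtual = pd.DataFrame(
        {"timestamp": [observed_return], "lon": [p.colony[0]], "lat": [p.colony[1]]}
    )
    t.fixes = pd.concat([t.fixes, virtual], ignore_index=True)
    t.return_time = observed_return
    t.completed_virtually = True
    t.recorded_fraction = frac
    return t


def resample_trip(t: Trip, p: QcParams) -> Trip:
    """Resample a closed trip onto a regular time grid.

    Fix times become departure + k·step; lon/lat are interpolated linearly in
    time between the bracketing original fixes. The grid never extends past
    the return time. Trips shorter than one step keep their two endpoint
    fixes and are flagged.
    """
    if t.return_time is None:
        raise ValueError("resample requires a closed trip")
    if len(t.fixes) < 2:
        raise ValueError("resample requires at least two fixes")
    step_s = p.resample_step * 60.0
    ts = t.fixes["timestamp"].astype("int64").to_numpy() / 1e9
    t0, t1 = ts[0], ts[-1]
    n_steps = int(np.floor((t1 - t0) / step_s + 1e-9))
    if n_steps < 1:
        logger.info("%s trip %d shorter than one resampling step", t.bird_id, t.trip_index)
        return replace(t, resample_flagged=True)
    grid = t0 + step_s * np.arange(n_steps + 1)
    lon = np.interp(grid, ts, t.fixes["lon"].to_numpy())
    lat = np.interp(grid, ts, t.fixes["lat"].to_numpy())
    fixes = pd.DataFrame(
        {
            "timestamp": pd.to_datetime((grid * 1e9).astype("int64"), utc=True),
            "lon": lon,
            "lat": lat,
        }
    )
    return replace(t, fixes=fixes)


@dataclass
class CohortSummary:
    """Per-season bookkeeping of individuals and trips."""

    table: pd.DataFrame  # index: n_trips per bird; columns: seasons + "Total"
    n_individuals: int
    n_trips: int
    mean_trips_per_bird: float
    sd_trips_per_bird: float


def summarize_cohort(trips: Sequence[Trip] | pd.DataFrame) -> CohortSummary:
    """Tabulate individuals by trip count per season, with totals.

    Accepts retained :class:`Trip` objects or a DataFrame with columns
    bird_id, season, trip_index.
    """
    if isinstance(trips, pd.DataFrame):
        meta = trips[["bird_id", "season"]].copy()
    else:
        meta = pd.DataFrame({"bird_id": [t.bird_id for t in trips], "season": [t.season for t in trips]})
    if meta.empty:
        raise ValueError("no retained trips to summarize")
    per_bird = meta.groupby(["season", "bird_id"]).size().rename("n_trips").reset_index()
    table = (
        per_bird.groupby(["n_trips", "season"]).size().unstack(fill_value=0).sort_index()
    )
    table["Total"] = table.sum(axis=1)
    counts = per_bird["n_trips"]
    return CohortSummary(
        table=table,
        n_individuals=int(len(per_bird)),
        n_trips=int(len(meta)),
        mean_trips_per_bird=float(counts.mean()),
        sd_trips_per_bird=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
    )


def trips_to_frames(trips: Sequence[Trip]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize trips to (fix-level, trip-metadata) frames for CSV export."""
    fix_frames, meta = [], []
    for t in trips:
        f = t.fixes.copy()
        f.insert(0, "bird_id", t.bird_id)
        f.insert(1, "season", t.season)
        f.insert(2, "trip_index", t.trip_index)
        fix_frames.append(f)
        meta.append(
            {
                "bird_id": t.bird_id,
                "season": t.season,
                "trip_index": t.trip_index,
                "departure": t.departure,
                "return_time": t.return_time,
                "completed_virtually": t.completed_virtually,
                "recorded_fraction": t.recorded_fraction,
            }
        )
    return pd.concat(fix_frames, ignore_index=True), pd.DataFrame(meta)


def trips_from_frames(fixes: pd.DataFrame, meta: pd.DataFrame) -> list[Trip]:
    """Inverse of :func:`trips_to_frames`."""
    fixes = fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
    grouped = {k: g[FIX_COLUMNS].reset_index(drop=True) for k, g in fixes.groupby(["bird_id", "season", "trip_index"])}
    trips = []
    for row in meta.itertuples(index=False):
        key = (row.bird_id, row.season, row.trip_index)
        trips.append(
            Trip(
                bird_id=row.bird_id,
                season=row.season,
                trip_index=int(row.trip_index),
                fixes=grouped[key],
                departure=pd.to_datetime(row.departure, utc=True),
                return_time=pd.to_datetime(row.return_time, utc=True),
                completed_virtually=bool(row.completed_virtually),
                recorded_fraction=float(row.recorded_fraction),
            )
        )
    return trips


def qc_deployment(
    dep: Deployment, p: QcParams | None = None, resample: bool = True
) -> list[Trip]:
    """Full QC for one deployment: clean, split, complete/discard, resample.

    Retained trips keep their chronological ``trip_index`` from splitting, so
    a discarded trip leaves a gap — downstream trip-pairing relies on this to
    avoid pairing across a discarded excursion.
    """
    p = p or QcParams()
    cleaned = clean_fixes(dep, p)
    kept: list[Trip] = []
    for t in split_trips(cleaned, p):
        resolved = complete_or_discard(t, dep.nest_checks.get(t.trip_index), p)
        if resolved is None:
            continue
        if resample:
            resolved = resample_trip(resolved, p)
        kept.append(resolved)
    return kept
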