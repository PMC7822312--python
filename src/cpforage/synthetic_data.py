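"""Synthetic central-place-foraging study generator.

Emits everything the pipeline consumes — multi-trip GPS tracks with a known
three-phase structure, nest-check return times, per-season peak hatching
dates and daily sea-ice fields with within-season recession — together with
a truth table for every upstream estimator (true phase fractions, true
foraging-patch centers, true between/within variances and hence the true
repeatability per trait).

A trip is built in a local tangent plane around the colony: an outbound
transit to a foraging patch at transit speed with small lateral jitter, a
slow, tortuous random walk at the patch for the central fraction of the
trip, and an inbound transit home. Per-bird traits (log patch distance,
heading) are drawn from normal population distributions with configurable
between- and within-individual standard deviations, so the realized
repeatability of the derived effort metrics is known by construction.
``fidelity_mode='faithful'`` keeps one patch per bird (low NND between
consecutive trips); ``'explorer'`` draws a fresh patch every trip.

Defaults mirror the Terre Adélie chick-rearing study: 129 birds spread over
six seasons with the observed distribution of 2-9 trips per bird, phase
fractions near 30/70% of trip duration, a 6.25 km ice grid over 64-67 S,
137-143 E receding through the season.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date as Date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import from_local_km
from .io_qc import COLONY_LONLAT
from .seaice import IceField

#: Table-1-style distribution of trips per bird (counts over 129 birds).
TRIPS_PER_BIRD_DIST = {2: 76, 3: 21, 4: 12, 5: 11, 6: 1, 7: 2, 8: 3, 9: 3}
#: Individuals per season in the reference cohort.
SEASON_WEIGHTS = {
    "2010-11": 17, "2011-12": 7, "2014-15": 11, "2015-16": 73, "2016-17": 2, "2017-18": 19,
}
#: Peak hatching dates (median date by which half the first eggs hatched).
PEAK_HATCH = {
    "2010-11": Date(2010, 12, 20), "2011-12": Date(2011, 12, 22),
    "2014-15": Date(2014, 12, 19), "2015-16": Date(2015, 12, 21),
    "2016-17": Date(2016, 12, 23), "2017-18": Date(2017, 12, 20),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-generator configuration; defaults are the reference conditions."""

    n_birds: int = 129
    trips_per_bird: dict[int, int] = field(default_factory=lambda: dict(TRIPS_PER_BIRD_DIST))
    seasons: dict[str, int] = field(default_factory=lambda: dict(SEASON_WEIGHTS))
    phase_fractions_true: tuple[float, float] = (30.0, 70.0)
    # per-bird trait population: log patch distance (km) and heading (deg)
    log_dmax_mean: float = np.log(20.0)
    log_dmax_between_sd: float = 0.35
    log_dmax_within_sd: float = 0.45
    heading_mean: float = 10.0
    heading_between_sd: float = 25.0
    heading_within_sd: float = 30.0
    step_minutes: float = 5.0
    transit_speed: float = 5.0  # km/h
    forage_speed: float = 1.5  # km/h
    transit_jitter_km: float = 0.08  # lateral positional noise during transits
    forage_turn_rho: float = 0.3  # turning-angle autocorrelation at the patch
    colony_dwell_hours: float = 6.0
    fidelity_mode: str = "faithful"  # or "explorer"
    # explorers prospect a fresh patch anywhere in the accessible arc each
    # trip; the default arc is the observed population bearing range
    explorer_heading_range: tuple[float, float] = (-72.0, 88.0)
    truncation_prob: float = 0.15
    truncation_fraction: tuple[float, float] = (0.5, 0.95)
    # ice field: latitudinal gradient, daily recession, smooth noise
    # grid margins extend past the 64-67 S / 137-143 E study box so every
    # simulated fix has a containing cell
    ice_lat_south: float = -68.0
    ice_lat_north: float = -64.0
    ice_lon_west: float = 136.0
    ice_lon_east: float = 144.0
    ice_cell_km: float = 6.25
    ice_south_concentration: float = 80.0  # % at the southern (coastal) edge, day 0
    ice_north_concentration: float = 5.0  # % at the northern edge, day 0
    ice_recession_per_day: float = 0.01
    ice_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        f1, f2 = self.phase_fractions_true
        if not 0.0 < f1 < f2 < 100.0:
            raise ValueError("phase fractions must satisfy 0 < f1 < f2 < 100")
        if min(self.log_dmax_between_sd, self.log_dmax_within_sd,
               self.heading_between_sd, self.heading_within_sd) < 0:
            raise ValueError("trait standard deviations must be >= 0")
        if not 0.0 <= self.truncation_prob <= 1.0:
            raise ValueError("truncation_prob must be in [0, 1]")
        if self.fidelity_mode not in ("faithful", "explorer"):
            raise ValueError("fidelity_mode must be 'faithful' or 'explorer'")


def true_repeatability(between_sd: float, within_sd: float) -> float:
    """R implied by the generator's variance decomposition."""
    tot = between_sd**2 + within_sd**2
    if tot == 0:
        raise ValueError("degenerate traits: both variances zero")
    return between_sd**2 / tot


@dataclass
class CohortSim:
    """Generator output: pipeline inputs plus the truth table."""

    tracks: pd.DataFrame  # bird_id, season, timestamp, lon, lat
    nest_checks: pd.DataFrame  # bird_id, season, trip_index, observed_return
    peak_hatch: dict[str, Date]
    bird_truth: pd.DataFrame  # per-bird true traits and patch centers
    trip_truth: pd.DataFrame  # per-trip true boundaries, patch, truncation
    true_R: dict[str, float]
    config: SimConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tracks.to_csv(out / "tracks.csv", index=False)
        self.nest_checks.to_csv(out / "nest_checks.csv", index=False)
        pd.DataFrame(
            {"season": list(self.peak_hatch), "peak_hatch": [str(d) for d in self.peak_hatch.values()]}
        ).to_csv(out / "peak_hatch.csv", index=False)
        self.bird_truth.to_csv(out / "truth_birds.csv", index=False)
        self.trip_truth.to_csv(out / "truth_trips.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump({"true_R": self.true_R, "config": _config_dict(self.config)}, fh, indent=1)


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["trips_per_bird"] = {str(k): v for k, v in d["trips_per_bird"].items()}
    return d


def _walk_trip(rng, cfg: SimConfig, patch_xy: np.ndarray, t_dep: pd.Timestamp):
    """One trip's fixes (timestamps, x, y in km) with its true boundaries."""
    f1, f2 = cfg.phase_fractions_true
    d = float(np.hypot(*patch_xy))
    t_out_h = d / cfg.transit_speed
    total_h = t_out_h / (f1 / 100.0)
    if total_h * (100.0 - f2) / 100.0 * cfg.transit_speed < d * 0.999:
        raise ValueError("infeasible geometry: patch unreachable on the inbound leg")
    dt_h = cfg.step_minutes / 60.0
    n_steps = max(int(np.floor(total_h / dt_h)), 8)
    # regular grid plus an exact on-colony return fix
    times_h = np.append(dt_h * np.arange(n_steps + 1), total_h)
    if times_h[-1] - times_h[-2] < dt_h / 4.0:
        times_h = np.delete(times_h, -2)
    n_steps = len(times_h) - 1
    t1_h, t2_h = total_h * f1 / 100.0, total_h * f2 / 100.0

    xy = np.zeros((n_steps + 1, 2))
    out_mask = times_h <= t1_h
    in_mask = times_h >= t2_h
    mid_mask = ~(out_mask | in_mask)
    # transits: linear colony<->patch plus lateral jitter
    frac_out = times_h[out_mask] / t1_h
    xy[out_mask] = frac_out[:, None] * patch_xy
    frac_in = (times_h[in_mask] - t2_h) / (total_h - t2_h)
    xy[in_mask] = (1.0 - frac_in[:, None]) * patch_xy
    jitter = rng.normal(0.0, cfg.transit_jitter_km, size=(n_steps + 1, 2))
    jitter[0] = jitter[-1] = 0.0
    # taper path wobble near the colony so departures/returns cross the
    # colony radius exactly once
    taper = np.minimum(np.hypot(xy[:, 0], xy[:, 1]) / 1.0, 1.0)
    xy[out_mask | in_mask] += (jitter * taper[:, None])[out_mask | in_mask]
    # central phase: slow correlated random walk around the patch
    n_mid = int(mid_mask.sum())
    if n_mid:
        step_len = cfg.forage_speed * dt_h
        ang = rng.uniform(-np.pi, np.pi)
        pos = patch_xy.astype(float).copy()
        pts = []
        for _ in range(n_mid):
            ang = cfg.forage_turn_rho * ang + rng.uniform(-np.pi, np.pi) * (1 - cfg.forage_turn_rho)
            # weak pull back toward the patch keeps the walk in a bounded patch
            pull = 0.05 * (patch_xy - pos)
            pos = pos + step_len * np.array([np.sin(ang), np.cos(ang)]) + pull
            pts.append(pos.copy())
        xy[mid_mask] = np.array(pts)
    ts = t_dep + pd.to_timedelta(times_h, unit="h")
    t_ret = t_dep + pd.to_timedelta(total_h, unit="h")
    bounds = (t_dep + pd.to_timedelta(t1_h, unit="h"), t_dep + pd.to_timedelta(t2_h, unit="h"))
    return ts, xy, t_ret, bounds


def simulate_cohort(cfg: SimConfig | None = None, seed: int | None = None) -> CohortSim:
    """Generate the full synthetic study; reproducible from the seed."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    colony_lon, colony_lat = COLONY_LONLAT

    season_names = list(cfg.seasons)
    season_p = np.array([cfg.seasons[s] for s in season_names], dtype=float)
    season_p /= season_p.sum()
    trip_counts = np.array(list(cfg.trips_per_bird), dtype=int)
    trip_p = np.array([cfg.trips_per_bird[k] for k in trip_counts], dtype=float)
    trip_p /= trip_p.sum()

    track_rows, check_rows, bird_rows, trip_rows = [], [], [], []
    for b in range(cfg.n_birds):
        bird = f"bird{b:03d}"
        season = rng.choice(season_names, p=season_p)
        n_trips = int(rng.choice(trip_counts, p=trip_p))
        log_d_i = rng.normal(cfg.log_dmax_mean, cfg.log_dmax_between_sd)
        head_i = rng.normal(cfg.heading_mean, cfg.heading_between_sd)
        ph = PEAK_HATCH.get(season, Date(2015, 12, 21))
        start = pd.Timestamp(str(ph), tz="UTC") + pd.to_timedelta(
            rng.uniform(-3.0, 12.0) * 24.0, unit="h"
        )
        t_cursor = start
        for k in range(1, n_trips + 1):
            # realized per-trip trait: anchored to the bird in faithful mode,
            # drawn from the whole population (no individual signal) for
            # explorers — so the configured variance decomposition is what
            # the trips actually express
            if cfg.fidelity_mode == "faithful":
                log_d = log_d_i + rng.normal(0.0, cfg.log_dmax_within_sd)
                head = head_i + rng.normal(0.0, cfg.heading_within_sd)
            else:
                log_d = rng.normal(
                    cfg.log_dmax_mean,
                    np.hypot(cfg.log_dmax_between_sd, cfg.log_dmax_within_sd),
                )
                head = rng.uniform(*cfg.explorer_heading_range)
            d = float(np.clip(np.exp(log_d), 2.0, 120.0))
            theta = np.radians(head)
            patch = d * np.array([np.sin(theta), np.cos(theta)])  # x east, y north
            # colony dwell fixes before departure
            dwell_n = max(int(cfg.colony_dwell_hours), 1)
            for h in range(dwell_n, 0, -1):
                # offset by 30 min so dwell fixes never collide with the
                # previous trip's return fix
                ts = t_cursor - pd.to_timedelta(h, unit="h") + pd.to_timedelta(30, unit="m")
                jx, jy = rng.normal(0.0, 0.03, size=2)
                lon, lat = from_local_km(jx, jy, colony_lon, colony_lat)
                track_rows.append((bird, season, ts, float(lon), float(lat)))
            ts, xy, t_ret, (b1, b2) = _walk_trip(rng, cfg, patch, t_cursor)
            # a truncated recording = the logger died at sea: nothing is
            # recorded afterwards, so the deployment ends with this trip
            truncated = rng.random() < cfg.truncation_prob
            if truncated:
                frac = rng.uniform(*cfg.truncation_fraction)
                cutoff = t_cursor + frac * (t_ret - t_cursor)
                keep = ts <= cutoff
            else:
                keep = np.ones(len(ts), dtype=bool)
            lon, lat = from_local_km(xy[:, 0], xy[:, 1], colony_lon, colony_lat)
            for t, lo, la in zip(ts[keep], lon[keep], lat[keep]):
                track_rows.append((bird, season, t, float(lo), float(la)))
            check_rows.append((bird, season, k, t_ret))
            trip_rows.append(
                {
                    "bird_id": bird, "season": season, "trip_index": k,
                    "departure": t_cursor, "return": t_ret,
                    "phase1_end": b1, "phase2_end": b2,
                    "patch_x_km": patch[0], "patch_y_km": patch[1],
                    "true_max_distance_km": d, "true_heading_deg": head,
                    "truncated": truncated,
                }
            )
            if truncated:
                break
            t_cursor = t_ret + pd.to_timedelta(cfg.colony_dwell_hours, unit="h")
        bird_rows.append(
            {
                "bird_id": bird, "season": season, "n_trips": n_trips,
                "true_log_dmax": log_d_i, "true_heading": head_i,
            }
        )

    tracks = pd.DataFrame(track_rows, columns=["bird_id", "season", "timestamp", "lon", "lat"])
    checks = pd.DataFrame(check_rows, columns=["bird_id", "season", "trip_index", "observed_return"])
    if cfg.fidelity_mode == "faithful":
        true_R = {
            "log_max_distance": true_repeatability(cfg.log_dmax_between_sd, cfg.log_dmax_within_sd),
            "heading": true_repeatability(cfg.heading_between_sd, cfg.heading_within_sd),
        }
    else:  # explorers carry no individual signal
        true_R = {"log_max_distance": 0.0, "heading": 0.0}
    return CohortSim(
        tracks=tracks,
        nest_checks=checks,
        peak_hatch={s: PEAK_HATCH.get(s, Date(2015, 12, 21)) for s in season_names},
        bird_truth=pd.DataFrame(bird_rows),
        trip_truth=pd.DataFrame(trip_rows),
        true_R=true_R,
        config=cfg,
    )


def simulate_icefields(
    cfg: SimConfig | None = None, dates: list[Date] | None = None, seed: int | None = None
) -> dict[Date, IceField]:
    """Daily concentration fields: latitudinal gradient, recession, smooth noise.

    Day 0 is a south-to-north gradient plus smooth noise; each later day is
    the previous scaled by (1 - recession rate) plus noise, clipped to
    [0, 100]. The colony cell is masked (land).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng((cfg.seed + 1) if seed is None else seed)
    if dates is None:
        d0 = Date(2015, 12, 15)
        dates = [d0 + timedelta(days=i) for i in range(30)]
    dates = sorted(dates)
    dlat = cfg.ice_cell_km / 111.195
    dlon = dlat / np.cos(np.radians((cfg.ice_lat_south + cfg.ice_lat_north) / 2.0))
    lat = np.arange(cfg.ice_lat_south + dlat / 2.0, cfg.ice_lat_north, dlat)
    lon = np.arange(cfg.ice_lon_west + dlon / 2.0, cfg.ice_lon_east, dlon)

    # south (coastal) edge iciest, receding northward through the season
    frac = (lat - cfg.ice_lat_south) / (cfg.ice_lat_north - cfg.ice_lat_south)
    base = cfg.ice_south_concentration + frac * (
        cfg.ice_north_concentration - cfg.ice_south_concentration
    )
    grid = np.tile(base[:, None], (1, lon.size))

    def smooth_noise():
        if cfg.ice_noise_sd == 0:
            return 0.0
        coarse = rng.normal(0.0, cfg.ice_noise_sd, size=(max(lat.size // 8, 2), max(lon.size // 8, 2)))
        ii = np.linspace(0, coarse.shape[0] - 1, lat.size)
        jj = np.linspace(0, coarse.shape[1] - 1, lon.size)
        from scipy.ndimage import map_coordinates

        return map_coordinates(coarse, np.meshgrid(ii, jj, indexing="ij"), order=1)

    colony_i = int(np.clip(np.searchsorted(lon, COLONY_LONLAT[0]), 0, lon.size - 1))
    colony_j = int(np.clip(np.searchsorted(lat, COLONY_LONLAT[1]), 0, lat.size - 1))

    fields: dict[Date, IceField] = {}
    cur = np.clip(grid + smooth_noise(), 0.0, 100.0)
    for i, d in enumerate(dates):
        if i > 0:
            cur = np.clip(cur * (1.0 - cfg.ice_recession_per_day) + smooth_noise() * 0.2, 0.0, 100.0)
        g = cur.copy()
        g[colony_j, colony_i] = np.nan  # land
        fields[d] = IceField(date=d, cell_km=cfg.ice_cell_km, lon=lon, lat=lat, grid=g)
    return fields


def simulate_trait_data(
    n_birds: int,
    trips_per_bird: int,
    between_sd: float,
    within_sd: float,
    mean: float = 0.0,
    seasons: list[str] | None = None,
    season_effects: dict[str, float] | None = None,
    timing_slope: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trait-level simulation for variance-component recovery studies.

    Draws y_ij = mean + season effect + timing slope * t_ij + a_i + e_ij with
    a_i ~ N(0, between_sd^2), e_ij ~ N(0, within_sd^2); one row per trip with
    bird_id, season, days_since_peak_hatch and the response ``trait``.
    """
    rng = np.random.default_rng(seed)
    seasons = seasons or ["S1"]
    bird_season = rng.choice(seasons, size=n_birds)
    a = rng.normal(0.0, between_sd, size=n_birds)
    rows = []
    for i in range(n_birds):
        s = bird_season[i]
        shift = (season_effects or {}).get(s, 0.0)
        for j in range(trips_per_bird):
            t = rng.uniform(0.0, 20.0)
            y = mean + shift + timing_slope * t + a[i] + rng.normal(0.0, within_sd)
            rows.append(
                {
                    "bird_id": f"bird{i:03d}",
                    "season": s,
                    "trip_index": j + 1,
                    "days_since_peak_hatch": t,
                    "trait": y,
                }
            )
    return pd.DataFrame(rows)
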