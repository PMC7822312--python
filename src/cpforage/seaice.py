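"""Daily sea-ice concentration fields and trip-level ice covariates.

Fields are daily gridded percent concentrations (0-100) on regular lon/lat
grids at a nominal 6.25 or 12.5 km cell size, stored as NetCDF (variables
``sic(time, lat, lon)``). Extraction follows the analysis conventions:
a GPS fix takes the value of its containing cell (no interpolation, west
and south cell edges inclusive); regional means average unmasked cell
centers inside a polygon, then average over the days of a trip window.

Two spatial scales condition the analyses: the fixed whole study area
(64-67 S, 137-143 E) and the annually prospected area, the convex hull of
all retained fixes of a season. For a pair of consecutive trips the ice
covariates are the mean concentration in the prospected area over the two
trips' combined date span and the first-minus-second trip difference
(positive = ice receded between trips).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import shapely
from shapely.geometry import MultiPoint, Polygon, box

from .geo import laea_xy_km
from .io_qc import Trip

logger = logging.getLogger(__name__)


@dataclass
class IceField:
    """One day's concentration grid: regular lon/lat cell centers, NaN = masked."""

    date: Date
    cell_km: float
    lon: np.ndarray  # 1-D cell-center longitudes, ascending
    lat: np.ndarray  # 1-D cell-center latitudes, ascending
    grid: np.ndarray  # (lat, lon) percent concentrations in [0, 100], NaN masked

    @property
    def dlon(self) -> float:
        return float(self.lon[1] - self.lon[0])

    @property
    def dlat(self) -> float:
        return float(self.lat[1] - self.lat[0])


@dataclass(frozen=True)
class StudyRegion:
    """Spatial averaging region: fixed study area or annual prospected hull."""

    kind: str  # "whole_study_area" | "annual_prospected_area"
    polygon: Polygon
    season: str | None = None
    area_km2: float | None = None


#: The fixed regional scale: 64-67 S, 137-143 E.
WHOLE_STUDY_AREA = StudyRegion(kind="whole_study_area", polygon=box(137.0, -67.0, 143.0, -64.0))


@dataclass(frozen=True)
class TripPairIce:
    mean_sic_pair: float  # % over the combined date span, prospected area
    sic_difference: float  # % mean(trip n) - mean(trip n+1); positive = receded


def _field_from_dataset(ds: xr.Dataset, cell_km: float | None) -> list[IceField]:
    lon = np.asarray(ds["lon"].values, dtype=float)
    lat = np.asarray(ds["lat"].values, dtype=float)
    if cell_km is None:
        cell_km = float(ds.attrs.get("cell_km", 6.25))
    fields = []
    for i, t in enumerate(pd.to_datetime(ds["time"].values)):
        grid = np.asarray(ds["sic"].isel(time=i).values, dtype=float)
        bad = (grid < 0.0) | (grid > 100.0)
        if np.any(bad & np.isfinite(grid)):
            logger.warning("%s: %d out-of-range concentration(s) masked", t.date(), int(bad.sum()))
            grid = np.where(bad, np.nan, grid)
        fields.append(IceField(date=t.date(), cell_km=cell_km, lon=lon, lat=lat, grid=grid))
    return fields


def load_icefields(
    path: str | Path, date_range: tuple[Date, Date] | None = None, cell_km: float | None = None
) -> dict[Date, IceField]:
    """Load daily fields from a NetCDF file (or directory of files).

    Returns fields keyed by date; out-of-range values are masked with a
    warning and gaps in the date sequence are logged.
    """
    path = Path(path)
    paths = sorted(path.glob("*.nc")) if path.is_dir() else [path]
    if not paths:
        raise ValueError(f"no NetCDF files under {path}")
    fields: dict[Date, IceField] = {}
    for p in paths:
        with xr.open_dataset(p) as ds:
            for f in _field_from_dataset(ds.load(), cell_km):
                fields[f.date] = f
    if date_range is not None:
        d0, d1 = date_range
        fields = {d: f for d, f in fields.items() if d0 <= d <= d1}
    days = sorted(fields)
    if days:
        expected = {days[0] + timedelta(days=i) for i in range((days[-1] - days[0]).days + 1)}
        gaps = sorted(expected - set(days))
        if gaps:
            logger.warning("ice field gaps: %s", ", ".join(str(d) for d in gaps))
    return fields


def write_icefields(fields: dict[Date, IceField], path: str | Path) -> None:
    """Write daily fields to one NetCDF file (inverse of :func:`load_icefields`)."""
    days = sorted(fields)
    first = fields[days[0]]
    grid = np.stack([fields[d].grid for d in days])
    ds = xr.Dataset(
        {"sic": (("time", "lat", "lon"), grid)},
        coords={
            "time": pd.to_datetime([str(d) for d in days]),
            "lat": first.lat,
            "lon": first.lon,
        },
        attrs={"cell_km": first.cell_km},
    )
    ds.to_netcdf(path)


def regrid_to_fine(coarse: IceField, factor: int = 2) -> IceField:
    """Nearest-neighbour refinement: each coarse cell becomes a factor^2 block.

    Values are unchanged; fine cell centers subdivide each coarse cell, so
    sampling the fine field anywhere equals sampling the coarse field.
    """
    dlon, dlat = coarse.dlon / factor, coarse.dlat / factor
    lon0 = coarse.lon[0] - coarse.dlon / 2.0 + dlon / 2.0
    lat0 = coarse.lat[0] - coarse.dlat / 2.0 + dlat / 2.0
    lon = lon0 + dlon * np.arange(coarse.lon.size * factor)
    lat = lat0 + dlat * np.arange(coarse.lat.size * factor)
    grid = np.kron(coarse.grid, np.ones((factor, factor)))
    return IceField(
        date=coarse.date, cell_km=coarse.cell_km / factor, lon=lon, lat=lat, grid=grid
    )


def sample_at(f: IceField, lon, lat):
    """Concentration of the containing cell (west/south edges inclusive).

    Vectorized; points outside the grid extent return NaN with a warning.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    i = np.floor((lon - (f.lon[0] - f.dlon / 2.0)) / f.dlon).astype(int)
    j = np.floor((lat - (f.lat[0] - f.dlat / 2.0)) / f.dlat).astype(int)
    ok = (i >= 0) & (i < f.lon.size) & (j >= 0) & (j < f.lat.size)
    if not np.all(ok):
        logger.warning("%d point(s) outside the ice grid extent", int(np.sum(~ok)))
    out = np.full(np.broadcast(lon, lat).shape, np.nan)
    out[ok] = f.grid[j[ok], i[ok]]
    return float(out) if out.ndim == 0 else out


def resolution_correlation(
    fields_a: dict[Date, IceField], fields_b: dict[Date, IceField], fixes: pd.DataFrame
) -> tuple[float, int]:
    """Pearson r between per-fix extractions at two resolutions; returns (r, n)."""
    va, vb = [], []
    for day, grp in fixes.groupby(fixes["timestamp"].dt.date):
        if day not in fields_a or day not in fields_b:
            raise ValueError(f"both resolutions required for {day}")
        va.append(sample_at(fields_a[day], grp["lon"].to_numpy(), grp["lat"].to_numpy()))
        vb.append(sample_at(fields_b[day], grp["lon"].to_numpy(), grp["lat"].to_numpy()))
    a = np.concatenate(va)
    b = np.concatenate(vb)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 valid paired extractions")
    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return r, int(ok.sum())


def _window_days(window) -> list[Date]:
    if isinstance(window, tuple) and len(window) == 2:
        d0, d1 = window
        return [d0 + timedelta(days=i) for i in range((d1 - d0).days + 1)]
    return sorted(set(window))


def mean_sic_region(fields: dict[Date, IceField], region: StudyRegion, window) -> float:
    """Mean concentration over cells inside the region, then over window days.

    ``window`` is a (start, end) date pair (inclusive) or an iterable of
    dates. Missing days raise an error listing them; a polygon containing no
    cell centers is an error.
    """
    days = _window_days(window)
    missing = [d for d in days if d not in fields]
    if missing:
        raise ValueError(f"ice fields missing for: {', '.join(str(d) for d in missing)}")
    daily = []
    mask_cache: dict[int, np.ndarray] = {}
    for d in days:
        f = fields[d]
        key = id(f.lon)
        if key not in mask_cache:
            glon, glat = np.meshgrid(f.lon, f.lat)
            inside = shapely.contains_xy(region.polygon, glon, glat)
            if not inside.any():
                # a hull smaller than one cell: widen by a cell diagonal so
                # the nearest cells represent it rather than failing
                buffered = region.polygon.buffer(max(abs(f.dlon), abs(f.dlat)))
                inside = shapely.contains_xy(buffered, glon, glat)
                if inside.any():
                    logger.info("region smaller than one grid cell; buffered by one cell")
            mask_cache[key] = inside
        inside = mask_cache[key]
        if not inside.any():
            raise ValueError("no cell centers inside the region polygon")
        vals = f.grid[inside]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"region fully masked on {d}")
        daily.append(float(vals.mean()))
    return float(np.mean(daily))


def annual_prospected_area(trips: list[Trip]) -> StudyRegion:
    """Convex hull of all retained fixes of one season, with equal-area km^2.

    The area is computed in a Lambert azimuthal equal-area projection
    centred on the hull centroid.
    """
    if not trips:
        raise ValueError("no trips for prospected area")
    season = trips[0].season
    pts = np.vstack([t.fixes[["lon", "lat"]].to_numpy() for t in trips])
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("fewer than 3 non-collinear fixes: degenerate hull")
    cx, cy = hull.centroid.x, hull.centroid.y
    ex, ey = hull.exterior.xy
    px, py = laea_xy_km(np.asarray(ex), np.asarray(ey), cx, cy)
    area = Polygon(zip(px, py)).area
    return StudyRegion(
        kind="annual_prospected_area", polygon=hull, season=season, area_km2=float(area)
    )


def mean_sic_central_phase(segment: pd.DataFrame, fields: dict[Date, IceField]) -> float:
    """Mean of per-fix concentrations over a central-phase segment.

    Masked fixes are excluded (count logged); all-masked is an error.
    """
    if len(segment) == 0:
        raise ValueError("empty segment")
    vals = []
    for day, grp in segment.groupby(segment["timestamp"].dt.date):
        if day not in fields:
            raise ValueError(f"ice fields missing for: {day}")
        vals.append(sample_at(fields[day], grp["lon"].to_numpy(), grp["lat"].to_numpy()))
    v = np.concatenate(vals)
    n_masked = int(np.sum(~np.isfinite(v)))
    if n_masked:
        logger.info("%d masked fix extraction(s) excluded", n_masked)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("all fixes masked")
    return float(v.mean())


def _trip_days(t: Trip) -> list[Date]:
    d0 = t.departure.date()
    d1 = t.return_time.date()
    return [d0 + timedelta(days=i) for i in range((d1 - d0).days + 1)]


def trip_pair_ice(
    trip_n: Trip,
    trip_n1: Trip,
    fields: dict[Date, IceField],
    region: StudyRegion,
    pair_mode: str = "union",
) -> TripPairIce:
    """Ice covariates for two consecutive trips of one bird.

    ``mean_sic_pair`` averages the region over the union of the two trips'
    date spans (``pair_mode='mean_of_means'`` instead averages the two trip
    means); ``sic_difference`` is mean(trip n) - mean(trip n+1), positive
    when the ice receded between trips.
    """
    if trip_n.bird_id != trip_n1.bird_id or trip_n1.trip_index != trip_n.trip_index + 1:
        raise ValueError("trip pair must be consecutive trips of the same bird")
    m_n = mean_sic_region(fields, region, _trip_days(trip_n))
    m_n1 = mean_sic_region(fields, region, _trip_days(trip_n1))
    if pair_mode == "union":
        days = sorted(set(_trip_days(trip_n)) | set(_trip_days(trip_n1)))
        pair = mean_sic_region(fields, region, days)
    elif pair_mode == "mean_of_means":
        pair = 0.5 * (m_n + m_n1)
    else:
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    return TripPairIce(mean_sic_pair=pair, sic_difference=m_n - m_n1)
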