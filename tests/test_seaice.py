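"""Ice-field IO, sampling conventions, regional means and trip covariates."""

from datetime import date as Date, timedelta

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from cpforage.geo import from_local_km
from cpforage.io_qc import Trip
from cpforage.seaice import (
    IceField,
    StudyRegion,
    WHOLE_STUDY_AREA,
    annual_prospected_area,
    load_icefields,
    mean_sic_central_phase,
    mean_sic_region,
    regrid_to_fine,
    resolution_correlation,
    sample_at,
    trip_pair_ice,
    write_icefields,
)
from cpforage.synthetic_data import SimConfig, simulate_icefields

D0 = Date(2016, 1, 1)


def make_field(grid, date=D0, lon0=138.0, lat0=-67.0, dlon=0.15, dlat=0.06, cell_km=6.25):
    grid = np.asarray(grid, dtype=float)
    ny, nx = grid.shape
    lon = lon0 + dlon * (np.arange(nx) + 0.5)
    lat = lat0 + dlat * (np.arange(ny) + 0.5)
    return IceField(date=date, cell_km=cell_km, lon=lon, lat=lat, grid=grid)


# --------------------------------------------------------------------- IO


def test_write_then_load_roundtrip_bitwise(tmp_path):
    rng = np.random.default_rng(0)
    fields = {
        D0 + timedelta(days=i): make_field(rng.uniform(0, 100, (8, 10)), D0 + timedelta(days=i))
        for i in range(5)
    }
    path = tmp_path / "ice.nc"
    write_icefields(fields, path)
    loaded = load_icefields(path)
    assert sorted(loaded) == sorted(fields)
    for d in fields:
        np.testing.assert_array_equal(loaded[d].grid, fields[d].grid)
        np.testing.assert_array_equal(loaded[d].lon, fields[d].lon)


def test_load_masks_out_of_range_values(tmp_path, caplog):
    g = np.full((4, 4), 40.0)
    g[1, 2] = 105.0
    write_icefields({D0: make_field(g)}, tmp_path / "bad.nc")
    with caplog.at_level("WARNING"):
        loaded = load_icefields(tmp_path / "bad.nc")
    assert np.isnan(loaded[D0].grid[1, 2])
    assert np.isfinite(loaded[D0].grid).sum() == 15
    assert "masked" in caplog.text


def test_load_reports_date_gaps(tmp_path, caplog):
    fields = {d: make_field(np.full((3, 3), 10.0), d) for d in (D0, D0 + timedelta(days=3))}
    write_icefields(fields, tmp_path / "gap.nc")
    with caplog.at_level("WARNING"):
        load_icefields(tmp_path / "gap.nc")
    assert "gaps" in caplog.text


# ----------------------------------------------------------------- regrid


def test_regrid_constant_and_checkerboard_block_structure():
    const = make_field(np.full((4, 6), 40.0))
    fine = regrid_to_fine(const)
    assert fine.grid.shape == (8, 12)
    assert (fine.grid == 40.0).all()
    cb = make_field(np.indices((4, 6)).sum(axis=0) % 2 * 100.0)
    fine_cb = regrid_to_fine(cb)
    for j in range(4):
        for i in range(6):
            assert (fine_cb.grid[2 * j : 2 * j + 2, 2 * i : 2 * i + 2] == cb.grid[j, i]).all()


def test_regrid_preserves_regional_mean_and_sampling():
    rng = np.random.default_rng(1)
    coarse = make_field(rng.uniform(0, 100, (10, 12)))
    fine = regrid_to_fine(coarse)
    assert fine.grid.mean() == pytest.approx(coarse.grid.mean(), rel=1e-12)
    # regrid-then-sample equals sampling the coarse field directly
    lons = rng.uniform(coarse.lon[0], coarse.lon[-1], 500)
    lats = rng.uniform(coarse.lat[0], coarse.lat[-1], 500)
    np.testing.assert_array_equal(sample_at(fine, lons, lats), sample_at(coarse, lons, lats))


# ----------------------------------------------------------------- sample


def test_sample_cell_center_edge_convention_and_outside():
    f = make_field(np.arange(12, dtype=float).reshape(3, 4))
    # exact center of cell (j=1, i=2)
    assert sample_at(f, f.lon[2], f.lat[1]) == f.grid[1, 2]
    # west/south edges inclusive: a point on the shared edge belongs east/north cell
    west_edge = f.lon[2] - 0.15 / 2
    assert sample_at(f, west_edge, f.lat[1]) == f.grid[1, 2]
    south_edge = f.lat[1] - 0.06 / 2
    assert sample_at(f, f.lon[2], south_edge) == f.grid[1, 2]
    assert np.isnan(sample_at(f, 120.0, -66.8))


def test_sample_matches_bruteforce_nearest_center():
    rng = np.random.default_rng(2)
    f = make_field(rng.uniform(0, 100, (9, 11)))
    lons = rng.uniform(f.lon[0] - 0.07, f.lon[-1] + 0.07, 1000)
    lats = rng.uniform(f.lat[0] - 0.02, f.lat[-1] + 0.02, 1000)
    got = sample_at(f, lons, lats)
    for lo, la, v in zip(lons, lats, got):
        i = int(np.argmin(np.abs(f.lon - lo)))
        j = int(np.argmin(np.abs(f.lat - la)))
        # nearest-center equals containing-cell on a regular grid away from edges
        assert v == f.grid[j, i]


# ----------------------------------------------------- resolution correlation


def _fix_frame(lons, lats, date=D0):
    ts = pd.Timestamp(str(date), tz="UTC") + pd.to_timedelta(np.arange(len(lons)), unit="s")
    return pd.DataFrame({"timestamp": ts, "lon": lons, "lat": lats})


def test_resolution_correlation_identical_and_functional():
    rng = np.random.default_rng(3)
    f = make_field(rng.uniform(0, 100, (10, 12)))
    fine = regrid_to_fine(f)
    fixes = _fix_frame(
        rng.uniform(f.lon[0], f.lon[-1], 200), rng.uniform(f.lat[0], f.lat[-1], 200)
    )
    r, n = resolution_correlation({D0: f}, {D0: f}, fixes)
    assert r == pytest.approx(1.0)
    r2, _ = resolution_correlation({D0: fine}, {D0: f}, fixes)
    assert r2 == pytest.approx(1.0)


def test_resolution_correlation_independent_fields_near_zero():
    rng = np.random.default_rng(4)
    a = make_field(rng.uniform(0, 100, (40, 50)))
    b = make_field(rng.uniform(0, 100, (40, 50)))
    fixes = _fix_frame(
        rng.uniform(a.lon[0], a.lon[-1], 10_000), rng.uniform(a.lat[0], a.lat[-1], 10_000)
    )
    r, n = resolution_correlation({D0: a}, {D0: b}, fixes)
    assert abs(r) < 0.1 and n == 10_000


def test_resolution_correlation_too_few_pairs():
    f = make_field(np.full((3, 3), 10.0))
    fixes = _fix_frame([f.lon[0], f.lon[1]], [f.lat[0], f.lat[1]])
    with pytest.raises(ValueError, match="fewer than 3"):
        resolution_correlation({D0: f}, {D0: f}, fixes)


# ------------------------------------------------------------ regional means


def test_mean_sic_region_constant_and_day_average():
    region = StudyRegion("whole_study_area", box(138.1, -66.9, 139.0, -66.5))
    f20 = make_field(np.full((10, 12), 20.0), D0)
    f40 = make_field(np.full((10, 12), 40.0), D0 + timedelta(days=1))
    assert mean_sic_region({D0: f20}, region, (D0, D0)) == 20.0
    assert mean_sic_region(
        {D0: f20, D0 + timedelta(days=1): f40}, region, (D0, D0 + timedelta(days=1))
    ) == pytest.approx(30.0)


def test_mean_sic_region_matches_bruteforce_point_in_polygon():
    rng = np.random.default_rng(5)
    f = make_field(rng.uniform(0, 100, (10, 12)))
    poly = box(138.2, -66.8, 139.2, -66.55)
    region = StudyRegion("whole_study_area", poly)
    got = mean_sic_region({D0: f}, region, (D0, D0))
    vals = []
    for j, la in enumerate(f.lat):
        for i, lo in enumerate(f.lon):
            if poly.contains(shapely.Point(lo, la)):
                vals.append(f.grid[j, i])
    assert got == pytest.approx(np.mean(vals))


def test_mean_sic_region_missing_day_lists_dates():
    region = StudyRegion("whole_study_area", box(138.1, -66.9, 139.0, -66.5))
    f = make_field(np.full((10, 12), 20.0), D0)
    with pytest.raises(ValueError, match="2016-01-02"):
        mean_sic_region({D0: f}, region, (D0, D0 + timedelta(days=1)))


# --------------------------------------------------------- prospected area


def _square_trip(side_km=10.0, bird="b1", season="2015-16", idx=1):
    corners = np.array([[0, 0], [side_km, 0], [side_km, side_km], [0, side_km], [0, 0]])
    lon, lat = from_local_km(corners[:, 0] + 5, corners[:, 1] + 5, 140.01, -66.66)
    ts = pd.Timestamp("2016-01-05T00:00Z") + pd.to_timedelta(np.arange(5) * 20, unit="m")
    fixes = pd.DataFrame({"timestamp": ts, "lon": lon, "lat": lat})
    return Trip(bird, season, idx, fixes, ts[0], ts[-1])


def test_prospected_area_square_hull_and_interior_invariance():
    t = _square_trip()
    region = annual_prospected_area([t])
    assert region.kind == "annual_prospected_area"
    assert region.area_km2 == pytest.approx(100.0, rel=0.01)
    # adding interior fixes leaves the hull unchanged
    t2 = _square_trip()
    mid_lon, mid_lat = from_local_km(np.array([10.0]), np.array([10.0]), 140.01, -66.66)
    extra = pd.DataFrame(
        {"timestamp": [t2.fixes["timestamp"].iloc[-1] + pd.Timedelta(minutes=20)],
         "lon": mid_lon, "lat": mid_lat}
    )
    t2.fixes = pd.concat([t2.fixes, extra], ignore_index=True)
    region2 = annual_prospected_area([t2])
    assert region2.polygon.equals(region.polygon)


def test_prospected_area_degenerate_hull_errors():
    t = _square_trip()
    t.fixes = t.fixes.iloc[:2]
    with pytest.raises(ValueError, match="degenerate hull"):
        annual_prospected_area([t])


def test_simulator_season_hull_matches_generator_envelope(small_cohort):
    sim, trips = small_cohort
    season = max({t.season for t in trips}, key=lambda s: sum(t.season == s for t in trips))
    season_trips = [t for t in trips if t.season == season]
    region = annual_prospected_area(season_trips)
    # generator envelope: hull of the true patch centers + colony in local km
    from shapely.geometry import MultiPoint

    tt = sim.trip_truth
    keys = {(t.bird_id, t.trip_index) for t in season_trips}
    pts = [
        (r.patch_x_km, r.patch_y_km)
        for r in tt[tt.season == season].itertuples(index=False)
        if (r.bird_id, r.trip_index) in keys
    ] + [(0.0, 0.0)]
    envelope = MultiPoint(pts).convex_hull.area
    assert region.area_km2 == pytest.approx(envelope, rel=0.15)


# --------------------------------------------------------- central phase SIC


def test_central_phase_sic_simple_means():
    f = make_field(np.full((6, 8), 25.0))
    fixes = _fix_frame([f.lon[2]] * 4, [f.lat[3]] * 4)
    assert mean_sic_central_phase(fixes, {D0: f}) == 25.0
    g = np.full((6, 8), 10.0)
    g[:, 4:] = 30.0
    f2 = make_field(g)
    fixes2 = _fix_frame([f2.lon[1], f2.lon[2], f2.lon[5], f2.lon[6]], [f2.lat[0]] * 4)
    assert mean_sic_central_phase(fixes2, {D0: f2}) == pytest.approx(20.0)


def test_central_phase_sic_matches_bruteforce():
    rng = np.random.default_rng(6)
    f = make_field(rng.uniform(0, 100, (10, 12)))
    lons = rng.uniform(f.lon[0], f.lon[-1], 300)
    lats = rng.uniform(f.lat[0], f.lat[-1], 300)
    fixes = _fix_frame(lons, lats)
    got = mean_sic_central_phase(fixes, {D0: f})
    brute = np.mean([sample_at(f, lo, la) for lo, la in zip(lons, lats)])
    assert got == pytest.approx(brute)


def test_central_phase_sic_all_masked_errors():
    f = make_field(np.full((4, 4), np.nan))
    fixes = _fix_frame([f.lon[0]], [f.lat[0]])
    with pytest.raises(ValueError, match="all fixes masked"):
        mean_sic_central_phase(fixes, {D0: f})


# -------------------------------------------------------------- trip pairs


def _trip_on_dates(d0: Date, d1: Date, bird="b1", idx=1):
    ts = pd.to_datetime([str(d0) + "T06:00:00Z", str(d1) + "T18:00:00Z"])
    lon, lat = from_local_km(np.array([3.0, 4.0]), np.array([3.0, 4.0]), 140.01, -66.66)
    fixes = pd.DataFrame({"timestamp": ts, "lon": lon, "lat": lat})
    return Trip(bird, "2015-16", idx, fixes, ts[0], ts[-1])


def test_trip_pair_ice_constant_and_recession_sign():
    region = StudyRegion("whole_study_area", box(138.1, -66.9, 139.0, -66.5))
    days = [D0 + timedelta(days=i) for i in range(4)]
    const = {d: make_field(np.full((10, 12), 30.0), d) for d in days}
    t1 = _trip_on_dates(days[0], days[1], idx=1)
    t2 = _trip_on_dates(days[2], days[3], idx=2)
    pair = trip_pair_ice(t1, t2, const, region)
    assert pair.mean_sic_pair == pytest.approx(30.0)
    assert pair.sic_difference == pytest.approx(0.0)
    # receding ice: trip n at 40%, trip n+1 at 25% -> difference +15
    fields = {days[0]: make_field(np.full((10, 12), 40.0), days[0]),
              days[1]: make_field(np.full((10, 12), 40.0), days[1]),
              days[2]: make_field(np.full((10, 12), 25.0), days[2]),
              days[3]: make_field(np.full((10, 12), 25.0), days[3])}
    pair2 = trip_pair_ice(t1, t2, fields, region)
    assert pair2.sic_difference == pytest.approx(15.0)
    assert pair2.mean_sic_pair == pytest.approx(32.5)


def test_trip_pair_ice_composes_from_regional_means():
    rng = np.random.default_rng(7)
    region = StudyRegion("whole_study_area", box(138.1, -66.9, 139.0, -66.5))
    days = [D0 + timedelta(days=i) for i in range(4)]
    fields = {d: make_field(rng.uniform(0, 100, (10, 12)), d) for d in days}
    t1 = _trip_on_dates(days[0], days[1], idx=1)
    t2 = _trip_on_dates(days[2], days[3], idx=2)
    pair = trip_pair_ice(t1, t2, fields, region)
    m1 = mean_sic_region(fields, region, (days[0], days[1]))
    m2 = mean_sic_region(fields, region, (days[2], days[3]))
    assert pair.sic_difference == pytest.approx(m1 - m2)
    assert pair.mean_sic_pair == pytest.approx(
        mean_sic_region(fields, region, (days[0], days[3]))
    )
    alt = trip_pair_ice(t1, t2, fields, region, pair_mode="mean_of_means")
    assert alt.mean_sic_pair == pytest.approx(0.5 * (m1 + m2))


def test_trip_pair_requires_consecutive_same_bird():
    days = [D0, D0 + timedelta(days=1)]
    fields = {d: make_field(np.full((4, 4), 10.0), d) for d in days}
    region = StudyRegion("whole_study_area", box(138.0, -67.0, 139.0, -66.5))
    t1 = _trip_on_dates(days[0], days[0], idx=1)
    t3 = _trip_on_dates(days[1], days[1], idx=3)
    with pytest.raises(ValueError, match="consecutive"):
        trip_pair_ice(t1, t3, fields, region)


# ------------------------------------------------------- simulator ice suite


def test_two_scale_means_correlate_on_gradient_fields(small_cohort):
    from scipy.stats import spearmanr

    sim, trips = small_cohort
    cfg = sim.config
    dates = sorted({ts.date() for t in trips for ts in t.fixes["timestamp"]})
    fields = simulate_icefields(cfg, dates=dates)
    season = max({t.season for t in trips}, key=lambda s: sum(t.season == s for t in trips))
    season_trips = [t for t in trips if t.season == season]
    region = annual_prospected_area(season_trips)
    whole, local = [], []
    for t in season_trips:
        win = (t.departure.date(), t.return_time.date())
        whole.append(mean_sic_region(fields, WHOLE_STUDY_AREA, win))
        local.append(mean_sic_region(fields, region, win))
    rho = spearmanr(whole, local).statistic
    assert rho > 0.5
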