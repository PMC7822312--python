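"""Pooled changepoint model and central-phase extraction."""

import numpy as np
import pandas as pd
import pytest

from cpforage.io_qc import Trip
from cpforage.phase_segmentation import (
    DEFAULT_PHASE_MODEL,
    PhaseModel,
    ThreeSegmentRegression,
    extract_central_phase,
    fit_three_segment,
    normalize_trips,
    validate_phases,
)

from conftest import straight_trip


def trapezoid(x, f1=30.0, f2=70.0):
    """Noise-free bell profile: rise to 100 at f1, plateau, fall after f2."""
    return np.where(
        x < f1, 100.0 * x / f1, np.where(x <= f2, 100.0, 100.0 * (100.0 - x) / (100.0 - f2))
    )


def brute_force_fit(x, y, grid_step):
    """Independent exhaustive scan: per-pair lstsq on the hinge basis."""
    knots = np.arange(grid_step, 100.0, grid_step)
    best = (np.inf, None)
    for i, f1 in enumerate(knots):
        for f2 in knots[i + 1 :]:
            A = np.column_stack(
                [np.ones_like(x), x, np.maximum(x - f1, 0.0), np.maximum(x - f2, 0.0)]
            )
            if (
                (x <= f1).sum() < 3 or ((x > f1) & (x <= f2)).sum() < 3 or (x > f2).sum() < 3
            ):
                continue
            coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
            if rank < 4:
                continue
            rss = float(np.sum((y - A @ coef) ** 2))
            if rss < best[0]:
                best = (rss, (f1, f2))
    return best


# ------------------------------------------------------------ normalization


def test_profile_shape_and_distal_point(small_trips, qc_params):
    prof = normalize_trips(small_trips, qc_params.colony)
    assert prof["pct_duration"].between(0, 100).all()
    assert prof["pct_maxdist"].between(0, 100 + 1e-9).all()
    per_trip_max = prof.groupby(["bird_id", "season", "trip_index"])["pct_maxdist"].max()
    np.testing.assert_allclose(per_trip_max.to_numpy(), 100.0)


def test_profile_single_out_and_back_rises_then_falls():
    t = straight_trip(n_fixes=31)
    prof = normalize_trips([t], (140.01, -66.66))
    y = prof["pct_maxdist"].to_numpy()
    peak = int(np.argmax(y))
    assert (np.diff(y[: peak + 1]) >= -1e-9).all()
    assert (np.diff(y[peak:]) <= 1e-9).all()


def test_pooled_simulator_profile_plateau_spans_true_fractions(small_trips, qc_params, small_cohort):
    prof = normalize_trips(small_trips, qc_params.colony)
    mid = prof[(prof.pct_duration > 35) & (prof.pct_duration < 65)]
    out = prof[prof.pct_duration < 25]
    assert mid["pct_maxdist"].mean() > 90.0
    assert out["pct_maxdist"].mean() < 70.0


# ------------------------------------------------------------------ fitting


def test_noise_free_trapezoid_recovers_exact_corners():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 100, 1500)
    m = fit_three_segment(pd.DataFrame({"pct_duration": x, "pct_maxdist": trapezoid(x)}))
    assert m.f1 == pytest.approx(30.0, abs=0.5)
    assert m.f2 == pytest.approx(70.0, abs=0.5)
    assert m.fit_score < 1e-12 * 1500 * 100**2 + 1e-6


def test_noisy_trapezoid_recovers_within_two_points():
    rng = np.random.default_rng(42)
    x = rng.uniform(0, 100, 2000)
    y = trapezoid(x) + rng.normal(0, 5.0, x.size)
    m = fit_three_segment(pd.DataFrame({"pct_duration": x, "pct_maxdist": y}))
    assert m.f1 == pytest.approx(30.0, abs=2.0)
    assert m.f2 == pytest.approx(70.0, abs=2.0)
    assert 0 < m.f1 < m.f2 < 100


def test_grid_search_equals_bruteforce_enumeration():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 100, 300)
    y = trapezoid(x, 25.0, 64.0) + rng.normal(0, 8.0, x.size)
    reg = ThreeSegmentRegression(grid_step=2.0).fit(x, y)
    rss_bf, (f1_bf, f2_bf) = brute_force_fit(x, y, 2.0)
    assert (reg.model_.f1, reg.model_.f2) == (f1_bf, f2_bf)
    assert reg.model_.fit_score == pytest.approx(rss_bf, rel=1e-9)
    # the whole RSS surface agrees, not just the argmin
    sample = reg.rss_grid_.sample(40, random_state=0)
    for row in sample.itertuples(index=False):
        A = np.column_stack(
            [np.ones_like(x), x, np.maximum(x - row.f1, 0.0), np.maximum(x - row.f2, 0.0)]
        )
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        assert row.rss == pytest.approx(float(np.sum((y - A @ coef) ** 2)), rel=1e-8)


def test_fit_invariant_to_point_order():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 100, 800)
    y = trapezoid(x) + rng.normal(0, 4.0, x.size)
    m1 = fit_three_segment(pd.DataFrame({"pct_duration": x, "pct_maxdist": y}))
    perm = rng.permutation(x.size)
    m2 = fit_three_segment(pd.DataFrame({"pct_duration": x[perm], "pct_maxdist": y[perm]}))
    assert (m1.f1, m1.f2, m1.fit_score) == (m2.f1, m2.f2, pytest.approx(m1.fit_score))


def test_constant_profile_rejected():
    x = np.linspace(0, 100, 200)
    with pytest.raises(ValueError, match="no bell structure"):
        fit_three_segment(pd.DataFrame({"pct_duration": x, "pct_maxdist": np.full_like(x, 50.0)}))


def test_phase_model_validation_and_roundtrip(tmp_path):
    with pytest.raises(ValueError):
        PhaseModel(f1=70.0, f2=30.0)
    p = tmp_path / "m.json"
    DEFAULT_PHASE_MODEL.to_json(p)
    loaded = PhaseModel.from_json(p)
    assert (loaded.f1, loaded.f2) == (DEFAULT_PHASE_MODEL.f1, DEFAULT_PHASE_MODEL.f2)


# --------------------------------------------------------------- extraction


def test_central_phase_boundaries_inclusive_and_contiguous():
    t = straight_trip(n_fixes=101, step_min=6.0)  # fixes at pct 0,1,...,100
    seg = extract_central_phase(t, DEFAULT_PHASE_MODEL)
    pct = (
        (seg["timestamp"] - t.departure).dt.total_seconds()
        / (t.return_time - t.departure).total_seconds()
        * 100.0
    )
    assert pct.min() >= 31.2 and pct.max() <= 69.7
    assert len(seg) == 38  # pct 32..69 inclusive
    # contiguity: the extracted fixes are one unbroken time slice
    idx = t.fixes["timestamp"].searchsorted(seg["timestamp"])
    assert (np.diff(idx) == 1).all()
    # boundary fixes exactly at f1/f2 are kept
    m = PhaseModel(f1=10.0, f2=90.0)
    seg2 = extract_central_phase(t, m)
    assert len(seg2) == 81


def test_full_range_model_returns_whole_trip():
    t = straight_trip(n_fixes=31)
    seg = extract_central_phase(t, PhaseModel(f1=0.0, f2=100.0))
    assert len(seg) == len(t.fixes)


def test_extracted_phase_overlaps_true_foraging_regime(small_cohort):
    sim, trips = small_cohort
    truth = sim.trip_truth.set_index(["bird_id", "season", "trip_index"])
    model = PhaseModel(f1=30.0, f2=70.0)
    jaccards = []
    for t in trips:
        row = truth.loc[(t.bird_id, t.season, t.trip_index)]
        seg = extract_central_phase(t, model)
        if len(seg) < 2:
            continue
        pred = set(seg["timestamp"])
        true = set(
            t.fixes.loc[
                (t.fixes["timestamp"] >= row["phase1_end"])
                & (t.fixes["timestamp"] <= row["phase2_end"]),
                "timestamp",
            ]
        )
        jaccards.append(len(pred & true) / len(pred | true))
    assert np.mean(jaccards) > 0.8


# --------------------------------------------------------------- validation


def test_simulator_central_phase_slower_and_more_sinuous(small_trips):
    table = validate_phases(small_trips, PhaseModel(f1=30.0, f2=70.0))
    speed = table[table.variable == "mean_speed"]
    sinu = table[table.variable == "sinuosity"]
    assert (speed.direction == -1).all() and (speed.pvalue < 0.01).all()
    assert (sinu.direction == 1).all() and (sinu.pvalue < 0.01).all()


def test_identical_phases_show_no_difference():
    # a symmetric out-and-back at constant speed: every phase is a straight
    # line at the same speed
    trips = [straight_trip(n_fixes=61, bearing_deg=b) for b in (0.0, 20.0)]
    table = validate_phases(trips, PhaseModel(f1=25.0, f2=75.0))
    speeds = table[table.variable == "mean_speed"]
    assert (speeds.pvalue > 0.05).all()


def test_single_trip_descriptive_only(caplog):
    with caplog.at_level("WARNING"):
        table = validate_phases([straight_trip(n_fixes=61)], PhaseModel(f1=25.0, f2=75.0))
    assert table["pvalue"].isna().all()
    assert "descriptive" in caplog.text
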