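"""Pooled three-phase segmentation of foraging trips.

Central-place foraging trips decompose into an outbound transit, a central
foraging phase and an inbound transit. Pooling all trips onto a normalized
profile — percent of trip duration elapsed (x) against percent of the trip's
maximal colony distance (y) — produces a bell-shaped cloud whose two
inflection points locate the phase boundaries as population-level fractions
of trip duration.

The boundary fractions are estimated with a continuous two-breakpoint
piecewise-linear regression, minimizing the residual sum of squares over an
exhaustive (f1, f2) grid. For fixed breakpoints the model is linear in the
basis {1, x, (x-f1)+, (x-f2)+}, so each candidate pair costs one 4x4 solve;
the Gram matrices for the whole grid are assembled from suffix sums of the
sorted profile, making the exhaustive scan cheap even on large pooled
profiles. Breakpoint uncertainty is read off the RSS profile: the half-width
of the breakpoint range over all grid pairs whose RSS is within 5% of the
minimum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .geo import great_circle_km
from .io_qc import Trip
from .trip_metrics import SegmentKinematics, compare_phase_kinematics, segment_kinematics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhaseModel:
    """Two population breakpoint fractions (percent of trip duration)."""

    f1: float
    f2: float
    f1_halfwidth: float = 0.0
    f2_halfwidth: float = 0.0
    fit_score: float = float("nan")  # residual sum of squares at the optimum

    def __post_init__(self):
        if not 0.0 <= self.f1 < self.f2 <= 100.0:
            raise ValueError("require 0 <= f1 < f2 <= 100")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PhaseModel":
        with open(path) as fh:
            return cls(**json.load(fh))


#: Population defaults calibrated on the Terre Adélie chick-rearing cohort.
DEFAULT_PHASE_MODEL = PhaseModel(f1=31.2, f2=69.7)


def normalize_trips(trips, colony: tuple[float, float]) -> pd.DataFrame:
    """Pool trips onto the normalized distance-time profile.

    Every fix contributes one point: ``pct_duration`` — percent of the total
    trip duration elapsed at the fix — and ``pct_maxdist`` — its colony
    distance as a percent of the trip's maximal colony distance. Trips whose
    maximal distance is zero are excluded (logged).
    """
    frames = []
    for t in trips:
        d = np.atleast_1d(great_circle_km(np.array(colony), t.fixes[["lon", "lat"]].to_numpy()))
        dmax = d.max()
        if dmax <= 0:
            logger.warning("%s trip %d: zero maximal distance, excluded", t.bird_id, t.trip_index)
            continue
        dur = (t.return_time - t.departure).total_seconds()
        el = (t.fixes["timestamp"] - t.departure).dt.total_seconds().to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "bird_id": t.bird_id,
                    "season": t.season,
                    "trip_index": t.trip_index,
                    "pct_duration": np.clip(100.0 * el / dur, 0.0, 100.0),
                    "pct_maxdist": 100.0 * d / dmax,
                }
            )
        )
    if not frames:
        raise ValueError("no usable trips for profile pooling")
    return pd.concat(frames, ignore_index=True)


def _suffix_sums(x: np.ndarray, y: np.ndarray, knots: np.ndarray) -> dict[str, np.ndarray]:
    """Sums of 1, x, x^2, y, x*y over points with x > knot, for every knot."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    pos = np.searchsorted(xs, knots, side="right")
    out = {}
    for name, v in (
        ("c0", np.ones_like(xs)),
        ("c1", xs),
        ("c2", xs**2),
        ("cy", ys),
        ("cxy", xs * ys),
    ):
        cum = np.concatenate([[0.0], np.cumsum(v)])
        out[name] = cum[-1] - cum[pos]
    return out


class ThreeSegmentRegression:
    """Continuous two-breakpoint piecewise-linear least squares on a grid.

    Parameters
    ----------
    grid_step : float
        Breakpoint grid spacing in percent of trip duration (default 0.5).
    min_points : int
        Minimum number of profile points required in each of the three
        segments for a (f1, f2) pair to be admissible.

    Attributes (after :meth:`fit`)
    ----------
    model_ : PhaseModel with the argmin breakpoints and RSS-profile widths.
    coef_ : (intercept, slope, slope change at f1, slope change at f2).
    rss_grid_ : DataFrame of admissible (f1, f2, rss) — the full scan.
    """

    def __init__(self, grid_step: float = 0.5, min_points: int = 3, rss_tolerance: float = 1.05):
        self.grid_step = grid_step
        self.min_points = min_points
        self.rss_tolerance = rss_tolerance

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 3 * self.min_points:
            raise ValueError("profile too small for a three-segment fit")
        if np.ptp(y) < 1e-9:
            raise ValueError("no bell structure: profile is constant")

        knots = np.arange(self.grid_step, 100.0, self.grid_step)
        s = _suffix_sums(x, y, knots)
        n_tot, sx_tot, sxx_tot = x.size, x.sum(), (x**2).sum()
        sy_tot, sxy_tot, syy_tot = y.sum(), (x * y).sum(), (y**2).sum()

        k = len(knots)
        i1, i2 = np.triu_indices(k, k=1)  # all f1 < f2 pairs
        f1, f2 = knots[i1], knots[i2]

        # per-knot suffix moments at f1 and f2
        c0_1, c1_1, c2_1 = s["c0"][i1], s["c1"][i1], s["c2"][i1]
        cy_1, cxy_1 = s["cy"][i1], s["cxy"][i1]
        c0_2, c1_2, c2_2 = s["c0"][i2], s["c1"][i2], s["c2"][i2]
        cy_2, cxy_2 = s["cy"][i2], s["cxy"][i2]

        # admissibility: enough points per segment
        n_mid = c0_1 - c0_2
        n_low = n_tot - c0_1
        ok = (n_low >= self.min_points) & (n_mid >= self.min_points) & (c0_2 >= self.min_points)
        if not ok.any():
            raise ValueError("no admissible breakpoint pair on the grid")

        su1 = c1_1 - f1 * c0_1  # sum (x-f1)+
        su2 = c1_2 - f2 * c0_2  # sum (x-f2)+
        suu1 = c2_1 - 2 * f1 * c1_1 + f1**2 * c0_1
        suu2 = c2_2 - 2 * f2 * c1_2 + f2**2 * c0_2
        sxu1 = c2_1 - f1 * c1_1
        sxu2 = c2_2 - f2 * c1_2
        su1u2 = c2_2 - (f1 + f2) * c1_2 + f1 * f2 * c0_2  # over x > f2
        syu1 = cxy_1 - f1 * cy_1
        syu2 = cxy_2 - f2 * cy_2

        m = int(ok.sum())
        G = np.empty((m, 4, 4))
        G[:, 0, 0] = n_tot
        G[:, 0, 1] = G[:, 1, 0] = sx_tot
        G[:, 1, 1] = sxx_tot
        G[:, 0, 2] = G[:, 2, 0] = su1[ok]
        G[:, 0, 3] = G[:, 3, 0] = su2[ok]
        G[:, 1, 2] = G[:, 2, 1] = sxu1[ok]
        G[:, 1, 3] = G[:, 3, 1] = sxu2[ok]
        G[:, 2, 2] = suu1[ok]
        G[:, 2, 3] = G[:, 3, 2] = su1u2[ok]
        G[:, 3, 3] = suu2[ok]
        b = np.column_stack([np.full(m, sy_tot), np.full(m, sxy_tot), syu1[ok], syu2[ok]])

        rss = np.full(i1.shape, np.inf)
        try:
            beta = np.linalg.solve(G, b[..., None])[..., 0]
            rss_ok = syy_tot - np.einsum("ij,ij->i", beta, b)
        except np.linalg.LinAlgError:  # isolated singular pair: fall back per pair
            beta = np.empty((m, 4))
            rss_ok = np.full(m, np.inf)
            for j in range(m):
                try:
                    beta[j] = np.linalg.solve(G[j], b[j])
                    rss_ok[j] = syy_tot - beta[j] @ b[j]
                except np.linalg.LinAlgError:
                    pass
        rss[ok] = np.maximum(rss_ok, 0.0)

        best = int(np.argmin(rss))
        best_rss = float(rss[best])
        near = rss <= self.rss_tolerance * best_rss
        f1_hw = float(np.ptp(f1[near]) / 2.0)
        f2_hw = float(np.ptp(f2[near]) / 2.0)

        self.model_ = PhaseModel(
            f1=float(f1[best]), f2=float(f2[best]),
            f1_halfwidth=f1_hw, f2_halfwidth=f2_hw, fit_score=best_rss,
        )
        ok_idx = np.flatnonzero(ok)
        self.coef_ = beta[np.searchsorted(ok_idx, best)].copy()
        self.rss_grid_ = pd.DataFrame({"f1": f1[ok], "f2": f2[ok], "rss": rss[ok]})
        return self

    def predict(self, x):
        """Fitted piecewise-linear profile value at x (percent duration)."""
        if not hasattr(self, "coef_"):
            raise ValueError("call fit first")
        x = np.asarray(x, dtype=float)
        b0, b1, b2, b3 = self.coef_
        m = self.model_
        return (
            b0 + b1 * x + b2 * np.maximum(x - m.f1, 0.0) + b3 * np.maximum(x - m.f2, 0.0)
        )


def fit_three_segment(profile: pd.DataFrame, grid_step: float = 0.5) -> PhaseModel:
    """Fit the pooled three-segment changepoint model; returns the PhaseModel."""
    reg = ThreeSegmentRegression(grid_step=grid_step)
    reg.fit(profile["pct_duration"].to_numpy(), profile["pct_maxdist"].to_numpy())
    return reg.model_


def pct_duration(t: Trip) -> np.ndarray:
    dur = (t.return_time - t.departure).total_seconds()
    pct = 100.0 * (t.fixes["timestamp"] - t.departure).dt.total_seconds().to_numpy() / dur
    return np.clip(pct, 0.0, 100.0)  # guard float noise at the endpoints


def assign_phases(t: Trip, m: PhaseModel) -> np.ndarray:
    """Label each fix outbound / central / inbound; boundaries are central."""
    pct = pct_duration(t)
    labels = np.where(pct < m.f1, "outbound", np.where(pct > m.f2, "inbound", "central"))
    return labels


def extract_central_phase(t: Trip, m: PhaseModel) -> pd.DataFrame:
    """Fixes with percent duration in [f1, f2] (boundary fixes included).

    Returns a contiguous time slice of the trip's fixes; a result with fewer
    than two fixes is flagged by a logged warning (too short for fidelity).
    """
    pct = pct_duration(t)
    mask = (pct >= m.f1) & (pct <= m.f2)
    out = t.fixes[mask].reset_index(drop=True)
    if len(out) < 2:
        logger.warning("%s trip %d: central phase < 2 fixes", t.bird_id, t.trip_index)
    return out


def validate_phases(trips, m: PhaseModel) -> pd.DataFrame:
    """Per-phase kinematics check: the central phase should show shorter
    distances, slower speeds and more sinuous paths than both transits.

    Returns the comparison table from
    :func:`cpforage.trip_metrics.compare_phase_kinematics`.
    """
    per_phase: dict[str, list[SegmentKinematics]] = {"outbound": [], "central": [], "inbound": []}
    for t in trips:
        labels = assign_phases(t, m)
        for phase in per_phase:
            seg = t.fixes[labels == phase]
            if len(seg) >= 2:
                per_phase[phase].append(segment_kinematics(seg.reset_index(drop=True)))
    if sum(len(v) for v in per_phase.values()) == 0:
        raise ValueError("no phase segments with >= 2 fixes")
    return compare_phase_kinematics(per_phase)
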