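"""Foraging-site fidelity via the nearest-neighbour distance (NND).

For two consecutive trips of the same bird, every fix of the *focal* trip's
central phase (trip n+1) is matched to its nearest fix in the previous
trip's central phase (trip n); the NND is the mean of those great-circle
distances over the focal fixes. Identical routes give NND = 0; the lower
the NND, the higher the site fidelity. The statistic is asymmetric by
construction (focal = later trip).

Nearest neighbours are found exactly on the sphere: fixes are embedded as
unit vectors and queried through a k-d tree on chord distance, which is
monotone in the great-circle angle, then converted back to km.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geo import EARTH_RADIUS_KM
from .io_qc import Trip
from .phase_segmentation import PhaseModel, extract_central_phase
from .seaice import TripPairIce, trip_pair_ice

logger = logging.getLogger(__name__)


@dataclass
class FidelityRecord:
    bird_id: str
    season: str
    trip_from: int
    trip_to: int
    nnd: float  # km
    n_focal_points: int
    days_since_peak_hatch: float  # of the focal trip's departure
    ice: TripPairIce | None = None


def _unit_vectors(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    return np.column_stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )


def nnd(focal: pd.DataFrame, previous: pd.DataFrame) -> float:
    """Mean nearest-neighbour great-circle distance (km), focal vs previous.

    ``focal`` and ``previous`` are fix frames with lon/lat columns; both must
    be non-empty. Exactly equivalent to the quadratic all-pairs minimum.
    """
    if len(focal) == 0 or len(previous) == 0:
        raise ValueError("empty central-phase segment")
    pf = _unit_vectors(focal["lon"].to_numpy(), focal["lat"].to_numpy())
    pp = _unit_vectors(previous["lon"].to_numpy(), previous["lat"].to_numpy())
    chord, _ = cKDTree(pp).query(pf, k=1)
    angles = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    return float(np.mean(angles) * EARTH_RADIUS_KM)


def fidelity_table(
    trips: list[Trip],
    phase_model: PhaseModel,
    peak_hatch_by_season: dict[str, pd.Timestamp] | None = None,
    fields=None,
    region_by_season=None,
    allow_gaps: bool = False,
) -> list[FidelityRecord]:
    """One FidelityRecord per consecutive within-bird trip pair.

    Pairs are formed only between trips with consecutive indices (a discarded
    intermediate trip breaks the chain) unless ``allow_gaps``; birds with one
    trip contribute nothing. When ice fields and per-season regions are given,
    trip-pair ice covariates are attached. Focal central phases with fewer
    than 2 fixes are skipped (logged).
    """
    records: list[FidelityRecord] = []
    by_bird: dict[tuple[str, str], list[Trip]] = {}
    for t in trips:
        by_bird.setdefault((t.bird_id, t.season), []).append(t)
    for (bird, season), ts in sorted(by_bird.items()):
        ts = sorted(ts, key=lambda t: t.trip_index)
        if len(ts) < 2:
            logger.info("%s/%s: single trip, no fidelity pair", bird, season)
            continue
        for prev, foc in zip(ts[:-1], ts[1:]):
            if not allow_gaps and foc.trip_index != prev.trip_index + 1:
                logger.info(
                    "%s/%s: trips %d and %d not consecutive, pair skipped",
                    bird, season, prev.trip_index, foc.trip_index,
                )
                continue
            seg_prev = extract_central_phase(prev, phase_model)
            seg_foc = extract_central_phase(foc, phase_model)
            if len(seg_foc) < 2 or len(seg_prev) < 1:
                logger.warning(
                    "%s/%s pair (%d,%d): central phase too short, skipped",
                    bird, season, prev.trip_index, foc.trip_index,
                )
                continue
            ice = None
            if fields is not None and region_by_season is not None:
                ice = trip_pair_ice(prev, foc, fields, region_by_season[season])
            timing = np.nan
            if peak_hatch_by_season is not None:
                ph = pd.Timestamp(peak_hatch_by_season[season])
                if ph.tzinfo is None:
                    ph = ph.tz_localize("UTC")
                timing = (foc.departure - ph).total_seconds() / 86400.0
            records.append(
                FidelityRecord(
                    bird_id=bird,
                    season=season,
                    trip_from=prev.trip_index,
                    trip_to=foc.trip_index,
                    nnd=nnd(seg_foc, seg_prev),
                    n_focal_points=len(seg_foc),
                    days_since_peak_hatch=timing,
                    ice=ice,
                )
            )
    return records


def records_frame(records: list[FidelityRecord]) -> pd.DataFrame:
    """Flatten FidelityRecords (and any ice covariates) to a DataFrame."""
    rows = []
    for r in records:
        row = {
            "bird_id": r.bird_id,
            "season": r.season,
            "trip_from": r.trip_from,
            "trip_to": r.trip_to,
            "nnd": r.nnd,
            "n_focal_points": r.n_focal_points,
            "days_since_peak_hatch": r.days_since_peak_hatch,
        }
        if r.ice is not None:
            row["mean_sic_pair"] = r.ice.mean_sic_pair
            row["sic_difference"] = r.ice.sic_difference
        rows.append(row)
    return pd.DataFrame(rows)
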