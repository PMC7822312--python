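"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order::

    simulate -> qc -> metrics -> phases -> seaice -> repeatability
                                        -> fidelity -> models -> report

Each stage reads its inputs from the output directory (or the in-memory
state of the same run) and writes CSV/JSON artifacts there; the run
manifest records the configuration hash and root seed so identical reruns
reproduce identical deterministic artifacts. Configuration is a flat
``key = value`` text file; any key absent falls back to the defaults below.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_qc, phase_segmentation, seaice, site_fidelity, stats_models
from .io_qc import QcParams
from .repeatability import repeatability_table
from .synthetic_data import SimConfig, simulate_cohort, simulate_icefields
from .trip_metrics import metrics_table

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "metrics", "phases", "seaice", "repeatability", "fidelity", "models", "report"]


@dataclass
class PipelineConfig:
    out_dir: str = "cpforage_out"
    tracks: str | None = None
    nest_checks: str | None = None
    peak_hatch: str | None = None
    ice: str | None = None
    phase_mode: str = "fit"  # "fit" | "fixed"
    grid_step: float = 0.5
    n_boot: int = 0
    n_birds: int = 20
    fidelity_mode: str = "faithful"
    seed: int = 0
    qc: QcParams = field(default_factory=QcParams)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()
        cfg = cls()
        for k, v in kv.items():
            if k in ("grid_step",):
                setattr(cfg, k, float(v))
            elif k in ("n_boot", "n_birds", "seed"):
                setattr(cfg, k, int(v))
            elif hasattr(cfg, k):
                setattr(cfg, k, v)
            elif hasattr(cfg.qc, k):
                cfg.qc = QcParams(**{**vars(cfg.qc), k: float(v)})
            else:
                raise ValueError(f"unknown config key {k!r}")
        return cfg

    def digest(self) -> str:
        payload = {k: str(v) for k, v in vars(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


class Pipeline:
    """Run stages against one output directory, carrying state in memory."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}

    # -- helpers ----------------------------------------------------------
    def _manifest(self) -> None:
        with open(self.out / "run_manifest.json", "w") as fh:
            json.dump({"config_hash": self.cfg.digest(), "seed": self.cfg.seed}, fh, indent=1)

    def _peak_hatch(self) -> dict[str, pd.Timestamp]:
        if "peak_hatch" in self.state:
            return self.state["peak_hatch"]
        path = self.cfg.peak_hatch or self.out / "input" / "peak_hatch.csv"
        df = pd.read_csv(path)
        ph = {r.season: pd.Timestamp(r.peak_hatch, tz="UTC") for r in df.itertuples(index=False)}
        self.state["peak_hatch"] = ph
        return ph

    def _trips(self) -> list:
        if "trips" not in self.state:
            fixes = pd.read_csv(self.out / "trips_fixes.csv")
            meta = pd.read_csv(self.out / "trips_meta.csv")
            self.state["trips"] = io_qc.trips_from_frames(fixes, meta)
        return self.state["trips"]

    def _phase_model(self) -> phase_segmentation.PhaseModel:
        if "phase_model" not in self.state:
            path = self.out / "phase_model.json"
            if path.exists():
                self.state["phase_model"] = phase_segmentation.PhaseModel.from_json(path)
            else:
                self.state["phase_model"] = phase_segmentation.DEFAULT_PHASE_MODEL
        return self.state["phase_model"]

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> None:
        sim_cfg = SimConfig(
            n_birds=self.cfg.n_birds, fidelity_mode=self.cfg.fidelity_mode, seed=self.cfg.seed
        )
        sim = simulate_cohort(sim_cfg)
        in_dir = self.out / "input"
        sim.write(in_dir)
        dates = sorted(
            set(
                pd.concat(
                    [pd.to_datetime(sim.tracks["timestamp"]).dt.date,
                     pd.to_datetime(sim.nest_checks["observed_return"]).dt.date]
                )
            )
        )
        all_days = [dates[0] + pd.Timedelta(days=i).to_pytimedelta() for i in range((dates[-1] - dates[0]).days + 1)]
        fields = simulate_icefields(sim_cfg, dates=all_days)
        seaice.write_icefields(fields, in_dir / "icefields.nc")
        self.cfg.tracks = str(in_dir / "tracks.csv")
        self.cfg.nest_checks = str(in_dir / "nest_checks.csv")
        self.cfg.peak_hatch = str(in_dir / "peak_hatch.csv")
        self.cfg.ice = str(in_dir / "icefields.nc")
        self.state["sim"] = sim

    def stage_qc(self) -> None:
        if self.cfg.tracks is None:
            raise ValueError("qc stage requires a tracks path (or the simulate stage)")
        deployments = io_qc.read_tracks(self.cfg.tracks)
        checks = io_qc.read_nest_checks(self.cfg.nest_checks) if self.cfg.nest_checks else {}
        trips: list = []
        for dep in deployments:
            dep.nest_checks = checks.get((dep.bird_id, dep.season), {})
            trips.extend(io_qc.qc_deployment(dep, self.cfg.qc))
        if not trips:
            raise ValueError("qc produced no retained trips")
        fixes, meta = io_qc.trips_to_frames(trips)
        fixes.to_csv(self.out / "trips_fixes.csv", index=False)
        meta.to_csv(self.out / "trips_meta.csv", index=False)
        summary = io_qc.summarize_cohort(trips)
        summary.table.to_csv(self.out / "cohort_summary.csv")
        self.state["trips"] = trips
        self.state["cohort_summary"] = summary

    def stage_metrics(self) -> None:
        mt = metrics_table(self._trips(), self._peak_hatch(), self.cfg.qc.colony)
        mt.to_csv(self.out / "trip_metrics.csv", index=False)
        self.state["metrics"] = mt

    def stage_phases(self) -> None:
        trips = self._trips()
        if self.cfg.phase_mode == "fixed":
            model = phase_segmentation.DEFAULT_PHASE_MODEL
        else:
            profile = phase_segmentation.normalize_trips(trips, self.cfg.qc.colony)
            model = phase_segmentation.fit_three_segment(profile, grid_step=self.cfg.grid_step)
        model.to_json(self.out / "phase_model.json")
        validation = phase_segmentation.validate_phases(trips, model)
        validation.to_csv(self.out / "phase_validation.csv", index=False)
        self.state["phase_model"] = model

    def stage_seaice(self) -> None:
        if not self.cfg.ice:
            logger.warning("no ice path configured; seaice stage skipped")
            return
        fields = seaice.load_icefields(self.cfg.ice)
        trips = self._trips()
        model = self._phase_model()
        by_season: dict[str, list] = {}
        for t in trips:
            by_season.setdefault(t.season, []).append(t)
        regions = {s: seaice.annual_prospected_area(ts) for s, ts in by_season.items()}
        pd.DataFrame(
            [{"season": s, "area_km2": r.area_km2} for s, r in regions.items()]
        ).to_csv(self.out / "prospected_areas.csv", index=False)
        rows = []
        for t in trips:
            seg = phase_segmentation.extract_central_phase(t, model)
            if len(seg) == 0:
                continue
            try:
                sic = seaice.mean_sic_central_phase(seg, fields)
            except ValueError as exc:
                logger.warning("%s trip %d: %s", t.bird_id, t.trip_index, exc)
                continue
            rows.append(
                {"bird_id": t.bird_id, "season": t.season, "trip_index": t.trip_index,
                 "central_phase_sic": sic}
            )
        sic_df = pd.DataFrame(rows)
        sic_df.to_csv(self.out / "central_phase_sic.csv", index=False)
        self.state["fields"] = fields
        self.state["regions"] = regions
        self.state["central_sic"] = sic_df

    def stage_repeatability(self) -> None:
        mt = self.state.get("metrics")
        if mt is None:
            mt = pd.read_csv(self.out / "trip_metrics.csv")
        data = mt.copy()
        sic = self.state.get("central_sic")
        if sic is None and (self.out / "central_phase_sic.csv").exists():
            sic = pd.read_csv(self.out / "central_phase_sic.csv")
        if sic is not None and len(sic):
            data = data.merge(sic, on=["bird_id", "season", "trip_index"], how="left")
            data = data.rename(columns={"central_phase_sic": "central_phase_sic"})
        table = repeatability_table(data, n_boot=self.cfg.n_boot, seed=self.cfg.seed)
        table.to_csv(self.out / "repeatability.csv", index=False)
        self.state["repeatability"] = table

    def stage_fidelity(self) -> None:
        trips = self._trips()
        records = site_fidelity.fidelity_table(
            trips,
            self._phase_model(),
            peak_hatch_by_season=self._peak_hatch(),
            fields=self.state.get("fields"),
            region_by_season=self.state.get("regions"),
        )
        df = site_fidelity.records_frame(records)
        if df.empty:
            raise ValueError("no fidelity records formed")
        df.to_csv(self.out / "fidelity.csv", index=False)
        self.state["fidelity"] = df

    def stage_models(self) -> None:
        df = self.state.get("fidelity")
        if df is None:
            df = pd.read_csv(self.out / "fidelity.csv")
        year = stats_models.fit_year_model(df)
        year.table.to_csv(self.out / "nnd_year_model.csv", index=False)
        results = {"year": year}
        try:
            yt = stats_models.fit_year_timing_model(df)
            yt.table.to_csv(self.out / "nnd_year_timing_model.csv", index=False)
            yt.contrasts.to_csv(self.out / "nnd_year_contrasts.csv", index=False)
            results["year_timing"] = yt
        except ValueError as exc:
            logger.warning("year-timing model skipped: %s", exc)
        for cov in ("mean_sic_pair", "sic_difference"):
            if cov not in df.columns:
                continue
            try:
                sm = stats_models.fit_smooth_ice_model(df, covariate=cov)
            except ValueError as exc:
                logger.warning("smooth model on %s skipped: %s", cov, exc)
                continue
            pd.DataFrame(
                {cov: sm.grid, "log_nnd_fit": sm.fitted,
                 "band_low": sm.band_low, "band_high": sm.band_high}
            ).to_csv(self.out / f"nnd_smooth_{cov}.csv", index=False)
            results[f"smooth_{cov}"] = sm
        self.state["models"] = results

    def stage_report(self) -> None:
        lines = [f"cpforage run (config {self.cfg.digest()}, seed {self.cfg.seed})"]
        if "cohort_summary" in self.state:
            s = self.state["cohort_summary"]
            lines.append(
                f"cohort: {s.n_individuals} individuals, {s.n_trips} trips "
                f"({s.mean_trips_per_bird:.2f} +/- {s.sd_trips_per_bird:.2f} trips/bird)"
            )
        if "phase_model" in self.state:
            m = self.state["phase_model"]
            lines.append(f"phase breakpoints: f1={m.f1:.1f}%, f2={m.f2:.1f}% of trip duration")
        if "repeatability" in self.state:
            for row in self.state["repeatability"].itertuples(index=False):
                tag = "adjusted" if row.adjusted else "non-adjusted"
                lines.append(f"R[{row.response}, {tag}] = {row.R:.3f} ({row.category})")
        if "fidelity" in self.state:
            lines.append(f"fidelity records: {len(self.state['fidelity'])}, "
                         f"mean NND {self.state['fidelity']['nnd'].mean():.2f} km")
        (self.out / "report.txt").write_text("\n".join(lines) + "\n")

    def run(self, stages: list[str] | None = None) -> dict:
        stages = stages or STAGES
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        self._manifest()
        for name in STAGES:
            if name not in stages:
                continue
            try:
                getattr(self, f"stage_{name}")()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        return self.state


def run(config: PipelineConfig | str | Path, stages: list[str] | None = None) -> dict:
    """Run the pipeline from a config object or a flat key=value file."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    return Pipeline(config).run(stages)
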