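"""End-to-end orchestration: simulate → extremes → snr → richness → realms
→ analogues → report, behind one validated configuration.

Every numeric analysis constant lives in :mod:`oceanexposure.constants`;
the configuration holds the run-specific choices and is echoed, together
with SHA-256 hashes of every output file, into a manifest so two runs with
the same configuration and seed can be compared file-by-file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import analogues as an
from . import constants as c
from . import extremes as ex
from . import hotspots as hs
from . import realms as rl
from .grids import GriddedField, aggregate_mean, write_netcdf
from .synthetic import FUTURE_ERAS, World, WorldConfig, generate_world

__all__ = ["PipelineConfig", "run_pipeline", "report"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "detect-extremes", "snr", "richness", "realms", "analogues", "report")


@dataclass
class PipelineConfig:
    """Validated knobs of one pipeline run (see constants.py for defaults)."""

    world: WorldConfig = field(default_factory=WorldConfig.demo)
    window_yr: int = c.WINDOW_YEARS
    step_yr: int = c.STEP_YEARS
    threshold: float | str = "calibrate"  # °C/century, or "calibrate"
    control_percentile: float = c.CONTROL_PERCENTILE
    era_boundary_year: int = c.ERA_BOUNDARY_YEAR
    tau: float = c.OCCURRENCE_TAU
    hotspot_percentile: float = c.HOTSPOT_PERCENTILE
    exceedance_percentile: float = c.EXCEEDANCE_PERCENTILE
    exceedance_sweep: tuple[int, int] = c.EXCEEDANCE_SWEEP
    realm_min_cells: int = c.REALM_MIN_CELLS
    bias_overlap: tuple[int, int] = c.BIAS_OVERLAP
    htm_window_ce: tuple[int, int] | None = None  # None -> from HTM_WINDOW_BP
    future_upper_window: tuple[int, int] = c.FUTURE_UPPER_WINDOW
    horizon_years: float = c.REDISTRIBUTION_HORIZON_YEARS
    hovmoller_band_deg: float = 5.0
    tol_degc: float = 0.0
    connectivity: int = 8
    scenarios: tuple[str, ...] = FUTURE_ERAS
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tau <= 1:
            raise ValueError(f"occurrence threshold tau must lie in [0, 1], got {self.tau}")
        for name in ("control_percentile", "hotspot_percentile", "exceedance_percentile"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must lie in (0, 100], got {v}")
        if self.threshold != "calibrate" and not isinstance(self.threshold, (int, float)):
            raise ValueError("threshold must be a number or 'calibrate'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.realm_min_cells < 1 or self.window_yr < 3 or self.step_yr < 1:
            raise ValueError("invalid window/step/min-cells configuration")
        lo, hi = self.exceedance_sweep
        if not (0 < lo <= hi <= 100):
            raise ValueError("exceedance sweep must be an increasing range within (0, 100]")
        if self.world.master_seed != self.master_seed:
            self.world = dataclasses.replace(self.world, master_seed=self.master_seed)

    @classmethod
    def demo(cls, master_seed: int = 0, **overrides) -> "PipelineConfig":
        """Reduced-scale configuration matched to the demo world (its
        2,000-year past needs its own warm-period window)."""
        params = dict(
            world=WorldConfig.demo(master_seed),
            htm_window_ce=(1550, 1750),
            master_seed=master_seed,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        demo = raw.pop("demo", True)
        world_kwargs = raw.pop("world", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("exceedance_sweep", "bias_overlap", "htm_window_ce", "future_upper_window", "scenarios"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        seed = raw.get("master_seed", 0)
        maker = WorldConfig.demo if demo else WorldConfig
        world_kwargs.setdefault("master_seed", seed)
        if "events" in world_kwargs:
            world_kwargs["events"] = tuple(tuple(e) for e in world_kwargs["events"])
        raw["world"] = maker(**world_kwargs)
        base = cls.demo(seed) if demo else cls()
        return dataclasses.replace(base, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world"]["events"] = [list(e) for e in d["world"]["events"]]
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def _windows_to_frame(windows) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(start_year=w.start_year, end_year=w.end_year, global_rate=w.global_rate, is_extreme=w.is_extreme) for w in windows]
    )


def report(summaries: dict) -> dict:
    """Assemble the final JSON report from per-stage summaries.

    Emits global exceedance (plain / unweighted / area-weighted), per-realm
    table location, analogue distance means ± SD per scenario and candidate
    mask, realm-crossing and no-analogue percentages, and the hotspot area
    share by latitude band. Degenerate inputs (no hotspots) are flagged
    instead of dividing by zero.
    """
    out = dict(summaries)
    hot = summaries.get("hotspot_area_by_band", {})
    out["zero_hotspots"] = not hot or sum(hot.values()) == 0
    for block in out.get("exceedance", {}).values():
        for key in ("pct_global_hotspot_exceeding", "unweighted_mean_pct", "area_weighted_mean_pct"):
            v = block.get(key)
            if v is not None and np.isfinite(v) and not 0 <= v <= 100:
                raise AssertionError(f"{key} outside [0, 100]: {v}")
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages, write every output under ``outdir``, and return
    the manifest (also written as manifest.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"config": config.to_dict(), "seed": config.master_seed, "completed_stages": []}

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    state: dict = {}
    try:
        for stage in STAGES:
            _STAGE_FUNCS[stage](config, state, emit)
            manifest["completed_stages"].append(stage)
    except Exception as err:  # noqa: BLE001 - stage name must reach the user
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest["files"] = {str(p.relative_to(outdir)): _sha256(p) for p in written}
        _write_json(outdir / "manifest.json", manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest["files"] = {str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)}
    _write_json(outdir / "manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, state: dict, emit) -> None:
    world = generate_world(config.world, eras=("past", "control", *config.scenarios))
    state["world"] = world
    for era, series in world.series.items():
        emit(f"world_{era}.nc", lambda p, s=series: write_netcdf(p, s))
    emit("realm_ids.nc", lambda p: write_netcdf(p, world.realm_ids, "realm_id"))
    emit("eez_mask.nc", lambda p: write_netcdf(p, GriddedField(world.grid, world.eez_mask.astype(float), "mask"), "eez_mask"))
    truth = {
        era: {"event_windows": [list(w) for w in t.event_windows]}
        for era, t in world.truth.items()
    }
    emit("ground_truth.json", lambda p: _write_json(p, truth))
    log.info("simulated world: %d ocean cells, eras %s", int(world.grid.ocean_mask.sum()), list(world.series))


def _stage_extremes(config: PipelineConfig, state: dict, emit) -> None:
    world: World = state["world"]
    windows = {
        era: ex.rates_for_series(s, config.window_yr, config.step_yr) for era, s in world.series.items()
    }
    if config.threshold == "calibrate":
        threshold = ex.calibrate_threshold(windows["control"], config.control_percentile)
        calibrated = True
    else:
        threshold, calibrated = float(config.threshold), False
    windows = {era: ex.classify_extreme(w, threshold) for era, w in windows.items()}
    state["threshold"] = threshold
    state["windows"] = windows
    for era, w in windows.items():
        emit(f"windows_{era}.csv", lambda p, w=w: _windows_to_frame(w).to_csv(p, index=False))
    emit(
        "threshold.json",
        lambda p: _write_json(
            p, {"threshold_degc_per_century": threshold, "calibrated": calibrated, "percentile": config.control_percentile}
        ),
    )
    log.info("threshold %.4g °C/century (%s)", threshold, "calibrated" if calibrated else "configured")


def _stage_snr(config: PipelineConfig, state: dict, emit) -> None:
    world: World = state["world"]
    past_windows = [w for w in state["windows"]["past"] if w.start_year <= config.era_boundary_year]
    stats = {"past": ex.cell_stats_for_era(world.series["past"], past_windows, "past")}
    deltas = {}
    for scen in config.scenarios:
        future_windows = [w for w in state["windows"][scen] if w.start_year > config.era_boundary_year]
        stats[scen] = ex.cell_stats_for_era(world.series[scen], future_windows, scen)
        deltas[scen] = ex.delta_snr(stats["past"], stats[scen])
    state["stats"], state["deltas"] = stats, deltas

    grid = world.grid
    data = {}
    for era, s in stats.items():
        data[f"trend_{era}"] = (("lat", "lon"), s.trend, {"units": "degC/yr"})
        data[f"variability_{era}"] = (("lat", "lon"), s.variability, {"units": "degC"})
        data[f"snr_{era}"] = (("lat", "lon"), s.snr, {"global_trend_mean": s.global_trend_mean})
    for scen, d in deltas.items():
        data[f"delta_snr_{scen}"] = (("lat", "lon"), d.delta_snr, {})
    ds = xr.Dataset(data, coords={"lat": grid.lat_centers, "lon": grid.lon_centers})
    emit("snr.nc", lambda p: ds.to_netcdf(p, engine="scipy"))


def _stage_richness(config: PipelineConfig, state: dict, emit) -> None:
    world: World = state["world"]
    rich = hs.richness_from_probs(world.species_probs, world.grid_fine, config.tau, exclude=world.data_scarce)
    coarse = aggregate_mean(rich.as_field(), world.grid)
    hot = hs.hotspot_mask(coarse, config.hotspot_percentile)
    state["richness"], state["richness_coarse"], state["hotspots"] = rich, coarse, hot
    emit("richness_fine.nc", lambda p: write_netcdf(p, rich.as_field(), "richness"))
    emit("richness_coarse.nc", lambda p: write_netcdf(p, coarse, "richness"))
    emit("hotspot_mask.nc", lambda p: write_netcdf(p, GriddedField(world.grid, hot.mask.astype(float), "mask"), "hotspot_mask"))
    sens = hs.threshold_sensitivity(world.species_probs, world.grid_fine, exclude=world.data_scarce)
    emit("threshold_sensitivity.csv", lambda p: sens.to_csv(p, index=False))
    log.info("%d hotspot cells at percentile %g", int(hot.mask.sum()), config.hotspot_percentile)


def _stage_realms(config: PipelineConfig, state: dict, emit) -> None:
    world: World = state["world"]
    stats = state["stats"]
    state["realm_tables"], state["exceedance"] = {}, {}
    for scen in config.scenarios:
        table, global_summary = rl.summarize_realms(
            stats["past"].snr,
            stats[scen].snr,
            world.realm_ids.values,
            state["hotspots"].mask,
            world.grid,
            config.exceedance_percentile,
            config.exceedance_sweep,
            config.realm_min_cells,
        )
        state["realm_tables"][scen] = table
        state["exceedance"][scen] = global_summary
        emit(f"realm_summary_{scen}.csv", lambda p, t=table: t.to_csv(p, index=False))
    emit("global_exposure.json", lambda p: _write_json(p, state["exceedance"]))


def _stage_analogues(config: PipelineConfig, state: dict, emit) -> None:
    world: World = state["world"]
    graph = an.build_sea_graph(world.grid, config.connectivity)
    hot = state["hotspots"].mask
    state["analogue_summaries"] = {}
    for scen in config.scenarios:
        corrected = an.delta_bias_correct(world.series["past"], world.series[scen], config.bias_overlap)
        htm_up = an.htm_upper_temperature(corrected, window_ce=config.htm_window_ce)
        fut_up = an.future_upper_temperature(world.series[scen], config.future_upper_window)
        for label, mask in (("all", None), ("eez", world.eez_mask)):
            results = an.nearest_analogue(
                hot, htm_up, fut_up, graph, mask, config.tol_degc, scen, restricted_to_eez=label == "eez"
            )
            crossing = an.realm_crossing_summary(results, world.realm_ids.values)
            rates = an.redistribution_rate(results, config.horizon_years)
            rows = []
            for r in results:
                fi, fj = r.focal_cell
                ti, tj = r.target_cell if r.has_analogue else (None, None)
                rows.append(
                    dict(
                        focal_lat=world.grid.lat_centers[fi],
                        focal_lon=world.grid.lon_centers[fj],
                        target_lat=world.grid.lat_centers[ti] if ti is not None else np.nan,
                        target_lon=world.grid.lon_centers[tj] if tj is not None else np.nan,
                        distance_km=r.sea_distance_km,
                        rate_km_yr=r.rate_km_per_yr,
                        crosses_realm=r.crosses_realm,
                        no_analogue=not r.has_analogue,
                    )
                )
            emit(f"analogues_{scen}_{label}.csv", lambda p, rows=rows: pd.DataFrame(rows).to_csv(p, index=False))
            dists = np.array([r.sea_distance_km for r in results if r.has_analogue])
            state["analogue_summaries"][f"{scen}_{label}"] = {
                "mean_distance_km": float(dists.mean()) if dists.size else np.nan,
                "sd_distance_km": float(dists.std(ddof=1)) if dists.size > 1 else np.nan,
                "mean_rate_km_per_yr": float(np.nanmean(rates)) if np.isfinite(rates).any() else np.nan,
                **crossing,
            }
        hov = an.hovmoller(corrected, hot, config.hovmoller_band_deg)
        hov_f = an.hovmoller(world.series[scen], hot, config.hovmoller_band_deg)
        for tag, h in (("past", hov), (scen, hov_f)):
            frame = pd.DataFrame(
                h.values, index=pd.Index(h.band_edges[:-1], name="band_south_edge"), columns=h.years
            )
            emit(f"hovmoller_{scen}_{tag}.csv", lambda p, f=frame: f.to_csv(p))
    emit("analogue_summary.json", lambda p: _write_json(p, state["analogue_summaries"]))


def _stage_report(config: PipelineConfig, state: dict, emit) -> None:
    world: World = state["world"]
    hot = state["hotspots"].mask
    area = world.grid.cell_area
    lat = np.broadcast_to(world.grid.lat_centers[:, None], world.grid.shape)
    bands = {"tropical_|lat|<=30": 30, "mid_30-50": 50, "high_>50": 90}
    share, lo = {}, 0.0
    total = float(area[hot].sum()) if hot.any() else 0.0
    for name, hi in bands.items():
        sel = hot & (np.abs(lat) > lo) & (np.abs(lat) <= hi)
        share[name] = 100.0 * float(area[sel].sum()) / total if total else 0.0
        lo = hi
    summaries = {
        "threshold_degc_per_century": state["threshold"],
        "n_extreme_windows_past": sum(
            w.is_extreme for w in state["windows"]["past"] if w.start_year <= config.era_boundary_year
        ),
        "exceedance": state["exceedance"],
        "analogues": state["analogue_summaries"],
        "hotspot_area_by_band": share,
        "realm_overlap_by_band": {
            scen: {
                band: float(t[t.latitude_band == band]["overlap"].mean())
                for band in ("tropical_mid", "high")
            }
            for scen, t in state["realm_tables"].items()
        },
    }
    state["report"] = report(summaries)
    emit("report.json", lambda p: _write_json(p, state["report"]))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "detect-extremes": _stage_extremes,
    "snr": _stage_snr,
    "richness": _stage_richness,
    "realms": _stage_realms,
    "analogues": _stage_analogues,
    "report": _stage_report,
}
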