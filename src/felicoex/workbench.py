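"""Configuration and end-to-end pipeline orchestration.

Three pipelines mirror the study's analysis flow on any conforming dataset:

- SCR: event filtering → closure-window restriction → RPSV-based buffer →
  model-set fit → mask adequacy → sex-ratio LRT → HRCIW.
- Occupancy: covariate scaling and correlation screening → spatial model set →
  lag-covariate augmentation of the winner → prediction curves.
- Diet: per-predator profiles, niche indices, adequacy curves, aggregates.

Reports are flat JSON/CSV (plotting is left to downstream tooling) and embed
the package version and a hash of the configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, captrap, ctmso, diet, scr

log = logging.getLogger("felicoex")


@dataclass
class PipelineConfig:
    """Paths and tunables for the three pipelines (YAML-loadable)."""

    captures_csv: str | None = None
    traps_csv: str | None = None
    events_csv: str | None = None
    stations_csv: str | None = None
    scats_csv: str | None = None
    traits_csv: str | None = None
    out_dir: str | None = None
    detection_gap_min: float = 1.0
    capture_gap_min: float = 30.0
    buffer_mult: float = 4.5
    mask_spacing_km: float = 1.0
    closure_alpha: float = 0.05
    scr_models: tuple = ("null", "g0sex", "sigsex", "both")
    occ_models: tuple = ("dist", "site", "prey")
    quad_minutes: float = 60.0
    boot_iterations: int = 1000
    diet_iterations: int = 10_000
    corr_threshold: float = 0.6
    seed: int = 1
    species_pair: tuple = ("golden_cat", "leopard")
    u_max_hours: float = 72.0

    def digest(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    flat = {}
    for key, value in raw.items():
        if isinstance(value, dict):
            flat.update(value)
        else:
            flat[key] = value
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(flat) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k in ("scr_models", "occ_models", "species_pair"):
        if k in flat and isinstance(flat[k], list):
            flat[k] = tuple(flat[k])
    return PipelineConfig(**flat)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Stage:
    """Context manager logging per-stage wall time."""

    def __init__(self, name):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
            return False
        log.error("stage %s: failed after %.2fs (%s)", self.name, dt, exc)
        raise PipelineError(self.name, exc) from exc


def _require(path, what) -> Path:
    if path is None:
        raise FileNotFoundError(f"{what} path not configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def _report_header(config: PipelineConfig) -> dict:
    return {"package_version": __version__, "config_hash": config.digest()}


def _write_report(report: dict, out_dir, name: str) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / name, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer, np.bool_)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------


def run_scr_pipeline(config: PipelineConfig) -> dict:
    """Density estimation pipeline; returns (and optionally writes) a report
    mirroring a survey-summary table's SCR block."""
    report = _report_header(config)
    with _Stage("load"):
        captures = pd.read_csv(_require(config.captures_csv, "captures"))
        traps = pd.read_csv(_require(config.traps_csv, "traps"))
        hist = scr.capture_history_from_tables(captures, traps)
    with _Stage("closure"):
        z, p = scr.closure_test(hist)
        first, last = scr.longest_closed_window(hist, alpha=config.closure_alpha)
        restricted = scr.restrict_to_window(hist, first, last)
        report["closure"] = {
            "z": z, "p": p, "window": [int(first), int(last)],
            "occasions_retained": restricted.n_occasions,
            "capture_events": int(len(restricted.detections)),
            "individuals": restricted.n_individuals,
        }
    with _Stage("buffer"):
        movement = scr.rpsv(restricted)
        buffer_km = config.buffer_mult * movement / 1000.0
        mask = scr.build_mask(restricted.traps, buffer_km, config.mask_spacing_km)
        report["rpsv_m"] = movement
        report["buffer_km"] = buffer_km
        report["mask_points"] = mask.n_points
    with _Stage("fit"):
        fits = scr.fit_scr(restricted, mask, models=list(config.scr_models))
        report["model_table"] = [f.summary() for f in fits]
        best = next((f for f in fits if f.converged), None)
        if best is None:
            raise RuntimeError("no SCR model converged")
        report["best_model"] = best.summary()
    with _Stage("mask_adequacy"):
        adequacy = scr.mask_adequacy(
            restricted, best.spec, start_buffer_km=buffer_km,
            spacing_km=config.mask_spacing_km, max_steps=5,
        )
        report["mask_adequacy"] = adequacy
    with _Stage("sex_ratio"):
        if best.spec.pmix_free:
            from dataclasses import replace

            fixed_spec = replace(best.spec, pmix_free=False, name=best.spec.name + "_pmix0.5")
            fixed = scr.fit_single(restricted, mask, fixed_spec, compute_se=False)
            chi2, p_sex = scr.sex_ratio_lrt(best, fixed)
            report["sex_ratio"] = {"pmix": best.pmix, "chi2": chi2, "p": p_sex}
    with _Stage("precision"):
        if best.ci_D:
            report["hrciw_pct"] = scr.hrciw(best.D, *best.ci_D)
    _write_report(report, config.out_dir, "scr_report.json")
    return report


def _station_data_from_tables(
    events: pd.DataFrame, stations: pd.DataFrame, config: PipelineConfig
) -> tuple[ctmso.CTMSOData, pd.DataFrame]:
    """Assemble occupancy-model inputs from event and station tables.

    Detection times become decimal hours from each station's activation
    (timestamps are interpreted in local time; time of day is preserved by
    anchoring each station's clock at the midnight preceding activation).
    """
    sp1, sp2 = config.species_pair
    events = events.copy()
    events["timestamp"] = pd.to_datetime(events["timestamp"])
    covs = pd.DataFrame(
        {"dist_linear": stations["dist_linear_km"].astype(float).to_numpy()}
    )
    if (events["species"] == "prey").any():
        # prey RAI computed from prey-tagged events when provided
        effort = captrap.effort_from_stations(stations)
        rai_tab = captrap.rai(events, effort, "prey", per_station=True)
        covs["prey_rai"] = rai_tab["rai"].fillna(0.0).to_numpy()
    elif "prey_rai" in stations.columns and stations["prey_rai"].std(ddof=1) > 0:
        covs["prey_rai"] = stations["prey_rai"].astype(float).to_numpy()
    if "site" in stations.columns:
        sites = pd.factorize(stations["site"])[0].astype(float)
        if len(np.unique(sites)) > 1:
            covs["site"] = sites
    scaled, corr = captrap.scale_covariates(covs, config.corr_threshold)
    flagged = corr.loc[corr["flagged"]]
    if not flagged.empty:
        log.warning("covariate correlations above threshold:\n%s", flagged)
    station_data = []
    for j, row in stations.reset_index(drop=True).iterrows():
        anchor = pd.Timestamp(row["active_start"]).normalize()
        t1 = (pd.Timestamp(row["active_end"]) - anchor).total_seconds() / 3600.0 + 24.0
        times = {}
        for sp in (sp1, sp2):
            sel = events[(events["station_id"] == row["station_id"]) & (events["species"] == sp)]
            times[sp] = ((sel["timestamp"] - anchor).dt.total_seconds() / 3600.0).to_numpy()
        station_data.append(
            ctmso.StationData(
                station_id=row["station_id"],
                covariates={c: float(scaled[c].iloc[j]) for c in scaled.columns},
                window=(0.0, float(t1)),
                times=times,
            )
        )
    data = ctmso.CTMSOData(stations=station_data, species=(sp1, sp2), u_max=config.u_max_hours)
    return data, corr


def run_occu_pipeline(config: PipelineConfig) -> dict:
    """Two-species occupancy pipeline with two-stage model selection."""
    report = _report_header(config)
    with _Stage("load"):
        events = pd.read_csv(_require(config.events_csv, "events"))
        stations = pd.read_csv(_require(config.stations_csv, "stations"))
        sp1, sp2 = config.species_pair
        if not ((events["species"] == sp1) | (events["species"] == sp2)).any():
            raise ValueError("no detections of either focal species")
        data, corr = _station_data_from_tables(events, stations, config)
        report["covariate_correlations"] = corr
    with _Stage("spatial_selection"):
        have_site = all("site" in s.covariates for s in data.stations)
        have_prey = all("prey_rai" in s.covariates for s in data.stations)
        models = [
            m
            for m in ctmso.spatial_model_set(site=have_site, prey=have_prey)
            if m.name in config.occ_models
        ]
        staged = ctmso.two_stage_fit(data, models, quad_minutes=config.quad_minutes)
        report["aic_table"] = [
            {"model": f.model.name, "K": f.K, "logL": f.logL, "AIC": f.aic, "dAIC": f.delta_aic,
             "converged": f.converged}
            for f in staged["spatial_fits"] + [staged["lag_fit"]]
        ]
        final = staged["final"]
        report["final_model"] = final.model.name
        report["coefficients"] = final.coef_table()
    with _Stage("curves"):
        out = Path(config.out_dir) if config.out_dir else None
        if out:
            out.mkdir(parents=True, exist_ok=True)
        prey = data.covariate_values("prey_rai") if have_prey else np.zeros(1)
        levels = {"low": float(np.quantile(prey, 0.15)), "high": float(np.quantile(prey, 0.85))}
        curve_files = []
        for label, lev in levels.items():
            cur = ctmso.occupancy_curves(
                final, data, covariate="dist_linear", fix={"prey_rai": lev},
                n_boot=config.boot_iterations, seed=config.seed,
            )
            if out is not None:
                f = out / f"occupancy_vs_distance_prey_{label}.csv"
                cur.to_csv(f, index=False)
                curve_files.append(str(f))
        for sp, cond in [(sp2, None), (sp1, "co-occurring"), (sp1, "alone")]:
            act = ctmso.activity_curve(final, sp, condition=cond)
            bins = ctmso.binned_detection_proportions(
                final, sp, condition=cond, n_boot=min(config.boot_iterations, 500),
                seed=config.seed,
            )
            if out is not None:
                tag = f"{sp}_{cond or 'all'}".replace(" ", "")
                act.to_csv(out / f"activity_{tag}.csv", index=False)
                bins.to_csv(out / f"binned_{tag}.csv", index=False)
                curve_files += [str(out / f"activity_{tag}.csv"), str(out / f"binned_{tag}.csv")]
        report["curve_files"] = curve_files
    _write_report(report, config.out_dir, "occu_report.json")
    return report


def run_diet_pipeline(config: PipelineConfig) -> dict:
    """Scat-diet pipeline: profiles, indices, adequacy, aggregates."""
    report = _report_header(config)
    with _Stage("load"):
        scats = pd.read_csv(_require(config.scats_csv, "scats"))
        traits = pd.read_csv(_require(config.traits_csv, "prey traits")) if config.traits_csv else diet.load_prey_traits()
        if scats.empty:
            raise ValueError("scat table is empty")
    with _Stage("profiles"):
        predators = list(pd.unique(scats["predator"]))
        profiles = {}
        for pred in predators:
            sub = scats[scats["predator"] == pred]
            prof = diet.diet_profile(sub, traits, pred, diet.PREDATOR_ABM.get(pred))
            profiles[pred] = prof
            report[pred] = {
                "n_scats": prof.n_scats,
                "n_items": prof.n_items,
                "mean_items_per_scat": prof.mean_items_per_scat,
                "taxa": prof.taxa,
                "groups": prof.groups,
                "size_classes": prof.size_classes,
            }
    with _Stage("indices"):
        for pred, prof in profiles.items():
            p = prof.proportions("fo")
            report[pred]["levins_standardized"] = diet.levins_standardized(
                p.to_numpy(), len(p)
            ) if len(p) > 1 else 0.0
        if len(profiles) == 2:
            a, b = (profiles[p].proportions("fo") for p in predators)
            report["pianka_overlap_fo"] = diet.pianka(a, b)
    with _Stage("adequacy"):
        for pred in predators:
            sub = scats[scats["predator"] == pred]
            if sub["scat_id"].nunique() >= 2:
                curve = diet.accumulation_curve(
                    sub, iterations=config.diet_iterations, seed=config.seed
                )
                report[pred]["accumulation"] = curve
                report[pred]["sampling_adequate"] = curve.attrs["adequate"]
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pred, prof in profiles.items():
            prof.taxa.to_csv(out / f"diet_{pred}_taxa.csv", index=False)
            prof.groups.to_csv(out / f"diet_{pred}_groups.csv", index=False)
            prof.size_classes.to_csv(out / f"diet_{pred}_size_classes.csv", index=False)
    _write_report(report, config.out_dir, "diet_report.json")
    return report
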