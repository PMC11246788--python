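"""End-to-end orchestration: simulate -> climate -> observations -> GCC ->
phenometrics -> models/prediction -> development rates.

Each stage reads/writes plain CSV (comma-separated, UTF-8, header row,
empty fields for missing values, ISO-8601 dates) under a run directory and
logs its input/output row counts; a ``manifest.json`` records the
configuration hash and per-stage counts so a run can be audited and
reproduced.  All randomness flows from the single scenario seed, so a rerun
with the same configuration is byte-identical.
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

from . import microclimate, models, pdr, phenocam, phenology_obs, phenometrics
from . import synthetic_data as synth

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; unset paths default into ``run_dir``."""

    run_dir: str = "nivophen_run"
    seed: int = 0
    simulate: bool = True
    noise_sd_phase: float = 1.5
    # microclimate
    threshold_c: float = 2.0
    base_c: float = 0.0
    persistence_days: int = 1
    # phenocam
    window_days: int = 4
    percentile: float = 90.0
    max_exposure_s: float = 50.0
    min_exposure_ratio: float = 2.0
    # phenometrics
    baseline_frac: float = 0.1
    # models
    predictors: tuple = ("gdd", "dfsm", "doy")
    random_effects: tuple = ("plot", "year")
    train_site: str = "late"
    target_site: str = "early"
    # pdr
    pdr_axis: str = "gdd"
    pdr_mode: str = "ols"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("predictors", "random_effects"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def wrap(fn):
        def inner(ctx, *a, **k):
            try:
                out = fn(ctx, *a, **k)
            except Exception as exc:        # noqa: BLE001 - re-raise with stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return out
        inner.__name__ = fn.__name__
        return inner
    return wrap


@_stage("simulate")
def stage_simulate(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    scenario = ctx.get("scenario") or synth.default_scenario(
        seed=cfg.seed, noise_sd_phase=cfg.noise_sd_phase)
    ctx["scenario"] = scenario
    paths = synth.write_scenario(scenario, ctx["data_dir"], with_camera=True)
    ctx["counts"]["simulate"] = {
        "files": len(paths),
        "sites": len(scenario.sites),
        "years": len(scenario.years),
    }


@_stage("climate")
def stage_climate(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    data_dir = Path(ctx["data_dir"])
    files = sorted(data_dir.glob("soil_temp_*.csv"))
    if not files:
        raise FileNotFoundError(
            f"no soil_temp_*.csv files under {data_dir}")
    alignments, seasons = [], []
    for path in files:
        site_name, year = path.stem.split("_")[2], int(path.stem.split("_")[3])
        table = pd.read_csv(path, parse_dates=["timestamp"])
        for plot_id, g in table.groupby("plot_id"):
            series = microclimate.TemperatureSeries.from_frame(
                g, plot_id=str(plot_id))
            align = microclimate.align_climate(
                series, threshold_c=cfg.threshold_c, base_c=cfg.base_c,
                persistence_days=cfg.persistence_days)
            align["site"], align["year"] = site_name, year
            alignments.append(align)
            dosm = int(align["dosm"].iloc[0])
            means = series.daily_means()
            doys = means.index.dayofyear.to_numpy()
            seasons.append(microclimate.SnowSeason(
                plot_id=str(plot_id), year=year, dosm=dosm,
                snow_cover_days=int((doys < dosm).sum()),
                mean_soil_temp=round(float(means[doys >= dosm].mean()), 1),
                site=site_name))
    climate = pd.concat(alignments, ignore_index=True)
    climate.to_csv(ctx["run_dir"] / "climate_alignment.csv", index=False)
    pd.DataFrame([dataclasses.asdict(s) for s in seasons]).to_csv(
        ctx["run_dir"] / "snow_seasons.csv", index=False)
    ctx["climate"] = climate
    ctx["seasons"] = seasons
    ctx["counts"]["climate"] = {"plot_years": len(seasons),
                                "alignment_rows": len(climate)}


@_stage("obs")
def stage_obs(ctx: dict) -> None:
    data_dir = Path(ctx["data_dir"])
    obs = pd.read_csv(data_dir / "pheno_obs.csv", parse_dates=["date"])
    scale = phenology_obs.PhenophaseScale.default()
    for row in obs.itertuples():
        phenology_obs.validate_observation(
            phenology_obs.PhenoObservation(
                site=row.site, plot=row.plot, subplot=row.subplot,
                species=row.species, date=row.date, bbch=row.bbch),
            scale)
    medians = phenology_obs.plot_medians(obs)
    aligned = phenology_obs.align_observations(medians, ctx["climate"])
    aligned["year"] = pd.to_datetime(aligned["date"]).dt.year
    aligned.to_csv(ctx["run_dir"] / "aligned_observations.csv", index=False)
    ctx["aligned"] = aligned
    ctx["counts"]["obs"] = {"observations": len(obs),
                            "plot_medians": len(aligned)}


@_stage("gcc")
def stage_gcc(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    data_dir = Path(ctx["data_dir"])
    rules = phenocam.QCRules(max_exposure_s=cfg.max_exposure_s,
                             min_exposure_ratio=cfg.min_exposure_ratio)
    daily_frames = []
    n_images = n_rejected = 0
    for path in sorted(data_dir.glob("roi_means_*.csv")):
        site_name, year = path.stem.split("_")[2], int(path.stem.split("_")[3])
        table = pd.read_csv(path, parse_dates=["timestamp"])
        records = [phenocam.ImageRecord(
            filename=f"{site_name}_{r.timestamp:%Y%m%d_%H%M}.png",
            timestamp=r.timestamp, exposure_time_s=r.exposure_time_s,
            exposure_ratio=r.exposure_ratio, roi_mean_rgb=(r.r, r.g, r.b))
            for r in table.itertuples()]
        result = phenocam.extract_gcc_series(
            records, rules=rules, window_days=cfg.window_days,
            percentile=cfg.percentile)
        daily = result["daily"]
        daily["site"], daily["year"] = site_name, year
        daily["gcc_max_daily"] = result["daily_max"]["gcc_smoothed"]
        daily_frames.append(daily)
        n_images += len(records)
        n_rejected += len(result["rejections"])
    if not daily_frames:
        ctx["gcc_daily"] = pd.DataFrame()
        ctx["counts"]["gcc"] = {"images": 0, "rejected": 0}
        return
    gcc_daily = pd.concat(daily_frames, ignore_index=True)
    gcc_daily.to_csv(ctx["run_dir"] / "gcc_daily.csv", index=False)
    ctx["gcc_daily"] = gcc_daily
    ctx["counts"]["gcc"] = {"images": n_images, "rejected": n_rejected,
                            "days": len(gcc_daily)}


@_stage("metrics")
def stage_metrics(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    rows = []
    for (site_name, year), g in ctx["gcc_daily"].groupby(["site", "year"]):
        m = phenometrics.extract_season_metrics(
            g, baseline_frac=cfg.baseline_frac)
        rows.append({"site": site_name, "year": year, **m.as_dict()})
    table = pd.DataFrame(rows)
    table.to_csv(ctx["run_dir"] / "season_metrics.csv", index=False)
    ctx["season_metrics"] = table
    ctx["counts"]["metrics"] = {"site_years": len(table)}


@_stage("fit")
def stage_fit(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    aligned = ctx["aligned"]
    comparisons, fits = [], {}
    for species, g in aligned.groupby("species"):
        for site_name, gs in g.groupby("site"):
            species_fits = {
                p: models.fit_phenophase_smooth(
                    gs, predictor=p, random_effects=cfg.random_effects)
                for p in cfg.predictors}
            comp = models.compare_predictors(species_fits)
            for r in comp["table"].itertuples():
                comparisons.append({"species": species, "site": site_name,
                                    "predictor": r.predictor, "r2": r.r2,
                                    "aic": r.aic})
            if site_name == cfg.train_site:
                fits[species] = species_fits["gdd"]
    pd.DataFrame(comparisons).to_csv(
        ctx["run_dir"] / "model_comparison.csv", index=False)
    ctx["fits"] = fits
    ctx["counts"]["fit"] = {"models": len(comparisons)}


@_stage("predict")
def stage_predict(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    aligned = ctx["aligned"]
    target = aligned[aligned["site"] == cfg.target_site]
    predictions, assessments = [], []
    for species, fit in ctx["fits"].items():
        sub = target[target["species"] == species]
        if sub.empty:
            continue
        pred = models.predict_cross_site(fit, sub)
        out = sub[["species", "site", "plot", "date", "gdd",
                   "median_phase"]].reset_index(drop=True)
        out = pd.concat([out, pred.reset_index(drop=True)], axis=1)
        predictions.append(out)
        ass = models.assess_predictions(out["predicted"], out["median_phase"])
        assessments.append({"species": species,
                            "pearson_r": ass["pearson_r"],
                            "mean_abs_error_phases": ass["mean_abs_error_phases"],
                            "n": len(out)})
    pred_table = (pd.concat(predictions, ignore_index=True) if predictions
                  else pd.DataFrame(columns=["species", "site", "plot", "date",
                                             "gdd", "median_phase",
                                             "predicted"]))
    pred_table.to_csv(ctx["run_dir"] / "predictions.csv", index=False)
    assessment = pd.DataFrame(assessments)
    assessment.to_csv(ctx["run_dir"] / "prediction_assessment.csv", index=False)
    ctx["assessment"] = assessment
    ctx["counts"]["predict"] = {"rows": sum(len(p) for p in predictions)}


@_stage("pdr")
def stage_pdr(ctx: dict) -> None:
    cfg: PipelineConfig = ctx["config"]
    estimates = pdr.compute_pdr_table(ctx["aligned"], axis=cfg.pdr_axis,
                                      mode=cfg.pdr_mode)
    estimates.to_csv(ctx["run_dir"] / "pdr_estimates.csv", index=False)
    comparison = pdr.compare_sites_table(estimates, cfg.train_site,
                                         cfg.target_site)
    comparison.to_csv(ctx["run_dir"] / "pdr_comparison.csv", index=False)
    ctx["pdr_estimates"] = estimates
    ctx["pdr_comparison"] = comparison
    ctx["counts"]["pdr"] = {"estimates": len(estimates)}


STAGES = {
    "simulate": stage_simulate,
    "climate": stage_climate,
    "obs": stage_obs,
    "gcc": stage_gcc,
    "metrics": stage_metrics,
    "fit": stage_fit,
    "predict": stage_predict,
    "pdr": stage_pdr,
}


def analyze_scenario(scenario, threshold_c: float = 2.0, base_c: float = 0.0,
                     with_camera: bool = False) -> dict:
    """Run the analysis chain on a scenario entirely in memory.

    Simulates the scenario, detects melt days from the simulated loggers
    (the estimation path, not the generator truth), accumulates GDD, builds
    plot-median phenophase series and joins the covariates.  Returns a dict
    with ``aligned`` (plot-median table with doy/dfsm/gdd), ``melt``
    (detected vs constructed melt day per plot-year), and the raw scenario
    data under ``data``.
    """
    data = synth.simulate_scenario(scenario, with_camera=with_camera)
    alignments, melt_rows = [], []
    for (site_name, year, plot_id), series in data["temperatures"].items():
        align = microclimate.align_climate(series, threshold_c=threshold_c,
                                           base_c=base_c)
        align["site"], align["year"] = site_name, year
        alignments.append(align)
        melt_rows.append({"site": site_name, "year": year, "plot": plot_id,
                          "detected": int(align["dosm"].iloc[0])})
    climate = pd.concat(alignments, ignore_index=True)
    melt = pd.DataFrame(melt_rows).merge(
        data["melt_truth"], on=["site", "year", "plot"])
    medians = phenology_obs.plot_medians(data["observations"])
    aligned = phenology_obs.align_observations(medians, climate)
    aligned["year"] = pd.to_datetime(aligned["date"]).dt.year
    return {"aligned": aligned, "melt": melt, "climate": climate,
            "data": data}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None,
                 scenario=None) -> dict:
    """Execute the pipeline (or a prefix of it) and write a manifest.

    Returns the run context with every stage's in-memory tables.  On stage
    failure a :class:`PipelineError` names the stage; outputs of completed
    stages remain on disk alongside the manifest.
    """
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    data_dir = run_dir / "data"
    ctx: dict = {"config": config, "run_dir": run_dir, "data_dir": data_dir,
                 "counts": {}, "scenario": scenario}
    order = stages or ([s for s in STAGES if s != "simulate"]
                       if not config.simulate else list(STAGES))
    try:
        for name in order:
            logger.info("running stage %s", name)
            STAGES[name](ctx)
    finally:
        manifest = {
            "config": dataclasses.asdict(config),
            "config_hash": config.digest(),
            "stage_counts": ctx["counts"],
            "stages_run": [s for s in order if s in ctx["counts"]],
        }
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return ctx
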