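"""Synthetic snowbed scenario generator.

Generates datasets with the statistical structure the downstream analysis
assumes, so the full pipeline is testable without field data:

* hourly soil temperature per plot — a snow-insulated plateau (uniform in
  [-0.5, 1.5] °C, strictly below the 2 °C melt threshold) ending on a
  configurable melt day, followed by a diurnal sinusoid around the summer
  mean with day-to-day weather variation and hourly noise;
* ordinal BBCH observations per subplot — each species follows a monotone
  development program, linear in accumulated GDD after a species-specific
  onset lag, snapped to the nearest valid scale code, with independent
  subplot noise; plants are invisible (code 0) before the onset lag is met;
* phenocam frames — hourly images whose ROI-mean GCC traces a
  rise-plateau-decline season curve through prescribed event days
  (grey-soil baseline near 1/3, plateau 0.42-0.46), with configurable
  over-exposure, fog and out-of-window artifacts.

The default scenario mirrors the monitored design: two sites (late and
early snowmelt) x 3 years, 8 + 4 plots, 16 subplots each (one reduced to
14), five species spanning onset lags up to 250 GDD and development rates
0.06-0.09 BBCH per GDD.

Every draw derives from a single scenario seed through named-stream
spawning, so a fixed seed reproduces the whole scenario byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .microclimate import TemperatureSeries, compute_gdd
from .phenology_obs import PhenophaseScale, DEFAULT_MORPHOTYPE_MAP
from .phenocam import ImageRecord
from .phenometrics import SeasonMetrics

SEASON_START_DOY = 120
SEASON_END_DOY = 290
OBS_START_OFFSET_DAYS = 3      # first survey shortly after melt-out


class ScenarioError(ValueError):
    """Raised for inconsistent scenario configuration."""


def _stream(seed: int, *keys) -> np.random.Generator:
    """Deterministic named RNG stream derived from the scenario seed."""
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


@dataclass
class SiteSpec:
    """One study site: plot layout, melt calendar and summer climate."""

    name: str
    n_plots: int
    melt_doy_by_year: dict
    subplots_per_plot: int = 16
    reduced_plots: dict = field(default_factory=dict)   # plot index -> subplots
    summer_mean_temp: float = 10.0
    summer_mean_by_year: dict = field(default_factory=dict)
    diurnal_amplitude: float = 4.0
    hourly_noise_sd: float = 0.3
    daily_temp_sd: float = 2.0
    plot_melt_jitter_days: int = 2

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ScenarioError("n_plots must be >= 1")
        for year, doy in self.melt_doy_by_year.items():
            if not 1 <= doy <= 366:
                raise ScenarioError(f"melt_doy {doy} for {year} outside [1, 366]")
        if self.subplots_per_plot not in (14, 16):
            raise ScenarioError("subplots_per_plot must be 14 or 16")

    def summer_mean(self, year: int) -> float:
        return float(self.summer_mean_by_year.get(year, self.summer_mean_temp))

    def subplots(self, plot_index: int) -> int:
        return int(self.reduced_plots.get(plot_index, self.subplots_per_plot))

    def plot_melt_doy(self, year: int, plot_index: int, seed: int) -> int:
        """Plot-level melt day: site melt day plus a fixed per-plot jitter."""
        if year not in self.melt_doy_by_year:
            raise ScenarioError(f"no melt day configured for {self.name} {year}")
        base = int(self.melt_doy_by_year[year])
        if self.plot_melt_jitter_days == 0:
            return base
        rng = _stream(seed, "melt_jitter", self.name, year, plot_index)
        j = int(rng.integers(-self.plot_melt_jitter_days,
                             self.plot_melt_jitter_days + 1))
        return base + j


@dataclass
class SpeciesProgram:
    """Monotone development program: phase = rate * (GDD - onset lag)."""

    species: str
    morphotype: str = "P"
    onset_lag_gdd: float = 0.0
    rate_phase_per_gdd: float = 0.08
    senescence_phase: int = 59

    def __post_init__(self) -> None:
        if self.onset_lag_gdd < 0:
            raise ScenarioError("onset_lag_gdd must be >= 0")
        if self.rate_phase_per_gdd <= 0:
            raise ScenarioError("rate_phase_per_gdd must be > 0")

    def true_phase(self, gdd: np.ndarray) -> np.ndarray:
        """Noise-free continuous development level (0 before onset)."""
        gdd = np.asarray(gdd, dtype=float)
        ramp = self.rate_phase_per_gdd * (gdd - self.onset_lag_gdd)
        return np.where(gdd < self.onset_lag_gdd, 0.0,
                        np.clip(ramp, 0.0, self.senescence_phase))


@dataclass
class CameraSpec:
    """Phenocam emulation parameters."""

    image_size: tuple = (64, 64)
    baseline_gcc: float = 1.0 / 3.0
    plateau_gcc: float = 0.45
    gcc_noise_sd: float = 0.0
    artifact_rates: dict = field(
        default_factory=lambda: {"overexposed": 0.0, "fog": 0.0,
                                 "out_of_window": 0.0})

    def __post_init__(self) -> None:
        if not self.plateau_gcc > self.baseline_gcc:
            raise ScenarioError("plateau_gcc must exceed baseline_gcc")
        for name, p in self.artifact_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ScenarioError(f"artifact rate {name} outside [0, 1]")


@dataclass
class ScenarioConfig:
    """Full scenario: sites, years, species programs, cadence and noise."""

    sites: list
    years: list
    species: list
    seed: int = 0
    obs_interval_days: float = 14.0
    noise_sd_phase: float = 1.5
    camera: CameraSpec = field(default_factory=CameraSpec)

    def __post_init__(self) -> None:
        if self.obs_interval_days <= 0:
            raise ScenarioError("obs_interval_days must be > 0")
        if self.noise_sd_phase < 0:
            raise ScenarioError("noise_sd_phase must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sites = [SiteSpec(**{**s, "melt_doy_by_year":
                             {int(k): v for k, v in s["melt_doy_by_year"].items()}})
                 for s in raw["sites"]]
        species = [SpeciesProgram(**s) for s in raw.get("species", [])]
        camera = CameraSpec(**raw.get("camera", {}))
        return cls(sites=sites, years=[int(y) for y in raw["years"]],
                   species=species, seed=int(raw.get("seed", 0)),
                   obs_interval_days=float(raw.get("obs_interval_days", 14)),
                   noise_sd_phase=float(raw.get("noise_sd_phase", 1.5)),
                   camera=camera)

    def to_yaml(self, path) -> None:
        raw = {
            "sites": [asdict(s) for s in self.sites],
            "years": list(self.years),
            "species": [asdict(s) for s in self.species],
            "seed": self.seed,
            "obs_interval_days": self.obs_interval_days,
            "noise_sd_phase": self.noise_sd_phase,
            "camera": asdict(self.camera),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_species_programs() -> list[SpeciesProgram]:
    """The five monitored species with realistic onset lags and rates.

    Rates sit in the observed 0.06-0.095 BBCH/GDD band; the annual carries
    a 250-GDD germination delay and compensates with a fast rate.
    """
    return [
        SpeciesProgram("Salix herbacea", "P", 0.0, 0.089),
        SpeciesProgram("Gnaphalium supinum", "P", 40.0, 0.060),
        SpeciesProgram("Poa alpina", "G", 60.0, 0.080),
        SpeciesProgram("Veronica alpina", "P", 80.0, 0.068),
        SpeciesProgram("Euphrasia minima", "A", 250.0, 0.082),
    ]


def default_scenario(seed: int = 0, noise_sd_phase: float = 1.5,
                     camera: CameraSpec | None = None) -> ScenarioConfig:
    """The monitored design: late site (8 plots) vs early site (4 plots),
    3 years, 16 subplots (one early plot reduced to 14)."""
    late = SiteSpec(name="late", n_plots=8,
                    melt_doy_by_year={2018: 194, 2019: 182, 2020: 191},
                    summer_mean_temp=9.8,
                    summer_mean_by_year={2018: 8.6, 2019: 8.8, 2020: 10.2})
    early = SiteSpec(name="early", n_plots=4,
                     melt_doy_by_year={2018: 164, 2019: 193, 2020: 175},
                     reduced_plots={3: 14},
                     summer_mean_temp=10.4,
                     summer_mean_by_year={2018: 11.1, 2019: 8.8, 2020: 10.6})
    return ScenarioConfig(sites=[late, early], years=[2018, 2019, 2020],
                          species=default_species_programs(), seed=seed,
                          noise_sd_phase=noise_sd_phase,
                          camera=camera or CameraSpec())


# ---------------------------------------------------------------------------
# soil temperature


def simulate_soil_temperature(site: SiteSpec, year: int, seed: int,
                              plot_index: int = 0,
                              melt_doy: int | None = None) -> TemperatureSeries:
    """Hourly soil temperature for one plot-year.

    Before the melt day: uniform draws in [-0.5, 1.5] °C (snow insulation
    keeps the soil near 0 °C and strictly below the 2 °C threshold).  From
    the melt day onward: the year's summer mean plus a diurnal sinusoid,
    a day-level weather offset (clipped at 2.5 sd so no post-melt day drops
    back below the threshold) and hourly noise.  The first 2 °C crossing of
    the daily mean therefore falls exactly on the melt day.
    """
    if melt_doy is None:
        melt_doy = site.plot_melt_doy(year, plot_index, seed)
    if not SEASON_START_DOY < melt_doy < SEASON_END_DOY:
        raise ScenarioError(f"melt_doy {melt_doy} outside simulated season")
    rng = _stream(seed, "soil", site.name, year, plot_index)
    start = pd.Timestamp(year=year, month=1, day=1) \
        + pd.Timedelta(days=SEASON_START_DOY - 1)
    n_days = SEASON_END_DOY - SEASON_START_DOY + 1
    idx = pd.date_range(start, periods=n_days * 24, freq="h")
    doy = idx.dayofyear.to_numpy()
    hour = idx.hour.to_numpy()

    temp = np.empty(len(idx))
    pre = doy < melt_doy
    temp[pre] = rng.uniform(-0.5, 1.5, size=int(pre.sum()))

    mean = site.summer_mean(year)
    day_offsets = rng.normal(0.0, site.daily_temp_sd, size=n_days)
    if site.daily_temp_sd > 0:
        day_offsets = np.clip(day_offsets, -2.5 * site.daily_temp_sd,
                              2.5 * site.daily_temp_sd)
    offsets = day_offsets[doy - SEASON_START_DOY]
    diurnal = site.diurnal_amplitude * np.sin(2 * np.pi * (hour - 9) / 24.0)
    noise = rng.normal(0.0, site.hourly_noise_sd, size=len(idx)) \
        if site.hourly_noise_sd > 0 else 0.0
    post = ~pre
    temp[post] = (mean + offsets[post] + diurnal[post]
                  + (noise[post] if np.ndim(noise) else 0.0))
    return TemperatureSeries(
        plot_id=f"{site.name}_p{plot_index}", timestamps=idx, temp_c=temp)


# ---------------------------------------------------------------------------
# phenophase observations


def simulate_phenophases(program: SpeciesProgram, temps: TemperatureSeries,
                         scenario: ScenarioConfig, seed: int,
                         site: str = "", plot: str = "", n_subplots: int = 16,
                         melt_doy: int | None = None,
                         year: int | None = None,
                         snap: bool = True) -> pd.DataFrame:
    """Subplot-level BBCH observations for one species on one plot-year.

    Survey dates run on the configured cadence from shortly after melt-out
    to the season end.  Each subplot's recorded code is the species' linear
    GDD ramp (after its onset lag) plus independent Gaussian noise, clamped
    to [0, 59] and snapped to the nearest valid code of the snowbed scale
    for the species' morphotype; before onset the plant is invisible
    (code 0).

    ``snap=False`` bypasses the ordinal quantization and records the
    continuous development level instead — a diagnostic mode: quantization
    to the irregular code grid attenuates slope estimates by a few percent
    at the window edges, so quantization-free runs are the reference for
    exact parameter-recovery checks.
    """
    from .microclimate import detect_snowmelt_day
    if melt_doy is None:
        melt_doy = detect_snowmelt_day(temps)
    if year is None:
        year = int(temps.timestamps[0].year)
    scale = PhenophaseScale.default()
    codes = scale.codes_for(program.morphotype).astype(float)

    alignment = compute_gdd(temps, start_doy=melt_doy)
    obs_doys = np.arange(melt_doy + OBS_START_OFFSET_DAYS,
                         alignment["doy"].max() + 1,
                         scenario.obs_interval_days).astype(int)
    align_idx = alignment.set_index("doy")
    gdd = align_idx.loc[obs_doys, "gdd"].to_numpy(float)
    dates = align_idx.loc[obs_doys, "date"]

    rng = _stream(seed, "pheno", site, plot, program.species, year)
    rows = []
    true_vals = program.true_phase(gdd)
    pre_onset = gdd < program.onset_lag_gdd
    for sub in range(n_subplots):
        noise = rng.normal(0.0, scenario.noise_sd_phase, size=len(gdd)) \
            if scenario.noise_sd_phase > 0 else np.zeros(len(gdd))
        vals = np.clip(true_vals + noise, 0.0, 59.0)
        vals[pre_onset] = 0.0
        if snap:
            # snap to the nearest valid ordinal code (ties resolve downward)
            recorded = codes[np.argmin(
                np.abs(codes[None, :] - vals[:, None]), axis=1)]
        else:
            recorded = vals
        for d, doy_v, g, code in zip(dates, obs_doys, gdd, recorded):
            rows.append({"site": site, "plot": plot, "subplot": sub + 1,
                         "species": program.species, "date": d,
                         "doy": int(doy_v), "gdd": float(g),
                         "bbch": int(code) if snap else float(code),
                         "year": year})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenocam frames


def season_gcc_curve(doys: np.ndarray, metrics: SeasonMetrics,
                     baseline: float, peak: float,
                     peak_frac: float = 0.95,
                     baseline_frac: float = 0.1) -> np.ndarray:
    """Piecewise rise-plateau-decline daily GCC curve through the events.

    Constructed so that threshold-based extraction recovers the event days
    exactly on noise-free input: the series sits at the baseline before
    SOS-1, first reaches the 10 %-amplitude threshold on SOS, first enters
    the 95 %-of-maximum plateau on SPS, attains its unique maximum on POS,
    leaves the plateau after EPS and last touches the 10 % threshold on EOS.
    """
    sos, sps, pos, eps, eos = (metrics.sos, metrics.sps, metrics.pos,
                               metrics.eps, metrics.eos)
    thr = baseline + baseline_frac * (peak - baseline)
    plateau_edge = peak_frac * peak
    d = np.asarray(doys, dtype=float)
    g = np.full(d.shape, baseline)

    rise = (d >= sos) & (d < sps)
    if sps > sos:
        g[rise] = thr + (plateau_edge - thr) * (d[rise] - sos) / (sps - sos)
    in_peak = (d >= sps) & (d <= eps)
    left = in_peak & (d <= pos)
    right = in_peak & (d > pos)
    if pos > sps:
        g[left] = peak - (peak - plateau_edge) * ((pos - d[left]) / (pos - sps)) ** 2
    else:
        g[left] = peak
    if eps > pos:
        g[right] = peak - (peak - plateau_edge) * ((d[right] - pos) / (eps - pos)) ** 2
    fall = (d > eps) & (d <= eos)
    if eos > eps:
        g[fall] = plateau_edge + (thr - plateau_edge) * (d[fall] - eps) / (eos - eps)
    tail_len = 5.0
    tail = (d > eos) & (d <= eos + tail_len)
    g[tail] = thr + (baseline - thr) * (d[tail] - eos) / tail_len
    return g


def gcc_to_rgb(gcc: np.ndarray, total: float = 210.0) -> np.ndarray:
    """RGB triples with the requested green chromatic coordinate.

    Red and blue split the non-green share equally, so grey soil
    (GCC = 1/3) maps to an equal-channel pixel.
    """
    gcc = np.asarray(gcc, dtype=float)
    g = gcc * total
    rb = (total - g) / 2.0
    return np.stack([rb, g, rb], axis=-1)


def make_frame_pixels(gcc: float, size: tuple, rng: np.random.Generator,
                      pixel_noise_sd: float = 0.0) -> np.ndarray:
    """A (H, W, 3) float pixel array whose ROI mean has the given GCC."""
    h, w = size
    base = gcc_to_rgb(np.full((h, w), gcc))
    if pixel_noise_sd > 0:
        base = base + rng.normal(0.0, pixel_noise_sd, size=base.shape)
    return np.clip(base, 0.0, 255.0)


def simulate_phenocam(camera: CameraSpec, metrics_true: SeasonMetrics,
                      seed: int, year: int = 2020, site: str = "",
                      with_pixels: bool = False,
                      hours: tuple = (10, 17)) -> list[ImageRecord]:
    """Hourly camera frames tracing the season curve through the true events.

    Artifacts are injected independently per frame at the configured rates:
    over-exposed frames get an exposure time above the 50 s QC limit and
    washed-out bright pixels; fog frames are bright and grey (GCC pulled to
    the 1/3 soil value); out-of-window frames are re-stamped to 08:00.
    Frames carry pixel arrays when ``with_pixels`` is set, otherwise
    precomputed ROI means (identical GCC either way).
    """
    if None in (metrics_true.sos, metrics_true.sps, metrics_true.pos,
                metrics_true.eps, metrics_true.eos):
        raise ScenarioError("simulate_phenocam needs all five event days")
    rng = _stream(seed, "camera", site, year)
    d0 = metrics_true.sos - 12
    d1 = metrics_true.eos + 10
    doys = np.arange(d0, d1 + 1)
    daily = season_gcc_curve(doys, metrics_true, camera.baseline_gcc,
                             camera.plateau_gcc)
    rates = camera.artifact_rates
    records: list[ImageRecord] = []
    base_date = pd.Timestamp(year=year, month=1, day=1)
    for doy, g_day in zip(doys, daily):
        for hour in range(hours[0], hours[1] + 1):
            g = g_day + (rng.normal(0.0, camera.gcc_noise_sd)
                         if camera.gcc_noise_sd > 0 else 0.0)
            g = float(np.clip(g, 0.02, 0.98))
            ts = base_date + pd.Timedelta(days=int(doy) - 1, hours=hour)
            exposure = float(rng.uniform(0.01, 1.0))
            ratio = float(rng.uniform(4.0, 8.0))
            total = 210.0
            flags = []
            if rng.random() < rates.get("overexposed", 0.0):
                exposure = float(rng.uniform(55.0, 90.0))
                total = 600.0
                flags.append("overexposed")
            if rng.random() < rates.get("fog", 0.0):
                g = float(1.0 / 3.0 + rng.normal(0.0, 0.005))
                total = 540.0
                flags.append("fog")
            if rng.random() < rates.get("out_of_window", 0.0):
                ts = ts.normalize() + pd.Timedelta(hours=8)
                flags.append("out_of_window")
            rgb = tuple(gcc_to_rgb(np.array(g), total=total).ravel())
            rec = ImageRecord(
                filename=f"{site}_{ts.strftime('%Y%m%d_%H%M')}.png",
                timestamp=ts, exposure_time_s=exposure, exposure_ratio=ratio,
                roi_mean_rgb=None if with_pixels else rgb,
                pixels=(make_frame_pixels(g, camera.image_size, rng)
                        * (total / 210.0) if with_pixels else None),
            )
            records.append(rec)
    return records


def true_season_metrics(site: SiteSpec, year: int, camera: CameraSpec,
                        seed: int = 0) -> SeasonMetrics:
    """Ground-truth season events for one site-year, anchored to melt-out.

    Green-up starts shortly after melt (SOS = melt + 10), peaks about three
    weeks later and browns down by late September, matching the observed
    rise-plateau-decline pattern.
    """
    melt = int(site.melt_doy_by_year[year])
    sos = melt + 10
    pos = sos + 21
    return SeasonMetrics(sos=sos, sps=pos - 8, pos=pos, eps=pos + 18,
                         eos=min(sos + 75, SEASON_END_DOY - 10),
                         gcc_max=camera.plateau_gcc)


# ---------------------------------------------------------------------------
# whole-scenario orchestration


def simulate_scenario(config: ScenarioConfig,
                      with_camera: bool = True) -> dict:
    """Generate every dataset of the scenario.

    Returns a dict with ``temperatures`` (plot-year -> TemperatureSeries),
    ``melt_truth`` (frame of constructed melt days), ``observations``
    (subplot-level BBCH frame) and, optionally, ``camera`` (site-year ->
    list of ImageRecord) plus ``camera_truth`` (site-year -> SeasonMetrics).
    """
    temps: dict = {}
    melt_rows = []
    obs_frames = []
    for site in config.sites:
        for year in config.years:
            for p in range(site.n_plots):
                melt = site.plot_melt_doy(year, p, config.seed)
                series = simulate_soil_temperature(site, year, config.seed,
                                                   plot_index=p, melt_doy=melt)
                plot_id = f"{site.name}_p{p}"
                temps[(site.name, year, plot_id)] = series
                melt_rows.append({"site": site.name, "year": year,
                                  "plot": plot_id, "melt_doy": melt})
                for program in config.species:
                    obs = simulate_phenophases(
                        program, series, config, config.seed,
                        site=site.name, plot=plot_id,
                        n_subplots=site.subplots(p), melt_doy=melt, year=year)
                    obs_frames.append(obs)
    out = {
        "temperatures": temps,
        "melt_truth": pd.DataFrame(melt_rows),
        "observations": pd.concat(obs_frames, ignore_index=True),
    }
    if with_camera:
        cam, truth = {}, {}
        for site in config.sites:
            for year in config.years:
                m = true_season_metrics(site, year, config.camera, config.seed)
                truth[(site.name, year)] = m
                cam[(site.name, year)] = simulate_phenocam(
                    config.camera, m, config.seed, year=year, site=site.name)
        out["camera"] = cam
        out["camera_truth"] = truth
    return out


def write_scenario(config: ScenarioConfig, outdir, with_camera: bool = False,
                   with_images: bool = False) -> dict:
    """Materialise a scenario to disk in the pipeline's file formats.

    Writes ``soil_temp_<site>_<year>.csv`` per site-year (all plots
    stacked), ``pheno_obs.csv``, ``melt_truth.csv`` and, with the camera
    enabled, ``roi_means.csv`` per site-year (plus PNG frames and
    ``image_meta.csv`` when ``with_images`` is set).
    """
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_scenario(config, with_camera=with_camera)
    paths = {}
    for site in config.sites:
        for year in config.years:
            frames = []
            for p in range(site.n_plots):
                series = data["temperatures"][(site.name, year, f"{site.name}_p{p}")]
                f = series.to_frame()
                f.insert(0, "plot_id", series.plot_id)
                frames.append(f)
            path = outdir / f"soil_temp_{site.name}_{year}.csv"
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
            paths[f"soil_temp_{site.name}_{year}"] = path
    obs_path = outdir / "pheno_obs.csv"
    data["observations"][["site", "plot", "subplot", "species", "date",
                          "bbch"]].to_csv(obs_path, index=False)
    paths["pheno_obs"] = obs_path
    truth_path = outdir / "melt_truth.csv"
    data["melt_truth"].to_csv(truth_path, index=False)
    paths["melt_truth"] = truth_path
    if with_camera:
        for (site_name, year), records in data["camera"].items():
            rows = []
            for rec in records:
                r, g, b = rec.roi_mean_rgb
                rows.append({"timestamp": rec.timestamp, "r": r, "g": g,
                             "b": b, "exposure_time_s": rec.exposure_time_s,
                             "exposure_ratio": rec.exposure_ratio})
            path = outdir / f"roi_means_{site_name}_{year}.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            paths[f"roi_means_{site_name}_{year}"] = path
        if with_images:
            _write_images(config, data, outdir)
    return paths


def _write_images(config: ScenarioConfig, data: dict, outdir) -> None:
    from PIL import Image
    img_dir = outdir / "images"
    img_dir.mkdir(exist_ok=True)
    meta_rows = []
    for (site_name, year), records in data["camera"].items():
        for rec in records[:48]:      # desk-scale subset
            r, g, b = rec.roi_mean_rgb
            gcc = g / (r + g + b)
            px = gcc_to_rgb(np.full(config.camera.image_size, gcc),
                            total=r + g + b)
            Image.fromarray(np.clip(px, 0, 255).astype(np.uint8)).save(
                img_dir / rec.filename)
            meta_rows.append({"filename": rec.filename,
                              "timestamp": rec.timestamp,
                              "exposure_time_s": rec.exposure_time_s,
                              "exposure_ratio": rec.exposure_ratio})
    pd.DataFrame(meta_rows).to_csv(outdir / "image_meta.csv", index=False)
    from PIL import Image as _Img
    mask = np.full(config.camera.image_size, 255, dtype=np.uint8)
    _Img.fromarray(mask).save(outdir / "roi_mask.png")
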