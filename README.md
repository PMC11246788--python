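# nivophen

Alpine snowbed plants spend most of the year under an insulating snowpack;
the day the snow melts out opens a growing season of only two to three
months.  `nivophen` is a Python pipeline for analysing how snowbed phenology
responds to advancing snowmelt.  It covers the full chain from raw field
data to statistical inference:

* **Microclimate** — detect the day of snowmelt (DOSM) from hourly soil
  temperature (daily mean first sustained above 2 °C), and derive the
  seasonal covariates DOY (day of year), DFSM (days from snowmelt) and
  GDD (growing degree days, thermal sum of daily means above 0 °C).
* **Phenophase observations** — a snowbed-adapted ordinal BBCH scale
  (codes 0–59 over six principal growth stages, with annual/perennial/
  graminoid variants), record validation, and plot-level median phenophase
  across subplots.
* **Phenocam greenness** — the green chromatic coordinate
  GCC = G/(R+G+B) of ROI-mean RGB from time-lapse imagery, quality
  filtering (exposure, time-of-day, brightness band, snow/fog clustering)
  and a 90th-percentile moving-window daily series.
* **Season phenometrics** — the five event days SOS/SPS/POS/EPS/EOS;
  the peak period (SPS–EPS) is where GCC stays within 95 % of its seasonal
  maximum, the season bounds use a 10 %-of-amplitude threshold over the
  pre-season baseline.
* **Models** — phenophase (quasi-continuous BBCH) as a penalized cubic
  spline of one seasonal covariate with plot and year as penalized random
  intercepts; predictor choice by AIC after a Pearson collinearity screen;
  an additive per-species model for ecosystem GCC; and space-for-time
  transfer (a late-snowmelt-site fit predicting the early site).
* **PDR** — the phenological development rate: OLS slope of median
  phenophase vs. GDD between emergence (BBCH ≥ 09) and the last
  pre-senescent record (BBCH < 59), aggregated per species/site and
  compared between sites with Welch's t-test.

A built-in synthetic scenario generator reproduces the structure of the
field design (two sites with contrasting melt calendars × 3 years,
8 + 4 plots × 16 subplots, five species with distinct onset lags and
development rates, seasonal greenness curves with camera artifacts), so
every stage is testable end to end without any field download.

## Worked example

```python
from nivophen.pipeline import PipelineConfig, run_pipeline

ctx = run_pipeline(PipelineConfig(run_dir="demo_run", seed=1))
print(ctx["season_metrics"][["site", "year", "sos", "pos", "eos"]])
print(ctx["assessment"][["species", "pearson_r", "mean_abs_error_phases"]])
```

prints (abridged) the extracted season events per site-year,

```
    site  year  sos  pos  eos
0  early  2018  174  195  252
1  early  2019  203  224  281
2  early  2020  185  206  263
3   late  2018  204  225  282
4   late  2019  192  213  270
5   late  2020  201  222  279
```

— green-up starts about 10 days after each site's melt-out and peaks about
three weeks later — and the cross-site prediction quality per species,

```
              species  pearson_r  mean_abs_error_phases
0    Euphrasia minima   0.998493               1.197744
1  Gnaphalium supinum   0.996982               1.435733
2          Poa alpina   0.999467               0.696214
3      Salix herbacea   0.999067               0.626554
4     Veronica alpina   0.999145               0.814602
```

where `mean_abs_error_phases` is the mean absolute prediction error in BBCH
units when a model trained at the late-snowmelt site predicts the early
site.  The same pipeline is scriptable from the shell:

```
nivophen run --seed 1 --run-dir demo_run
nivophen gcc --config scenario.yaml
```

Each run directory contains `snow_seasons.csv`, `climate_alignment.csv`,
`aligned_observations.csv`, `gcc_daily.csv`, `season_metrics.csv`,
`model_comparison.csv`, `predictions.csv`, `prediction_assessment.csv`,
`pdr_estimates.csv`, `pdr_comparison.csv` and a `manifest.json` with the
configuration hash and per-stage record counts.  Reruns with the same seed
are byte-identical.

## Documentation

`docs/methods.md` describes the models, the numerical choices and the
synthetic-data assumptions in detail.
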