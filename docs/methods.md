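# Methods

This note documents the models and procedures implemented in `nivophen`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate
about real field data.

## Microclimate covariates

**Snowmelt detection.** A plot counts as snow-free on the first day whose
*daily mean* soil temperature exceeds the threshold (default 2 °C) and
stays above it for `persistence_days` consecutive days (default 1).  The
daily-mean basis is deliberate: under snow, a single warm hourly reading
(logger disturbance, radiative spikes) must not trigger a melt date, while
a genuinely warm day qualifies immediately.  The rule is monotone in the
threshold — raising it can only delay the detected day.  A series that
never qualifies returns a distinct no-snowmelt sentinel rather than a day.

**Degree days.** GDD accumulates `max(daily_mean − base, 0)` from the melt
day onward, with base temperature 0 °C — snowbed species grow at very low
temperatures, so a conventional 5 °C base would discard real growth signal.
Daily means are computed from hourly records; days with fewer than 75 % of
the expected 24 records are linearly interpolated from neighbouring days
and logged.  GDD on daily means (rather than hourly sums / 24) follows
standard agro-climatological practice; an oracle test pins the convention.

**Site summaries.** DOSM summaries report per-site means rounded to the
nearest day, min–max ranges and per-year values; the two-site comparison
reports the mean of yearly signed differences.  The soil-temperature
average is taken over the snow-free period and reported to 0.1 °C.

## Phenophase processing

The snowbed BBCH adaptation (codes 0, 09, 10–19, 20, 23, 25, 29, 30, 33,
35, 37, 39, 40, 43, 45, 47, 49, 50, 53, 55, 59) ships as a packaged CSV;
code 47 ("late milk") exists only for graminoids.  Codes are stored as
integers with 09 ≡ 9 and ordinal distance equal to integer difference,
because the downstream models treat the scale as quasi-continuous.

Subplot records aggregate to plot level by the sample median; an even
subplot count takes the midpoint of the two central codes, which may fall
between valid codes (e.g. 31 from {29, 33}) and is kept real-valued.  All
subplots present on a date enter the median, including zeros where the
species has not emerged — the plot median then honestly reflects partial
emergence.  Covariate alignment joins each plot-median record to its plot's
climate table; records dated before melt-out receive a negative DFSM and an
explicit flag.

## Phenocam greenness

GCC = G/(R+G+B) of the ROI-mean RGB.  It is evaluated as
`1/((R+B)/G + 1)`, algebraically identical but bit-exact on grey pixels
(any equal-channel pixel gives exactly 1/3 — the grey-soil baseline).

Quality control runs as a cascade:

1. **Metadata rules** (per record): exposure time ≤ 50 s, exposure ratio
   ≥ 2, acquisition time within 10:00–17:00.  The exposure ratio is a
   camera-reported quantity passed through from metadata; it cannot be
   reconstructed from pixels.  The time rule defaults to a hard window; a
   lenient mode keeps outside-window frames whose exposure is short.
   Retention under these rules is monotone when any rule is relaxed, and is
   property-tested as such.
2. **Brightness band**: mean ROI brightness (channel mean) within a
   quantile band of the surviving population, default (2.5 %, 97.5 %).
   The thresholds are configurable defaults, not field-calibrated values.
   The channel mean — not a luma-weighted sum — is used so that greenness
   changes (which shift channel *composition*) do not masquerade as
   brightness changes; exposure-driven artifacts move all channels
   together.
3. **Cluster rule**: 2-means on standardized (brightness, GCC) per image.
   The cluster that is simultaneously brighter and less green (snow or fog
   frames) is dropped; if no cluster is both, nothing is dropped, so clean
   archives pass untouched.

Rules 2 and 3 are population statistics recomputed on the survivors of
rule 1, so strict monotonicity holds only for the metadata rules — the
property test therefore disables the statistical filters.

The retained per-image GCC values reduce to a daily series as the 90th
percentile (linear interpolation between order statistics) over a 4-day
trailing window anchored at each day.  A trailing window is causal; the
anchoring is configurable and pinned by tests.  Window 1 with percentile
100 reproduces the daily-maximum series.  Days with no retained image in
their window are marked missing.

## Season phenometrics

From a smoothed daily series: `gcc_max` is the seasonal maximum and POS the
earliest day attaining it; SPS/EPS are the first/last days with
GCC ≥ 0.95·`gcc_max` ("within 95 % of the maximum" read as a relative
threshold — the only reading that yields a contiguous plateau period); no
contiguity is enforced, but a plateau interrupted by dips below the line
sets a `fragmented_peak` flag.  SOS/EOS use a 10 %-of-amplitude crossing
above the pre-season baseline (median GCC of the first five snow-free
days); the fraction is configurable.  Both rules are relative, so event
days are invariant to rescaling the series and equivariant under time
shifts — both property-tested.  A monotone series with no green-down
yields partial metrics with EOS missing and a `no_fall` flag.

## Phenology models

Median phenophase is modelled as

    phase = α + f(x) + b_plot + b_year + ε,

with `x` one of DOY/DFSM/GDD.  `f` is a cubic B-spline (default basis
dimension 8 — 10–15 observation dates per season bound the usable
flexibility) penalized by the exact integrated squared second derivative,
computed by 2-point Gauss–Legendre per knot interval (exact for cubic
splines).  The penalty's null space is the straight line, so the
infinite-smoothing limit *is* the OLS line — verified against a
closed-form regression.  Random effects enter as penalized (ridge) group
intercepts, the standard mixed-model-as-penalty representation; a group
with a single level is dropped with a warning.  All smoothing parameters
are selected jointly by GCV (coarse grid seed, Nelder–Mead refinement).
The ridge weight keeps a small floor because group dummies are collinear
with the intercept in the unpenalized limit (a mixed model's σ²/τ² is
strictly positive).

Reported per fit: adjusted R², effective degrees of freedom (trace of the
hat matrix, per term via its diagonal block) and a Gaussian conditional
AIC, `−2·loglik + 2(edf + 1)`.  AIC magnitudes are convention-dependent
and comparable only within this package.  Predictor comparison refuses
fits of different response vectors (fingerprint check) and breaks exact
AIC ties by the priority GDD > DFSM > DOY.  The candidate covariates are
screened first: pairs with Pearson |r| > 0.90 are flagged for
single-predictor modelling (they are all time-driven and typically nearly
collinear).

The ecosystem-greenness model is additive: GCC as a sum of per-species
phenophase smooths (default basis dimension 5, N ≳ 10 matched dates),
with per-term approximate p-values from drop-term F-tests at the full
model's smoothing levels — approximate in the usual additive-model sense.

Cross-site transfer evaluates the population-level curve (random effects
at zero, pooled fixed-effect curve) on the target site's GDD axis;
predictions clamp to [0, 59] with the raw value retained, and rows beyond
the training GDD range are flagged (the spline evaluates at the range
boundary — constant extrapolation, never polynomial blow-up).  Assessment
reports Pearson r, mean absolute error in BBCH units and residuals binned
by principal growth stage.

## Development rate (PDR)

PDR is the OLS slope of median phenophase against GDD over the
observations from the first record with phase ≥ 09 to the last with
phase < 59, endpoints inclusive.  The GDD axis is the primary one: the
observed magnitudes (0.06–0.095) correspond to ~50 BBCH units over
600–800 degree-days; a per-calendar-day axis is available by flag.  The
"slope of the regression line" over the window is read as an OLS fit over
all in-window observations, not a two-point chord; a two-point mode exists
and agrees with OLS on two-point windows by construction.  Pre-window and
post-completion records never affect the estimate (tested as an
invariance).

Per species and site, plot-year estimates aggregate to mean M and sample
SD.  The site comparison defaults to Welch's two-sample t on plot-year
values — group sizes (8 vs 4 plots) and variances differ — with a
year-paired t available because the field design's unit of replication is
ambiguous.  Two zero-variance groups with equal means return p = 1 by
convention.

## Synthetic scenario

The generator emulates the monitored design: a late-snowmelt site (8
plots, melt DOY 194/182/191 over three years) and an early site (4 plots,
one reduced to 14 subplots, melt DOY 164/193/175), five species with onset
lags 0–250 GDD and rates 0.060–0.089 BBCH/GDD, observation cadence 14
days, within-plot noise 1.5 BBCH units (within-plot variance is not a
published quantity; 1.5 is this package's scenario default).

*Soil temperature*: pre-melt uniform in [−0.5, 1.5] °C — snow insulation
keeps soil near 0 °C and strictly below the 2 °C detection threshold, so
the constructed melt day is recovered exactly.  Post-melt: the year's
summer mean (site means near the observed 9.8/10.4 °C, varied by year)
plus a diurnal sinusoid (amplitude 4 °C), a day-level weather offset
(SD 2 °C, clipped at 2.5 SD so no post-melt day falls back below
threshold) and hourly noise.  The day-level weather term matters
structurally: without it GDD is exactly proportional to DFSM and the
predictor comparison would be decided by the tie-break alone; with it, GDD
genuinely carries the growth signal and wins the AIC comparison on merit.

*Phenophases*: each species' development is linear in GDD after its onset
lag, clamped at 59, plus independent subplot noise, snapped to the nearest
valid code of the scale (ties downward).  Plants are code 0 before onset.
Snapping to the irregular code grid attenuates recovered slopes by ~2–3 %
(the 0→9 and 55→59 gaps sit at the regression window's ends); a
`snap=False` diagnostic mode records the continuous level, on which rate
recovery is exact.  Tests assert exact recovery quantization-free and
±10 % recovery on the quantized path.

*Phenocam*: hourly frames (10:00–17:00) whose ROI-mean GCC follows a
piecewise rise–plateau–decline curve constructed to pass exactly through
the event-day thresholds (baseline 1/3, plateau 0.42–0.46), so
threshold extraction recovers SOS/SPS/POS/EPS/EOS to the day on noise-free
input.  Artifacts are injected per frame: over-exposed (exposure time
> 50 s, washed-out), fog (bright, grey) and out-of-window (re-stamped to
08:00).  Frames carry either pixel arrays (64×64 default, full-frame ROI)
or precomputed ROI means with identical GCC.

All randomness derives from one scenario seed through named streams, so a
fixed seed reproduces the entire scenario byte for byte.

**Noise-free event recovery uses the degenerate smoothing window.**  The
4-day trailing P90 window exists to suppress camera noise; on a noiseless
series it merely delays falling-limb crossings by up to 3 days.  The
recovery checks therefore smooth with window 1 (for which the P90 of a
day's identical frames is the day's value); pipelines on noisy archives
keep the 4-day default.

**What the synthetic tests do not show.**  The generator has no spatial
correlation between subplots, no weather beyond sinusoid + noise, no
realistic optics (no illumination geometry, occlusion or mixed-pixel
effects), monotone-by-construction development, and cross-site transfer is
exact by design (both sites share the species programs).  Passing tests
demonstrate that the estimators recover what the model family can express
— not that real snowbed data satisfy these assumptions.  In particular the
near-perfect cross-site prediction (r ≈ 0.999, MAE < 1 BBCH unit) reflects
the matched-program design; on field data, species-specific responses to
snowmelt timing leave substantially larger errors.

## Problem sizes

The recovery experiments run the full two-site, three-year, 12-plot design
over 20 independent seeds (720 plot-year melt detections, 100 species-level
rate recoveries, 20 predictor comparisons and cross-site transfers); the
power experiment draws 500 replicate group pairs.  These sizes give stable
Monte-Carlo estimates while keeping a full run of the suite and the
acceptance script in the tens of seconds on a single CPU.

## Known limitations

* The GAM machinery selects smoothness by GCV only; REML selection and
  confidence bands are not implemented.
* Smooth-term p-values are approximate drop-term F-tests at fixed
  smoothing levels; they are anti-conservative in small samples.
* The brightness and cluster QC filters are population statistics: their
  behaviour depends on archive composition, and retention is not monotone
  through them.
* The ordinal scale is modelled as quasi-continuous throughout; no ordinal
  link function is offered.
* Season phenometrics assume a single seasonal rise and fall; bimodal
  greenness seasons yield flagged, partially meaningful events.
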