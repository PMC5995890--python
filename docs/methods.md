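# Methods

## The estimation problem

Fractional woody cover *f*(p, e) ∈ [0, 1] is estimated per pixel p and
epoch e from per-epoch summaries of all cloud-free reflectance
observations, using a regression model trained on photo-interpreted
quadrats. Change is the OLS slope of *f* against year, with each epoch's
value placed at the epoch midpoint. The change surface, aggregated to a
coarse grid, is then regressed on explanatory variables with boosted
regression trees; variables with a temporal component (linear trends) are
"drivers", those without (long-term means, statics) "facilitators".

## Synthetic landscape

The generator is the package's ground-truth instrument. It is a pure
function of (config, seed); identical configs give bit-identical rasters.

**Covariates.** Each covariate is a smooth Gaussian random field
(`gaussian_filter` of white noise, wrap-around boundaries) with a
configured spatial mean, field SD, correlation length, mean per-year trend
and trend-field SD. Fields are centered and standardized after smoothing so
the configured levels are the *realized* spatial means — without centering,
small grids can drift into cover saturation by chance. Time-varying
covariates get an annual series `mean + trend·(year − midyear) + noise`.

**Cover dynamics.** Per-pixel forcing is

    F = Σ_i b_i · trend_i + Σ_j c_j · (mean_j − mean_j̄) + Σ_k q_k · trend_k²

and cover steps between epoch midpoints as
`f ← clip(f + Δt · F · f·(1−f), 0, 1)`. The logistic factor bounds cover
in [0, 1] and damps change near the bounds; the quadratic term yields the
hump-shaped response to population growth. The functional form is a design
choice — the source analysis asserts only qualitative driver effects — so
all coefficients are exposed in config.

**Default world.** Three active drivers (rain trend +0.003 per mm yr⁻¹,
temperature trend +0.5 per °C yr⁻¹, burned-area trend −2.5 per fraction
yr⁻¹), a population hump (−0.02 on squared trend), three null covariates
(wind, evaporation trends; static sand content). Magnitudes were fixed
once to reproduce the regime the method targets: net cover change ≈ +0.06
over 30 years with spatially variable sign (~57% of pixels gaining), slope
SD ≈ 0.01 yr⁻¹, ~1% of pixel-epochs at the [0, 1] bounds.

**Observation model.** Reflectance is the cover-weighted linear mixture of
a fixed woody endmember and a herbaceous endmember that oscillates
seasonally between green and dry spectra (so variance/range metrics are
informative). Sensor-specific gain/bias per band is applied before Gaussian
noise (SD 0.02, a typical surface-reflectance uncertainty); cloud flags are
independent Bernoulli draws (p = 0.3). Twelve observations per 5-year
epoch. Landsat-5-like epochs 1–3 and Landsat-7-like epochs 4–6 differ by a
few-percent band transform whose coefficients are known to the
harmonization step.

**Quadrats.** n locations sampled without replacement from the unmasked
area, each with a random epoch and an in-epoch acquisition date; labels are
true cover (plus optional interpreter noise — no error rate is asserted;
the SD is a free parameter) quantized to the nearest of
{0, 0.25, 0.5, 0.75, 1}. Quantization ties (0.125, 0.375, …) round half
up: deterministic and consistent with common photo-interpretation
practice. Configurable fractions of mis-dated and uncertain quadrats
exercise the exclusion rules.

**What the generator does not emulate:** orbital geometry, atmospheric and
BRDF effects, spatially correlated cloud fields, georeferencing error,
interpreter bias. A green test therefore establishes correctness of the
estimation machinery under the stated world, not robustness to those
artefacts.

## Numerical choices

- **Percentiles**: linear interpolation between closest ranks (the common
  default), locked so oracle tests are exact.
- **Windowed means**: mean of observations whose *values* fall inside the
  closed percentile interval. The alternative rank-window reading
  (observations whose rank positions fall in the window) is implemented
  behind `window="rank"`; the value-window is the default. With very short
  series a window can contain no observation; the documented fallback is
  the interpolated percentile at the window midpoint, which keeps all
  metrics defined whenever a pixel has at least one valid observation.
- **Variance**: population variance.
- **Index constants**: SAVI L = 0.5; EVI G = 2.5, C1 = 6, C2 = 7.5, L = 1.
- **Forest threshold**: strict `>` 0.40, from the definition's wording;
  height enters as a pre-classified tall/short raster.
- **Missing values**: IEEE NaN for continuous rasters, −1 for categorical.
- **Logit trend**: covers clamped to [ε, 1−ε], ε = 0.005 (arbitrary,
  documented).
- **Quality score**: per pixel, (timepoints/n_epochs) ×
  min(observations/target, 1); per cell, the mean over all pixels (masked
  pixels score 0), which factorizes into mean unmasked quality × unmasked
  fraction. The ingredients are prescribed, the combination is ours. Cells
  strictly below the 25th-percentile score (linear interpolation) are
  excluded; an all-equal score field excludes nothing.
- **Extreme rainfall**: sliding (stride-1) 5-day sums; threshold is the
  95th percentile of *all* of a cell's window sums, so counts are
  record-dependent (asserted in a regression test); strict exceedance; a
  window is attributed to the year of its first day. The "5-hourly"
  variability scale in the source is read as its sub-daily forcing
  interval; the operation takes whatever observation interval it is given.
- **TRI**: Riley formulation √Σ(center−neighbor)² by default (the cited
  index); the literal sum-of-absolute-differences is available by flag.
  Edge pixels use available neighbors only.
- **PCI**: classical annual formulation 100·Σp²/(Σp)²; multi-year input is
  reduced to mean monthly totals first.
- **Aggregation**: ≤500 m resolution → per-cell mean of valid pixels;
  >500 m → bilinear sampling at cell centroids, clamped at edges.
- **Collinearity**: Pearson r on complete cases (pairwise deletion);
  groups by transitive closure over |r| > 0.7; keep highest-priority, then
  alphabetical. Constant columns have undefined r and are treated as
  uncorrelated with a warning.

## Cover regression

Random forest (500 trees by default; 300 in the scripted runs for speed),
one model per sensor group plus a pooled model, trained on quantized labels
and predicting continuous fractions (no label weighting — none is asserted
by the protocol). Hold-out split 20%, stratified by label class when every
class has ≥2 members; out-of-bag R² serves as the internal validation.
Predictions are clipped to [0, 1], not re-normalized: bounded-label
regression can overshoot slightly and clipping preserves calibration
elsewhere.

**Known limitation — label quantization.** With every noise source off, a
perfect regressor reproduces the *quantized* covers, and the correlation
between slopes of quantized and true covers is capped near 0.93–0.97 on
the default world (quantization MSE 0.25²/12 against cover variance
≈ 0.06). The pipeline reaches that ceiling; it cannot exceed it while
labels are quarter-classes. Under observation noise the measured slope
recovery is r ≈ 0.96.

## Driver attribution

gbm-style boosting behind a deliberate re-implementation of the
surrounding procedure: Gaussian family (deviance = weighted squared
error), interaction depth 5, learning rate 0.01, bag fraction 0.5.
The tree count is selected at the minimum of 10-fold cross-validated
predictive deviance (searched from 20 trees up; each fold's full-length
stage-wise predictions are evaluated, so selection costs no extra fits),
and **CV deviance explained** = 1 − CV deviance / weighted total deviance
is reported from held-out predictions, never the training fit. Observation
weights (cell quality) enter the loss; uniform weight rescaling provably
leaves the fit unchanged.

- **Relative importance**: per-variable squared-improvement over all
  splits and trees, normalized to sum to 100.
- **Simplification**: backward elimination dropping the lowest-importance
  variable; stops when a drop would raise CV deviance more than one
  standard error (across folds) above the full model's CV estimate. The
  cited procedure admits several stopping rules; one-SE is the choice
  here, and the full elimination trace is always returned for audit.
- **Partial dependence**: brute-force averaging over the empirical
  distribution of the other variables on a grid clipped to the variable's
  5th–95th percentile, with decile rug positions and the interquartile
  band attached. A diagnostic OLS slope of the curve summarizes its sign.
- **Permutation sanity**: "failed to resolve" is operationalized as the CV
  selecting the minimum allowed tree count or CV deviance explained
  ≤ 0.05 (the source does not define the phrase).
- CV folds are random, not spatially blocked, matching the source.

## Hindcasting

Variables observed only around a reference epoch (herbivore density,
burned area) are extended across epochs by fitting the BRT on the
reference epoch's response and applying it to every epoch's predictors;
the per-cell linear slope of the reconstructed series is the variable's
trend layer. Cross-epoch validation retrains on one epoch of synthetic
truth and scores the others (R²), mirroring the source's burned-area
check. Hindcast hyperparameters default to the driver-model values.

## Degenerate inputs

Empty observation series → missing metrics; <2 epochs → missing slope;
p-values need ≥3 points; constant responses are rejected by the BRT
(deviance undefined); zero annual rainfall → missing PCI; zero-thickness
or non-contiguous soil layers are rejected; aggregation of an all-missing
cell is missing.
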