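# woodycover

Mapping three decades of fractional woody-plant-cover change from
multispectral scene time series, and attributing the spatial variation in
that change to climatic, edaphic and disturbance drivers with boosted
regression trees.

Woody plant encroachment (WPE) — the gradual thickening of trees and shrubs
in savannas, grasslands and shrublands — is one of the dominant land-cover
changes in non-forest biomes. Quantifying it requires (i) estimating
fractional woody cover *f* ∈ [0, 1] per 30 m pixel for a sequence of
multi-year epochs, (ii) defining per-pixel change as the OLS slope of
*f* against year, and (iii) regressing the resulting change surface on a
suite of explanatory variables split into **drivers** (temporal trends,
e.g. d(rainfall)/dt) and **facilitators** (long-term means and statics).

This package re-implements that pipeline at desk scale. Because the
continental Landsat/MODIS/GLDAS archives are not reproducible on a
workstation, a seeded synthetic landscape stands in for them: covariate
fields with known linear trends force woody-cover dynamics through a
logistic-bounded update, a spectral mixture model with seasonal herbaceous
phenology, sensor offsets, noise and clouds generates the scene stacks, and
photo-interpretation quadrats carry cover labels quantized to
{0, 0.25, 0.5, 0.75, 1}. Every stage can therefore be scored against known
ground truth.

## Pipeline

| stage | module | what it does |
|---|---|---|
| simulate | `woodycover.synthetic` | seeded landscape: covariates, true cover, scenes, quadrats |
| mask | `woodycover.mask` | exclude closed forest (>40% tall-tree cover), forestry (loss∧gain), non-natural landcover |
| metrics | `woodycover.metrics` | cloud filter; per-epoch min/max/percentile/windowed-mean metrics for 6 bands + NDVI/SAVI/EVI (+variance, range); sensor harmonization |
| cover | `woodycover.cover` | quadrat protocol (date + uncertainty exclusions), per-sensor random-forest regression, dual validation, clipped prediction |
| trends | `woodycover.trends` | per-pixel OLS slope/p-value of cover vs epoch-midpoint year; logit variant; cell quality weights with lowest-quartile exclusion |
| covariates | `woodycover.covariates` | mean+trend reduction, extreme 5-day rainfall counts, PCI, two-scale rainfall SD, depth-weighted soils, TRI, BRT hindcasting |
| drivers | `woodycover.brt` | 500 m-rule aggregation, \|r\|>0.7 collinearity filter, weighted Gaussian BRT (tree complexity 5, learning rate 0.01, bag fraction 0.5, 10-fold CV), importances, backward-elimination simplification, partial dependence, permutation sanity check |

The numbered scripts under `analysis/` run these stages in order and write
their tables to `results/`; `woodycover.pipeline` chains them for
programmatic use.

## Worked example

```bash
python analysis/01_simulate_landscape.py --seed 1
python analysis/04_trend_maps.py --seed 1
python analysis/06_driver_attribution.py --seed 1
```

prints (seed 1):

```
Simulated 64x64 landscape, 6 epochs, seed 1
  net cover change +0.063 (sd 0.241); 57% of pixels gaining
...
Estimated slopes correlate with truth at r = 0.962
  mean slope +0.0006 /yr; significant gain 23%, loss 20%
  raw/logit slope sign agreement 99%; 16/64 cells excluded by quality
...
Driver model: CV deviance explained 0.88 (800 trees); collinearity removed none
  importances (%): {'rain_trend': 48.7, 'temp_trend': 25.8, 'fire_trend': 12.9,
                    'evap_trend': 6.1, 'pop_trend': 3.4, 'wind_trend': 3.2}
  simplified to ['rain_trend', 'temp_trend', 'fire_trend'] (dropped ['wind_trend', 'pop_trend', 'evap_trend'])
  PD slope rain_trend: +0.0006
  PD slope temp_trend: +0.0699
  PD slope fire_trend: -0.3284
  permutation sanity: failed to resolve = True (deviance explained -0.087)
```

Reading: the generating world forces cover change upward where rainfall and
temperature trends are positive and downward where burned area declines
reverse (fire coefficient negative); the fitted attribution recovers
exactly those three variables as the retained drivers, with
partial-dependence slopes of the generating signs, while the two null
covariates (`wind_trend`, `evap_trend`) are eliminated and a
permuted-response refit fails to resolve. The trend map itself tracks the
true slope field at r ≈ 0.96 — the residual gap is dominated by the
quarter-class quantization of the training labels, not by the estimator.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole computation from scratch at the given seed: the cover
pipeline (simulation → mask → metrics → regression → trend → quality
weights), coarse-grid aggregation and BRT attribution, and the
driver-recovery exercise on a 400-cell covariate table with three signed
active drivers, a hump-shaped population term and three null covariates,
printing each stage's measured statistics before writing the JSON report.
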