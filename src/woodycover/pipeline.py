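"""End-to-end orchestration of the synthetic-landscape analysis.

Chains the stages in the order the full-scale analysis runs them: simulate
the landscape, build the analysis mask, compute per-epoch metrics, train
and apply the cover regressor, estimate per-pixel trends and cell weights,
aggregate to the coarse grid, and attribute drivers with the weighted BRT.
Used by the numbered analysis scripts and the acceptance script so every
number they report is recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brt import (
    BRTParams,
    DriverModel,
    collinearity_filter,
    fit_brt,
    partial_dependence,
    permutation_sanity,
    simplify_model,
)
from .cover import CoverRegressor, assemble_training, fit_cover_regressor, predict_cover
from .mask import AnalysisMask, apply_mask, build_mask
from .metrics import MetricCube, build_metric_cube
from .synthetic import LandscapeConfig, TrueState, default_config, generate_covariates, generate_mask_inputs, generate_true_cover, sample_quadrats, simulate_scenes
from .trends import CellWeights, QualityLayers, TrendMap, pixel_trend, quality_weights

__all__ = ["CoverPipelineResult", "run_cover_pipeline", "build_cell_table", "run_driver_attribution"]


@dataclass
class CoverPipelineResult:
    config: LandscapeConfig
    state: TrueState
    mask: AnalysisMask
    cube: MetricCube
    regressor: CoverRegressor
    cover_pred: np.ndarray
    trend: TrendMap
    weights: CellWeights
    quadrats: pd.DataFrame
    slope_truth_r: float


def run_cover_pipeline(
    config: LandscapeConfig | None = None,
    n_quadrats: int = 2000,
    n_estimators: int = 300,
    seed: int = 1,
    masked: bool = True,
) -> CoverPipelineResult:
    """Simulate, mask, featurize, regress, predict and trend one landscape."""
    config = config or default_config(seed=seed)
    state = generate_true_cover(generate_covariates(config), config)
    mask = build_mask(generate_mask_inputs(config), excluded_classes=(1, 2, 3))
    stack = simulate_scenes(state)
    cube = build_metric_cube(stack, config.epochs)
    excl = mask.excluded if masked else np.zeros_like(mask.excluded)
    quads = sample_quadrats(state, n_quadrats, seed=seed + 10, mask_excluded=excl)
    table = assemble_training(quads, cube, config.epochs, config.obs.sensor_by_epoch)
    reg = fit_cover_regressor(table, n_estimators=n_estimators, seed=seed)
    pred = predict_cover(reg, cube)
    if masked:
        pred = np.stack([apply_mask(pred[e], mask) for e in range(pred.shape[0])])
    trend = pixel_trend(pred, config.epoch_midpoints)
    layers = QualityLayers(
        timepoints=(~np.isnan(pred)).sum(axis=0),
        observations=cube.counts.sum(axis=0),
    )
    weights = quality_weights(
        layers,
        excl,
        cell_size=config.cell_size,
        n_epochs=len(config.epochs),
        target_observations=len(config.epochs) * config.obs.n_per_epoch // 2,
    )
    ok = ~np.isnan(trend.slope) & ~np.isnan(state.slope)
    r = float(np.corrcoef(trend.slope[ok], state.slope[ok])[0, 1]) if ok.sum() > 2 else float("nan")
    return CoverPipelineResult(
        config=config,
        state=state,
        mask=mask,
        cube=cube,
        regressor=reg,
        cover_pred=pred,
        trend=trend,
        weights=weights,
        quadrats=quads,
        slope_truth_r=r,
    )


def _cell_mean(arr: np.ndarray, cell: int) -> np.ndarray:
    import warnings

    ny, nx = arr.shape
    blocks = arr.reshape(ny // cell, cell, nx // cell, cell).swapaxes(1, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(blocks, axis=(2, 3))


def build_cell_table(result: CoverPipelineResult) -> pd.DataFrame:
    """Coarse-grid table: response (cell-mean slope), weights, covariates.

    Covariate trend fields become driver columns ("<name>_trend"), mean
    fields facilitator columns ("<name>_mean"); the estimated cell slope is
    the response and the quality score the weight.
    """
    cfg = result.config
    cell = cfg.cell_size
    cols: dict[str, np.ndarray] = {}
    for name, fieldv in result.state.covariates.fields.items():
        cols[f"{name}_mean"] = _cell_mean(fieldv.mean_field, cell).ravel()
        if fieldv.series is not None:
            cols[f"{name}_trend"] = _cell_mean(fieldv.trend_field, cell).ravel()
    df = pd.DataFrame(cols)
    df["cover_change"] = _cell_mean(result.trend.slope, cell).ravel()
    df["true_change"] = _cell_mean(result.state.slope, cell).ravel()
    df["weight"] = result.weights.weight.ravel()
    df["excluded"] = result.weights.excluded.ravel()
    return df


@dataclass
class DriverAttributionResult:
    model: DriverModel
    reduced: DriverModel
    trace: list
    partial_dependence: dict[str, object]
    sanity: list
    removed_collinear: list[str]


def run_driver_attribution(
    table: pd.DataFrame,
    variables: list[str],
    response: str,
    weight: str,
    params: BRTParams,
    collinearity_threshold: float = 0.7,
    priority: list[str] | None = None,
    sanity_seeds: tuple[int, ...] = (0,),
) -> DriverAttributionResult:
    """Collinearity filter, weighted BRT, simplification, PD and sanity."""
    sub = table[~table["excluded"]] if "excluded" in table else table
    Xfull = sub[variables]
    reduced_X, rep = collinearity_filter(Xfull, threshold=collinearity_threshold, priority=priority)
    y = sub[response].to_numpy(dtype=float)
    w = sub[weight].to_numpy(dtype=float)
    model = fit_brt(reduced_X, y, w, params)
    reduced, trace = simplify_model(model, reduced_X, y, w, params)
    pds = {v: partial_dependence(reduced, reduced_X, v) for v in reduced.features}
    sanity = permutation_sanity(reduced_X, y, w, params, seeds=sanity_seeds)
    return DriverAttributionResult(
        model=model,
        reduced=reduced,
        trace=trace,
        partial_dependence=pds,
        sanity=sanity,
        removed_collinear=rep["removed"],
    )
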