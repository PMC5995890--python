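"""Explanatory-variable derivation: climatic, edaphic and disturbance layers.

Every explanatory variable enters the driver model either as a long-term
mean ("facilitator") or as the slope of its linear trend over time
("driver").  Beyond plain mean-and-trend reduction this module implements
the bespoke climate statistics — annual counts of extreme 5-day rainfall,
the precipitation concentration index, rainfall variability at two temporal
scales — plus depth-weighted soil-profile aggregation, the terrain
ruggedness index, and boosted-tree hind/fore-casting of variables (herbivore
density, burned area) observed only around a reference epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trends import ols_slope

__all__ = [
    "mean_and_trend",
    "extreme_rainfall_counts",
    "precipitation_concentration_index",
    "rainfall_variability",
    "depth_weighted_soil",
    "terrain_ruggedness",
    "HindcastModel",
    "fit_hindcast",
    "CovariateTable",
]


def mean_and_trend(series: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Long-term temporal mean and OLS slope along the leading axis.

    NaN timepoints are skipped per cell; all-missing series raise.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("need at least two timepoints")
    if np.all(np.isnan(series)):
        raise ValueError("all-missing series")
    mean = np.nanmean(series, axis=0)
    slope, _, _, _ = ols_slope(series, times)
    return mean, slope


@dataclass
class ExtremeRainfall:
    years: np.ndarray          # distinct calendar years
    counts: np.ndarray         # events per year, shape (n_years,) + cell shape
    threshold: np.ndarray      # the 95th-percentile 5-day total per cell
    trend: np.ndarray          # OLS slope of annual counts


def extreme_rainfall_counts(
    daily: np.ndarray,
    day_years: np.ndarray,
    window: int = 5,
    quantile: float = 95.0,
) -> ExtremeRainfall:
    """Annual counts of extreme multi-day rainfall and their trend.

    Sliding (stride-1) ``window``-day sums are computed over the full daily
    record; the cell threshold is the ``quantile`` percentile of *all* of the
    cell's window sums, so the threshold — and therefore every year's count —
    depends on the full record.  A window is attributed to the year of its
    first day and counts only on strict exceedance.
    """
    daily = np.asarray(daily, dtype=float)
    day_years = np.asarray(day_years)
    if daily.shape[0] < window:
        raise ValueError(f"daily series shorter than the {window}-day window")
    if day_years.shape[0] != daily.shape[0]:
        raise ValueError("day_years must label every day")
    # cumulative-sum sliding window along axis 0
    c = np.cumsum(daily, axis=0)
    sums = np.empty((daily.shape[0] - window + 1,) + daily.shape[1:])
    sums[0] = c[window - 1]
    sums[1:] = c[window:] - c[:-window]
    threshold = np.percentile(sums, quantile, axis=0)
    exceed = sums > threshold
    win_year = day_years[: sums.shape[0]]
    years = np.unique(win_year)
    counts = np.stack([exceed[win_year == y].sum(axis=0) for y in years])
    trend, _, _, _ = ols_slope(counts.astype(float), years.astype(float))
    return ExtremeRainfall(years=years, counts=counts, threshold=threshold, trend=trend)


def precipitation_concentration_index(monthly: np.ndarray) -> np.ndarray:
    """PCI = 100 * sum(p_i^2) / (sum(p_i))^2 over 12 monthly totals.

    Input may be (12, ...) monthly totals or (n_years, 12, ...) multi-year
    records, which are first reduced to mean monthly totals.  Ranges from
    100/12 (perfectly even) to 100 (all rain in one month); zero annual
    rainfall yields NaN.
    """
    p = np.asarray(monthly, dtype=float)
    if p.ndim >= 2 and p.shape[0] != 12 and p.shape[1] == 12:
        p = p.mean(axis=0)
    if p.shape[0] != 12:
        raise ValueError("expected 12 monthly totals on the leading axis")
    if np.any(p < 0):
        raise ValueError("negative monthly rainfall")
    tot = p.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pci = 100.0 * (p**2).sum(axis=0) / tot**2
    return np.where(tot > 0, pci, np.nan)


def rainfall_variability(obs: np.ndarray, obs_years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rainfall SD at two scales: across annual totals and across raw obs.

    ``obs`` is the sub-daily (or daily) precipitation record along the
    leading axis, ``obs_years`` the calendar year of each observation.
    Returns ``(sd_annual, sd_subannual)`` as population standard deviations.
    """
    obs = np.asarray(obs, dtype=float)
    obs_years = np.asarray(obs_years)
    if obs.shape[0] == 0:
        raise ValueError("empty series")
    years = np.unique(obs_years)
    annual = np.stack([obs[obs_years == y].sum(axis=0) for y in years])
    return annual.std(axis=0), obs.std(axis=0)


def depth_weighted_soil(values: np.ndarray, depth_intervals: list[tuple[float, float]]) -> np.ndarray:
    """Thickness-weighted average over a soil profile.

    ``values`` has the layer axis leading; intervals are (top, bottom)
    depths, contiguous with positive thickness.
    """
    values = np.asarray(values, dtype=float)
    iv = np.asarray(depth_intervals, dtype=float)
    if iv.ndim != 2 or iv.shape[0] != values.shape[0]:
        raise ValueError("one (top, bottom) interval per layer required")
    thick = iv[:, 1] - iv[:, 0]
    if np.any(thick <= 0):
        raise ValueError("depth intervals must have positive thickness")
    if np.any(iv[1:, 0] != iv[:-1, 1]):
        raise ValueError("depth intervals must be contiguous")
    w = thick / thick.sum()
    return np.tensordot(w, values, axes=(0, 0))


_NEIGHBOR_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def terrain_ruggedness(dem: np.ndarray, method: str = "riley") -> np.ndarray:
    """Terrain ruggedness index over the 8-neighborhood.

    ``method="riley"`` (default): sqrt of the summed squared elevation
    differences between a pixel and its neighbors.  ``method="sum_abs"``:
    the literal sum of absolute differences.  Edge pixels use only their
    available neighbors.
    """
    dem = np.asarray(dem, dtype=float)
    acc = np.zeros_like(dem)
    for di, dj in _NEIGHBOR_SHIFTS:
        nb = np.full_like(dem, np.nan)
        src_i = slice(max(di, 0), dem.shape[0] + min(di, 0))
        dst_i = slice(max(-di, 0), dem.shape[0] + min(-di, 0))
        src_j = slice(max(dj, 0), dem.shape[1] + min(dj, 0))
        dst_j = slice(max(-dj, 0), dem.shape[1] + min(-dj, 0))
        nb[dst_i, dst_j] = dem[src_i, src_j]
        diff = np.where(np.isnan(nb), 0.0, dem - nb)
        if method == "riley":
            acc += diff**2
        elif method == "sum_abs":
            acc += np.abs(diff)
        else:
            raise ValueError("method must be 'riley' or 'sum_abs'")
    return np.sqrt(acc) if method == "riley" else acc


@dataclass
class HindcastModel:
    """Boosted-tree model trained on a reference epoch, applied to all epochs."""

    model: object
    reference_epoch: int
    contributions: pd.Series        # relative importance, sums to 100
    predictions: pd.DataFrame       # cells x epochs
    trend: np.ndarray               # per-cell slope of the hindcast series
    validation_r2: dict             # epoch -> R2 against held-out truth


def fit_hindcast(
    response_ref: np.ndarray,
    predictors_by_epoch: dict[int, pd.DataFrame],
    epoch_midpoints: dict[int, float],
    params=None,
    seed: int = 0,
    reference_epoch: int | None = None,
    validation_responses: dict[int, np.ndarray] | None = None,
) -> HindcastModel:
    """Hind/fore-cast a variable observed only around a reference epoch.

    A boosted regression tree is fitted on the reference epoch's response and
    predictors, then applied to every epoch's predictors to reconstruct the
    full response time series; the per-cell linear slope of that series is
    the variable's trend layer.  If truth is supplied for non-reference
    epochs, cross-epoch validation R2 is reported for each.
    """
    from .brt import BRTParams, fit_brt

    epochs = sorted(predictors_by_epoch)
    missing = [e for e in epochs if e not in epoch_midpoints]
    if missing:
        raise ValueError(f"missing epoch midpoints for {missing}")
    params = params or BRTParams(seed=seed)
    # the reference epoch is the one whose response is observed
    ref_epoch = epochs[0] if reference_epoch is None else reference_epoch
    if ref_epoch not in predictors_by_epoch:
        raise ValueError(f"no predictors for reference epoch {ref_epoch}")
    Xref = predictors_by_epoch[ref_epoch]
    model = fit_brt(Xref, np.asarray(response_ref, dtype=float), np.ones(len(Xref)), params)
    preds = {}
    for e in epochs:
        preds[e] = model.predict(predictors_by_epoch[e])
    pred_df = pd.DataFrame(preds)
    times = np.array([epoch_midpoints[e] for e in epochs], dtype=float)
    trend, _, _, _ = ols_slope(pred_df.to_numpy().T, times)
    validation = {}
    if validation_responses:
        for e, truth in validation_responses.items():
            if e == ref_epoch:
                continue
            truth = np.asarray(truth, dtype=float)
            resid = truth - preds[e]
            validation[e] = float(1.0 - (resid**2).sum() / ((truth - truth.mean()) ** 2).sum())
    return HindcastModel(
        model=model,
        reference_epoch=ref_epoch,
        contributions=model.importances,
        predictions=pred_df,
        trend=trend,
        validation_r2=validation,
    )


ROLE_DRIVER = "driver"
ROLE_FACILITATOR = "facilitator"


@dataclass
class CovariateTable:
    """Coarse-grid cells x explanatory variables with role/provenance tags.

    ``data`` holds one row per cell (cell id index, centroid x/y columns
    plus one column per variable); ``roles`` and ``provenance`` map variable
    name to "driver"/"facilitator" and "observed"/"hindcast".  Driver
    variables are temporal trends; facilitators are long-term means or
    static layers.
    """

    data: pd.DataFrame
    roles: dict[str, str]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        dup = self.data.columns[self.data.columns.duplicated()]
        if len(dup):
            raise ValueError(f"duplicated variable names: {list(dup)}")
        for v, r in self.roles.items():
            if r not in (ROLE_DRIVER, ROLE_FACILITATOR):
                raise ValueError(f"unknown role {r!r} for {v!r}")

    def variables(self, role: str | None = None) -> list[str]:
        names = [c for c in self.data.columns if c in self.roles]
        if role is None:
            return names
        return [c for c in names if self.roles[c] == role]
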