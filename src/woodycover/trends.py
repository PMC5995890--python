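"""Per-pixel change estimation and quality weighting.

The change statistic for every pixel is the ordinary-least-squares slope of
fractional woody cover against year, with each epoch's cover placed at the
epoch midpoint.  A logit-scale variant is provided as a robustness check for
the bounded response.  Cell-level quality weights combine the number of epoch
timepoints available for the regression with the fraction of each coarse cell
that survives masking; cells in the lowest quartile of the resulting score
are excluded from driver modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TrendMap",
    "QualityLayers",
    "CellWeights",
    "ols_slope",
    "pixel_trend",
    "logit_trend",
    "quality_weights",
    "exclude_low_quality",
]


def ols_slope(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of ``y`` on ``x`` along the leading axis.

    ``y`` has shape ``(T, ...)``; ``x`` has shape ``(T,)``.  NaN entries of
    ``y`` are skipped per series (pairwise deletion).  Returns
    ``(slope, intercept, pvalue, n)`` with the trailing shape of ``y``.
    Slope and intercept are NaN where fewer than two points remain; the
    p-value (two-sided t-test on the slope) is NaN where fewer than three.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("time axis of y must match length of x")
    valid = ~np.isnan(y)
    n = valid.sum(axis=0)
    xv = np.where(valid, x.reshape((-1,) + (1,) * (y.ndim - 1)), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing series
        xbar = np.nanmean(xv, axis=0)
        ybar = np.nanmean(np.where(valid, y, np.nan), axis=0)
        dx = np.where(valid, xv - xbar, 0.0)
        dy = np.where(valid, y - ybar, 0.0)
        sxx = (dx * dx).sum(axis=0)
        sxy = (dx * dy).sum(axis=0)
        slope = np.where(n >= 2, sxy / sxx, np.nan)
        intercept = ybar - slope * xbar
        # two-sided p-value from the t statistic on n-2 df
        resid = np.where(valid, dy - slope * dx, 0.0)
        sse = (resid * resid).sum(axis=0)
        df = n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(sse / np.where(df > 0, df, np.nan) / sxx)
            tstat = slope / se
        pvalue = np.where(df > 0, 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1)), np.nan)
        # exact fits (zero residual) give se == 0 -> t inf -> p 0
        pvalue = np.where((df > 0) & (se == 0), 0.0, pvalue)
    return slope, intercept, pvalue, n


@dataclass
class TrendMap:
    """Per-pixel linear-change layers: slope (yr^-1), intercept, p-value, n."""

    slope: np.ndarray
    intercept: np.ndarray
    pvalue: np.ndarray
    n: np.ndarray
    scale: str = "cover"  # "cover" or "logit"


@dataclass
class QualityLayers:
    """Per-pixel ingredients of the quality score.

    ``timepoints``: epochs available for the trend regression;
    ``observations``: total valid scene observations behind the metrics;
    ``score``: composite per-pixel quality in [0, 1].
    """

    timepoints: np.ndarray
    observations: np.ndarray
    score: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.any(self.timepoints < 0) or np.any(self.observations < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class CellWeights:
    score: np.ndarray      # per-cell quality score
    weight: np.ndarray     # per-cell weight (0 where excluded)
    excluded: np.ndarray   # per-cell bool
    threshold: float


def pixel_trend(cover: np.ndarray, epoch_midpoints: np.ndarray) -> TrendMap:
    """OLS slope of cover against year at each pixel.

    ``cover`` has shape ``(n_epochs, ny, nx)`` (NaN = missing epoch); the
    abscissa is the epoch midpoint in calendar years.  Pixels with fewer
    than two non-missing epochs get NaN slope.
    """
    slope, intercept, pvalue, n = ols_slope(cover, np.asarray(epoch_midpoints, dtype=float))
    return TrendMap(slope=slope, intercept=intercept, pvalue=pvalue, n=n)


def logit_trend(cover: np.ndarray, epoch_midpoints: np.ndarray, eps: float = 0.005) -> TrendMap:
    """Trend of logit-transformed cover, with covers clamped to [eps, 1-eps]."""
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    c = np.clip(np.asarray(cover, dtype=float), eps, 1.0 - eps)
    c = np.where(np.isnan(cover), np.nan, c)
    z = np.log(c / (1.0 - c))
    out = pixel_trend(z, epoch_midpoints)
    out.scale = "logit"
    return out


def _block_reduce(arr: np.ndarray, cell: int, how: str = "mean") -> np.ndarray:
    ny, nx = arr.shape
    if ny % cell or nx % cell:
        raise ValueError("grid dimensions must be a multiple of the cell size")
    blocks = arr.reshape(ny // cell, cell, nx // cell, cell).swapaxes(1, 2)
    if how == "mean":
        return blocks.mean(axis=(2, 3))
    raise ValueError(how)


def quality_weights(
    layers: QualityLayers,
    mask_excluded: np.ndarray,
    cell_size: int,
    n_epochs: int,
    target_observations: int,
    exclusion_quantile: float = 0.25,
) -> CellWeights:
    """Cell-level quality score, exclusion flags and model weights.

    Per-pixel quality is the product of the normalized timepoint count
    (``timepoints / n_epochs``) and the normalized observation count
    (``min(observations / target_observations, 1)``); masked pixels score
    zero.  The cell score is the mean pixel quality, which equals
    (mean unmasked quality) x (unmasked fraction).  Cells scoring strictly
    below the ``exclusion_quantile`` quantile (linear interpolation) of all
    cell scores are flagged excluded and receive weight 0.
    """
    tp = np.asarray(layers.timepoints, dtype=float)
    ob = np.asarray(layers.observations, dtype=float)
    if tp.size == 0:
        raise ValueError("empty quality layers")
    pix = (tp / float(n_epochs)) * np.minimum(ob / float(target_observations), 1.0)
    pix = np.where(mask_excluded, 0.0, pix)
    layers.score = pix
    score = _block_reduce(pix, cell_size)
    return exclude_low_quality(score, exclusion_quantile)


def exclude_low_quality(score: np.ndarray, exclusion_quantile: float = 0.25) -> CellWeights:
    """Flag cells whose quality score falls strictly below the given quantile.

    The threshold is the linear-interpolation quantile of all cell scores;
    ties at the threshold are retained (strict ``<``), so a degenerate
    all-equal score field excludes nothing.
    """
    score = np.asarray(score, dtype=float)
    if score.size == 0:
        raise ValueError("empty cell set")
    threshold = float(np.percentile(score, 100.0 * exclusion_quantile))
    excluded = score < threshold
    weight = np.where(excluded, 0.0, score)
    return CellWeights(score=score, weight=weight, excluded=excluded, threshold=threshold)
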