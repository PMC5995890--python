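"""Per-epoch time-series spectral metrics.

Each pixel's cloud-free observation series within an epoch is summarized,
band by band and index by index, into the metric feature set used to predict
fractional woody cover: minimum, maximum, the 10/25/50/75/90th percentiles,
and mean reflectance over the 10-25, 25-50, 50-75, 75-90 and 25-75 percentile
windows.  For the three vegetation indices (NDVI, SAVI, EVI) the temporal
variance and range are added, since woody and herbaceous vegetation separate
most clearly in their phenological dynamics.

Percentiles use linear interpolation between closest ranks.  Windowed means
default to the value-window reading (observations whose values fall inside
the percentile interval, inclusive); a rank-window variant is available via
``window="rank"``.  Variance is the population variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack import BANDS, SceneStack

__all__ = [
    "INDICES",
    "WINDOWS",
    "MetricCube",
    "vegetation_indices",
    "ndvi",
    "savi",
    "evi",
    "cloud_filter",
    "epoch_metrics",
    "build_metric_cube",
    "harmonize_sensors",
]

INDICES = ("ndvi", "savi", "evi")
PERCENTILES = (10, 25, 50, 75, 90)
WINDOWS = ((10, 25), (25, 50), (50, 75), (75, 90), (25, 75))

SAVI_L = 0.5
EVI_G, EVI_C1, EVI_C2, EVI_L = 2.5, 6.0, 7.5, 1.0


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den == 0, np.nan, out)


def ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    return _safe_div(nir - red, nir + red)


def savi(nir: np.ndarray, red: np.ndarray, L: float = SAVI_L) -> np.ndarray:
    return _safe_div((1.0 + L) * (nir - red), nir + red + L)


def evi(nir: np.ndarray, red: np.ndarray, blue: np.ndarray) -> np.ndarray:
    return _safe_div(EVI_G * (nir - red), nir + EVI_C1 * red - EVI_C2 * blue + EVI_L)


def vegetation_indices(refl: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """NDVI, SAVI and EVI from a band-name -> array mapping."""
    for b in ("blue", "red", "nir"):
        if b not in refl:
            raise KeyError(f"missing required band {b!r}")
    return {
        "ndvi": ndvi(refl["nir"], refl["red"]),
        "savi": savi(refl["nir"], refl["red"]),
        "evi": evi(refl["nir"], refl["red"], refl["blue"]),
    }


def cloud_filter(stack: SceneStack) -> SceneStack:
    """Mask out invalid (cloudy) observations pixel-wise.

    Returns a stack whose reflectance is NaN wherever the validity flag is
    False; observation order is preserved, counts are recoverable from the
    flags.
    """
    out = stack.copy()
    out.refl[~np.broadcast_to(stack.valid[:, None], stack.refl.shape)] = np.nan
    return out


def _windowed_means_value(values: np.ndarray, pcts: np.ndarray) -> dict[str, np.ndarray]:
    """Mean of observations whose values lie inside each percentile interval.

    Short series can leave a window empty (no observation between the
    interpolated bounds); the documented fallback is the interpolated
    percentile at the window midpoint, keeping metrics defined whenever the
    series is non-empty.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mids = {
            (lo, hi): np.nanpercentile(values, (lo + hi) / 2.0, axis=0, method="linear")
            for lo, hi in WINDOWS
        }
    out = {}
    for lo, hi in WINDOWS:
        plo = pcts[PERCENTILES.index(lo)]
        phi = pcts[PERCENTILES.index(hi)]
        inside = (values >= plo) & (values <= phi)
        cnt = inside.sum(axis=0)
        s = np.where(inside, values, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = s / cnt
        out[f"m{lo}_{hi}"] = np.where(cnt > 0, m, mids[(lo, hi)])
    return out


def _windowed_means_rank(values: np.ndarray) -> dict[str, np.ndarray]:
    """Mean of observations whose rank position lies inside each window.

    Position of the i-th of m sorted values is 100*i/(m-1); a single
    observation is assigned to every window.
    """
    srt = np.sort(values, axis=0)  # NaN sort to the end
    m = (~np.isnan(values)).sum(axis=0)
    idx = np.arange(values.shape[0]).reshape((-1,) + (1,) * (values.ndim - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = 100.0 * idx / np.maximum(m - 1, 1)
    pos = np.where(m == 1, 50.0, pos)  # singleton contributes everywhere
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mids = {
            (lo, hi): np.nanpercentile(values, (lo + hi) / 2.0, axis=0, method="linear")
            for lo, hi in WINDOWS
        }
    out = {}
    for lo, hi in WINDOWS:
        inside = (idx < m) & (pos >= lo) & (pos <= hi)
        cnt = inside.sum(axis=0)
        s = np.where(inside, np.where(np.isnan(srt), 0.0, srt), 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = s / cnt
        out[f"m{lo}_{hi}"] = np.where(cnt > 0, mu, mids[(lo, hi)])
    return out


def epoch_metrics(values: np.ndarray, extras: bool = False, window: str = "value") -> dict[str, np.ndarray]:
    """Summaries of one channel's observation series along the leading axis.

    ``values`` has shape (n_obs, ...) with NaN marking filtered observations;
    empty series yield NaN metrics.  With ``extras=True`` the population
    variance and range are included (used for vegetation indices).
    """
    values = np.asarray(values, dtype=float)
    n = (~np.isnan(values)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        vmin = np.nanmin(values, axis=0)
        vmax = np.nanmax(values, axis=0)
        pcts = np.nanpercentile(values, PERCENTILES, axis=0, method="linear")
    out: dict[str, np.ndarray] = {"min": vmin, "max": vmax}
    for q, arr in zip(PERCENTILES, pcts):
        out[f"p{q}"] = arr
    if window == "value":
        out.update(_windowed_means_value(values, pcts))
    elif window == "rank":
        out.update(_windowed_means_rank(values))
    else:
        raise ValueError("window must be 'value' or 'rank'")
    if extras:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(values, axis=0)
            var = np.nanmean((values - mean) ** 2, axis=0)  # population variance
        out["var"] = var
        out["range"] = vmax - vmin
    empty = n == 0
    if np.any(empty):
        for key, arr in out.items():
            out[key] = np.where(empty, np.nan, arr)
    return out


@dataclass
class MetricCube:
    """Per-pixel, per-epoch metric features.

    ``features`` maps "<channel>_<metric>" to arrays of shape
    (n_epochs, ny, nx); ``counts`` is the valid-observation count behind each
    pixel/epoch (metrics are NaN where it is zero).
    """

    features: dict[str, np.ndarray]
    counts: np.ndarray
    epochs: tuple[tuple[float, float], ...]
    window: str = "value"

    @property
    def feature_names(self) -> list[str]:
        return list(self.features)

    @property
    def n_epochs(self) -> int:
        return self.counts.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.counts.shape[1], self.counts.shape[2]

    def to_frame(self, epoch: int) -> pd.DataFrame:
        """Feature table for one epoch, one row per pixel (row-major order)."""
        ny, nx = self.grid_shape
        data = {k: v[epoch].ravel() for k, v in self.features.items()}
        df = pd.DataFrame(data)
        df.insert(0, "row", np.repeat(np.arange(ny), nx))
        df.insert(1, "col", np.tile(np.arange(nx), ny))
        return df


def build_metric_cube(
    stack: SceneStack,
    epochs: tuple[tuple[float, float], ...],
    window: str = "value",
) -> MetricCube:
    """Cloud-filter a scene stack and compute the full per-epoch feature set."""
    filtered = cloud_filter(stack)
    ny, nx = stack.grid_shape
    n_epochs = len(epochs)
    features: dict[str, np.ndarray] = {}
    counts = np.zeros((n_epochs, ny, nx), dtype=int)
    for e in range(n_epochs):
        sel = filtered.epoch == e
        counts[e] = filtered.valid[sel].sum(axis=0) if sel.any() else 0
        channels: dict[str, np.ndarray] = {b: filtered.refl[sel, i] for i, b in enumerate(stack.bands)}
        channels.update(
            vegetation_indices({b: channels[b] for b in ("blue", "red", "nir")})
        )
        for name, series in channels.items():
            extras = name in INDICES
            mets = epoch_metrics(series, extras=extras, window=window)
            for mname, arr in mets.items():
                key = f"{name}_{mname}"
                if key not in features:
                    features[key] = np.full((n_epochs, ny, nx), np.nan)
                features[key][e] = arr
    return MetricCube(features=features, counts=counts, epochs=tuple(epochs), window=window)


def harmonize_sensors(
    stack: SceneStack,
    coefficients: dict[str, dict[str, tuple[float, float]]],
    primary: str,
) -> SceneStack:
    """Cross-calibrate secondary sensors onto the primary and merge by date.

    ``coefficients[sensor][band] = (gain, bias)`` applies ``gain*x + bias``
    band-wise to that sensor's reflectance.  Every sensor present in the
    stack other than the primary must have coefficients.
    """
    out = stack.copy()
    present = set(np.unique(stack.sensor).tolist())
    for s in sorted(present - {primary}):
        if s not in coefficients:
            raise KeyError(f"no cross-calibration coefficients for sensor {s!r}")
        sel = out.sensor == s
        for i, b in enumerate(out.bands):
            gain, bias = coefficients[s][b]
            out.refl[sel, i] = gain * out.refl[sel, i] + bias
    order = np.argsort(out.dates, kind="stable")
    out.dates = out.dates[order]
    out.epoch = out.epoch[order]
    out.sensor = out.sensor[order]
    out.refl = out.refl[order]
    out.valid = out.valid[order]
    return out
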