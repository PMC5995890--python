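"""Fractional-cover regression on time-series spectral metrics.

Quadrat labels (cover quantized to quarters) are joined to their pixel/epoch
metric vectors, rows violating the quadrat protocol are dropped (acquisition
date outside the epoch range, or any interpreter uncertainty), and a random
forest regressor is fitted per sensor group.  Two validation figures are
recorded, mirroring the dual-validation convention for such models: the
forest's internal out-of-bag R2 and the R2/RMSE on an independent hold-out
split stratified by label class.  Predictions are clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import train_test_split

from .metrics import MetricCube

__all__ = [
    "TrainingTable",
    "CoverRegressor",
    "assemble_training",
    "fit_cover_regressor",
    "predict_cover",
]

LABEL_CLASSES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class TrainingTable:
    """Quadrat rows joined to metric features, after protocol exclusions."""

    data: pd.DataFrame
    feature_names: list[str]
    dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.data["label"])) - set(LABEL_CLASSES)
        if bad:
            raise ValueError(f"labels outside the quarter classes: {sorted(bad)}")
        if self.data.get("uncertain", pd.Series(dtype=bool)).any():
            raise ValueError("uncertain rows must be dropped before training")


def assemble_training(
    quadrats: pd.DataFrame,
    cube: MetricCube,
    epochs: tuple[tuple[float, float], ...],
    sensor_by_epoch: tuple[str, ...] | None = None,
) -> TrainingTable:
    """Join quadrats to metric vectors and apply the two exclusion rules.

    A quadrat is dropped if its acquisition date falls outside its epoch's
    date range, or if its uncertainty flag is set.  Rows whose pixel has no
    valid observations (all-NaN metrics) are also dropped and reported.
    """
    ny, nx = cube.grid_shape
    q = quadrats.copy()
    if ((q["row"] < 0) | (q["row"] >= ny) | (q["col"] < 0) | (q["col"] >= nx)).any():
        raise ValueError("quadrat outside raster extent")
    starts = np.array([a for a, _ in epochs])
    ends = np.array([b for _, b in epochs])
    e = q["epoch"].to_numpy()
    date_ok = (q["date"].to_numpy() >= starts[e]) & (q["date"].to_numpy() <= ends[e])
    certain = ~q["uncertain"].to_numpy().astype(bool)
    n_date = int((~date_ok).sum())
    n_unc = int((certain[date_ok] == False).sum())  # noqa: E712 - count among date-valid rows
    keep = date_ok & certain
    q = q[keep].reset_index(drop=True)

    feats = {
        name: arr[q["epoch"].to_numpy(), q["row"].to_numpy(), q["col"].to_numpy()]
        for name, arr in cube.features.items()
    }
    fdf = pd.DataFrame(feats)
    complete = ~fdf.isna().any(axis=1)
    n_missing = int((~complete).sum())
    data = pd.concat([q, fdf], axis=1)[complete.to_numpy()].reset_index(drop=True)
    if sensor_by_epoch is not None:
        data["sensor"] = [sensor_by_epoch[e] for e in data["epoch"]]
    return TrainingTable(
        data=data,
        feature_names=list(cube.features),
        dropped={"date": n_date, "uncertain": n_unc, "missing_metrics": n_missing},
    )


@dataclass
class CoverRegressor:
    """Fitted per-sensor-group forest plus validation statistics."""

    model: RandomForestRegressor
    sensor_group: str
    feature_names: list[str]
    oob_r2: float
    holdout_r2: float
    holdout_rmse: float
    n_train: int
    n_holdout: int
    seed: int


def fit_cover_regressor(
    table: TrainingTable,
    sensor_group: str = "all",
    n_estimators: int = 500,
    min_samples_leaf: int = 1,
    seed: int = 0,
    holdout_fraction: float = 0.2,
    min_rows: int = 50,
) -> CoverRegressor:
    """Random-forest regression of quantized cover labels on metric features.

    The hold-out split is stratified by label class and disjoint from the
    training rows; both the out-of-bag R2 (internal validation) and the
    hold-out R2/RMSE (independent validation) are recorded.  Deterministic
    given the seed.
    """
    data = table.data
    if sensor_group != "all":
        if "sensor" not in data:
            raise ValueError("training table carries no sensor column")
        data = data[data["sensor"] == sensor_group].reset_index(drop=True)
    y = data["label"].to_numpy(dtype=float)
    if len(data) < min_rows:
        raise ValueError(f"only {len(data)} rows; need at least {min_rows}")
    if np.all(y == y[0]):
        raise ValueError("constant labels: R2 undefined")
    X = data[table.feature_names].to_numpy(dtype=float)
    # stratify by label class unless a class is too rare to split
    _, counts = np.unique(y, return_counts=True)
    strat = y if counts.min() >= 2 else None
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=strat
    )
    rf = RandomForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(Xtr, ytr)
    pred = np.clip(rf.predict(Xte), 0.0, 1.0)
    return CoverRegressor(
        model=rf,
        sensor_group=sensor_group,
        feature_names=table.feature_names,
        oob_r2=float(rf.oob_score_),
        holdout_r2=float(r2_score(yte, pred)),
        holdout_rmse=float(np.sqrt(mean_squared_error(yte, pred))),
        n_train=len(ytr),
        n_holdout=len(yte),
        seed=seed,
    )


def predict_cover(regressor: CoverRegressor, cube: MetricCube) -> np.ndarray:
    """Per-pixel cover prediction for every epoch, clipped to [0, 1].

    Pixels with any missing metric (no valid observations, or masked) stay
    NaN.
    """
    missing = [f for f in regressor.feature_names if f not in cube.features]
    if missing:
        raise ValueError(f"metric cube lacks model features: {missing[:5]}")
    n_epochs = cube.n_epochs
    ny, nx = cube.grid_shape
    out = np.full((n_epochs, ny, nx), np.nan)
    for e in range(n_epochs):
        cols = [cube.features[f][e].ravel() for f in regressor.feature_names]
        X = np.column_stack(cols)
        ok = ~np.isnan(X).any(axis=1)
        if ok.any():
            pred = np.clip(regressor.model.predict(X[ok]), 0.0, 1.0)
            flat = out[e].ravel()
            flat[ok] = pred
            out[e] = flat.reshape(ny, nx)
    return out
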