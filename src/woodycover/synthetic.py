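"""Seeded synthetic subcontinent with known woody-cover dynamics.

The generator replaces the continental satellite/climate archives with a toy
landscape in which every quantity the pipeline estimates is known exactly:

* smooth covariate fields with prescribed per-pixel linear trends,
* fractional woody cover evolving per epoch under a logistic-bounded linear
  forcing built from those covariates (including a quadratic population-
  growth term that produces a hump-shaped response),
* a spectral observation model — each scene is a linear mixture of fixed
  woody and herbaceous endmember spectra weighted by true cover, with
  seasonal herbaceous phenology, per-sensor linear band offsets, Gaussian
  reflectance noise and independent cloud flags,
* photo-interpretation quadrats whose labels are the true cover quantized
  to the nearest quarter {0, 0.25, 0.5, 0.75, 1} (ties round half up).

Everything is a pure function of (config, seed): the same configuration
reproduces bit-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stack import BANDS, SceneStack
from .trends import ols_slope

__all__ = [
    "CovariateSpec",
    "ObservationSpec",
    "LandscapeConfig",
    "CovariateSet",
    "TrueState",
    "WOODY_SPECTRUM",
    "HERB_GREEN_SPECTRUM",
    "HERB_DRY_SPECTRUM",
    "generate_covariates",
    "generate_true_cover",
    "simulate_scenes",
    "sample_quadrats",
    "quantize_label",
    "generate_mask_inputs",
    "generate_driver_table",
    "default_config",
    "save_config",
    "load_config",
]

# fixed endmember reflectance (blue, green, red, nir, swir1, swir2); values
# are plausible surface-reflectance magnitudes, frozen for reproducibility
WOODY_SPECTRUM = np.array([0.035, 0.062, 0.045, 0.30, 0.17, 0.09])
HERB_GREEN_SPECTRUM = np.array([0.05, 0.09, 0.065, 0.40, 0.24, 0.13])
HERB_DRY_SPECTRUM = np.array([0.10, 0.14, 0.21, 0.27, 0.32, 0.24])

DEFAULT_EPOCHS = (
    (1986.0, 1991.0),
    (1991.0, 1996.0),
    (1996.0, 2001.0),
    (2001.0, 2006.0),
    (2006.0, 2011.0),
    (2011.0, 2016.0),
)

# substream tags so each generator op draws from an independent stream
_TAG_COVARIATES, _TAG_COVER, _TAG_SCENES, _TAG_QUADRATS, _TAG_MASK = range(5)


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], corr_length: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with the given
    correlation length.

    Centering makes a configured mean level or trend the *realized* spatial
    mean, so small grids cannot drift into saturation by chance.
    """
    white = rng.standard_normal(shape)
    if corr_length <= 0:
        return white - white.mean()
    f = gaussian_filter(white, sigma=corr_length, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


@dataclass
class CovariateSpec:
    """One synthetic covariate: spatial field parameters and temporal trend."""

    name: str
    role: str = "driver"            # "driver" (trend enters model) / "facilitator"
    mean: float = 0.0               # spatial mean level
    mean_field_sd: float = 1.0      # SD of the smooth mean field
    trend: float = 0.0              # mean per-year trend
    trend_field_sd: float = 0.0     # SD of the smooth trend field
    corr_length: float = 6.0        # correlation length (pixels)
    noise_sd: float = 0.0           # interannual observation noise
    time_varying: bool = True


@dataclass
class ObservationSpec:
    """Scene observation model parameters."""

    n_per_epoch: int = 12
    cloud_prob: float = 0.3
    noise_sd: float = 0.02
    # sensor label per epoch, and per-sensor (gain, bias) per band
    sensor_by_epoch: tuple[str, ...] = ("TM", "TM", "TM", "ETM", "ETM", "ETM")
    sensor_coefficients: dict = field(
        default_factory=lambda: {
            "TM": {b: (1.0, 0.0) for b in BANDS},
            "ETM": {
                "blue": (1.03, 0.002),
                "green": (0.99, 0.004),
                "red": (1.02, -0.002),
                "nir": (0.98, 0.005),
                "swir1": (1.01, 0.003),
                "swir2": (0.97, 0.002),
            },
        }
    )


@dataclass
class LandscapeConfig:
    """Full study design of the toy subcontinent."""

    ny: int = 64
    nx: int = 64
    cell_size: int = 8                           # fine pixels per coarse cell
    epochs: tuple[tuple[float, float], ...] = DEFAULT_EPOCHS
    covariates: tuple[CovariateSpec, ...] = ()
    trend_coefs: dict = field(default_factory=dict)       # covariate trend -> forcing
    mean_coefs: dict = field(default_factory=dict)        # covariate mean -> forcing
    quad_trend_coefs: dict = field(default_factory=dict)  # squared trend -> forcing (hump)
    cover_noise_sd: float = 0.0                  # dynamic noise per epoch step
    initial_cover_mean: float = 0.45
    initial_cover_sd: float = 0.18
    initial_cover_fine_sd: float = 0.12          # pixel-scale heterogeneity
    initial_corr_length: float = 6.0
    obs: ObservationSpec = field(default_factory=ObservationSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ny <= 0 or self.nx <= 0:
            raise ValueError("grid dimensions must be positive")
        for (a0, a1), (b0, b1) in zip(self.epochs, self.epochs[1:]):
            if a1 > b0 or a0 >= a1:
                raise ValueError("epochs must be ordered and non-overlapping")
        if not 0.0 <= self.obs.cloud_prob <= 1.0:
            raise ValueError("cloud probability must lie in [0, 1]")
        names = {c.name for c in self.covariates}
        for coefs in (self.trend_coefs, self.mean_coefs, self.quad_trend_coefs):
            unknown = set(coefs) - names
            if unknown:
                raise ValueError(f"coefficients reference unknown covariates: {sorted(unknown)}")
        active = (
            {k for k, v in self.trend_coefs.items() if v != 0}
            | {k for k, v in self.mean_coefs.items() if v != 0}
            | {k for k, v in self.quad_trend_coefs.items() if v != 0}
        )
        if self.covariates and not (names - active):
            raise ValueError("at least one zero-effect (null) covariate is required")

    @property
    def epoch_midpoints(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.epochs])

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.epochs[0][0], self.epochs[-1][1] + 1.0)

    def active_covariates(self) -> list[str]:
        out = []
        for c in self.covariates:
            if (
                self.trend_coefs.get(c.name, 0)
                or self.mean_coefs.get(c.name, 0)
                or self.quad_trend_coefs.get(c.name, 0)
            ):
                out.append(c.name)
        return out

    def null_covariates(self) -> list[str]:
        return [c.name for c in self.covariates if c.name not in self.active_covariates()]


@dataclass
class CovariateField:
    name: str
    mean_field: np.ndarray                 # (ny, nx)
    trend_field: np.ndarray                # (ny, nx), per year
    series: np.ndarray | None              # (n_years, ny, nx) if time-varying
    years: np.ndarray | None


@dataclass
class CovariateSet:
    fields: dict[str, CovariateField]

    def __getitem__(self, name: str) -> CovariateField:
        return self.fields[name]

    def names(self) -> list[str]:
        return list(self.fields)


def generate_covariates(config: LandscapeConfig) -> CovariateSet:
    """Smooth covariate fields with prescribed linear trends.

    Time-varying covariates get an annual series
    ``mean_field + trend_field * (year - midyear) + noise``; static ones
    only the mean field.  Deterministic given the config seed.
    """
    rng = _rng(config.seed, _TAG_COVARIATES)
    years = config.years
    midyear = years.mean()
    out: dict[str, CovariateField] = {}
    for spec in config.covariates:
        mean_field = spec.mean + spec.mean_field_sd * _smooth_field(rng, (config.ny, config.nx), spec.corr_length)
        trend_field = spec.trend + (
            spec.trend_field_sd * _smooth_field(rng, (config.ny, config.nx), spec.corr_length)
            if spec.trend_field_sd > 0
            else 0.0
        )
        trend_field = np.broadcast_to(np.asarray(trend_field, dtype=float), (config.ny, config.nx)).copy()
        series = None
        yr = None
        if spec.time_varying:
            yr = years
            series = mean_field[None] + trend_field[None] * (years - midyear)[:, None, None]
            if spec.noise_sd > 0:
                series = series + spec.noise_sd * rng.standard_normal(series.shape)
        out[spec.name] = CovariateField(
            name=spec.name, mean_field=mean_field, trend_field=trend_field, series=series, years=yr
        )
    return CovariateSet(fields=out)


@dataclass
class TrueState:
    """Ground truth: cover per epoch, its OLS slope, and the generating model."""

    cover: np.ndarray                      # (n_epochs, ny, nx) in [0, 1]
    slope: np.ndarray                      # per-pixel OLS slope of cover vs midpoint year
    covariates: CovariateSet
    config: LandscapeConfig
    forcing: np.ndarray                    # the per-pixel linear forcing used

    def __post_init__(self) -> None:
        if np.nanmin(self.cover) < 0 or np.nanmax(self.cover) > 1:
            raise ValueError("true cover must stay within [0, 1]")


def generate_true_cover(covariates: CovariateSet, config: LandscapeConfig) -> TrueState:
    """Evolve cover per epoch under logistic-bounded linear forcing.

    The per-pixel forcing is a linear combination of covariate trend fields,
    mean fields and squared trend fields (the latter giving the hump-shaped
    population-growth response); each epoch step adds
    ``dt * forcing * cover * (1 - cover)`` plus optional dynamic noise, and
    the result is clipped to [0, 1].
    """
    for coefs in (config.trend_coefs, config.mean_coefs, config.quad_trend_coefs):
        unknown = set(coefs) - set(covariates.names())
        if unknown:
            raise KeyError(f"unknown coefficient names: {sorted(unknown)}")
    rng = _rng(config.seed, _TAG_COVER)
    ny, nx = config.ny, config.nx
    forcing = np.zeros((ny, nx))
    for name, b in config.trend_coefs.items():
        forcing += b * covariates[name].trend_field
    for name, b in config.mean_coefs.items():
        f = covariates[name].mean_field
        forcing += b * (f - f.mean())
    for name, b in config.quad_trend_coefs.items():
        forcing += b * covariates[name].trend_field ** 2

    c0 = (
        config.initial_cover_mean
        + config.initial_cover_sd * _smooth_field(rng, (ny, nx), config.initial_corr_length)
        + (config.initial_cover_fine_sd * rng.standard_normal((ny, nx)) if config.initial_cover_fine_sd else 0.0)
    )
    c = np.clip(c0, 0.0, 1.0)
    mids = config.epoch_midpoints
    covers = [c]
    for k in range(1, len(mids)):
        dt = mids[k] - mids[k - 1]
        step = forcing
        if config.cover_noise_sd > 0:
            step = step + config.cover_noise_sd * rng.standard_normal((ny, nx))
        c = np.clip(c + dt * step * c * (1.0 - c), 0.0, 1.0)
        covers.append(c)
    cover = np.stack(covers)
    slope, _, _, _ = ols_slope(cover, mids)
    return TrueState(cover=cover, slope=slope, covariates=covariates, config=config, forcing=forcing)


def _herb_greenness(dates: np.ndarray) -> np.ndarray:
    """Seasonal herbaceous phenology phase in [0, 1] (1 = peak green)."""
    frac = np.mod(dates, 1.0)
    return 0.5 + 0.5 * np.cos(2.0 * np.pi * (frac - 0.15))


def simulate_scenes(state: TrueState, config: LandscapeConfig | None = None) -> SceneStack:
    """Dated multiband observations of the true landscape.

    Reflectance is the cover-weighted mixture of the woody endmember and a
    phenology-dependent herbaceous endmember, passed through the observing
    sensor's linear band transform, plus Gaussian noise; cloud flags are
    independent Bernoulli draws per pixel and observation.
    """
    config = config or state.config
    obs = config.obs
    rng = _rng(config.seed, _TAG_SCENES)
    ny, nx = config.ny, config.nx
    dates, epoch_idx, sensors = [], [], []
    for e, (a, b) in enumerate(config.epochs):
        d = np.sort(rng.uniform(a, b, obs.n_per_epoch))
        dates.append(d)
        epoch_idx.append(np.full(obs.n_per_epoch, e))
        sensors.append(np.full(obs.n_per_epoch, obs.sensor_by_epoch[e], dtype=object))
    dates = np.concatenate(dates)
    epoch_idx = np.concatenate(epoch_idx).astype(int)
    sensors = np.concatenate(sensors)

    n = dates.shape[0]
    refl = np.empty((n, len(BANDS), ny, nx))
    green = _herb_greenness(dates)
    for i in range(n):
        c = state.cover[epoch_idx[i]]
        herb = green[i] * HERB_GREEN_SPECTRUM + (1.0 - green[i]) * HERB_DRY_SPECTRUM
        clean = c[None] * WOODY_SPECTRUM[:, None, None] + (1.0 - c)[None] * herb[:, None, None]
        coeff = obs.sensor_coefficients[sensors[i]]
        for bi, band in enumerate(BANDS):
            gain, bias = coeff[band]
            refl[i, bi] = gain * clean[bi] + bias
    if obs.noise_sd > 0:
        refl += obs.noise_sd * rng.standard_normal(refl.shape)
    valid = rng.random((n, ny, nx)) >= obs.cloud_prob
    return SceneStack(dates=dates, epoch=epoch_idx, sensor=sensors, refl=refl, valid=valid)


LABEL_CLASSES = (0.0, 0.25, 0.5, 0.75, 1.0)


def quantize_label(cover: np.ndarray) -> np.ndarray:
    """Nearest quarter-class label; ties (0.125, 0.375, ...) round half up."""
    x = np.clip(np.asarray(cover, dtype=float), 0.0, 1.0)
    return np.clip(np.floor(x * 4.0 + 0.5), 0.0, 4.0) / 4.0


def sample_quadrats(
    state: TrueState,
    n: int,
    seed: int | None = None,
    label_noise_sd: float = 0.0,
    uncertain_frac: float = 0.0,
    date_violation_frac: float = 0.0,
    mask_excluded: np.ndarray | None = None,
) -> pd.DataFrame:
    """Photo-interpretation quadrats with quantized cover labels.

    ``n`` pixel locations are drawn without replacement from the unmasked
    area; each quadrat gets a random epoch, an acquisition date inside that
    epoch (a configurable fraction is deliberately mis-dated to exercise the
    date-range exclusion), a label equal to the true cover plus optional
    interpreter noise quantized to the nearest quarter, and an uncertainty
    flag on a configurable fraction.
    """
    if n < 1:
        raise ValueError("need n >= 1 quadrats")
    config = state.config
    rng = _rng(config.seed if seed is None else seed, _TAG_QUADRATS)
    ny, nx = config.ny, config.nx
    free = np.ones((ny, nx), dtype=bool) if mask_excluded is None else ~mask_excluded
    avail = np.flatnonzero(free.ravel())
    if n > avail.size:
        raise ValueError(f"requested {n} quadrats but only {avail.size} unmasked pixels")
    pick = rng.choice(avail, size=n, replace=False)
    rows, cols = np.unravel_index(pick, (ny, nx))
    epochs = rng.integers(0, len(config.epochs), size=n)
    starts = np.array([config.epochs[e][0] for e in epochs])
    ends = np.array([config.epochs[e][1] for e in epochs])
    dates = rng.uniform(starts, ends)
    violate = rng.random(n) < date_violation_frac
    dates = np.where(violate, starts - rng.uniform(0.5, 3.0, size=n), dates)
    cover = state.cover[epochs, rows, cols]
    if label_noise_sd > 0:
        cover = cover + label_noise_sd * rng.standard_normal(n)
    labels = quantize_label(cover)
    uncertain = rng.random(n) < uncertain_frac
    return pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "epoch": epochs,
            "date": dates,
            "label": labels,
            "uncertain": uncertain,
        }
    )


def generate_mask_inputs(config: LandscapeConfig):
    """Synthetic masking rasters: tree cover/height, forest change, landcover.

    Landcover codes: 0 natural, 1 urban, 2 water, 3 cropland.
    """
    from .mask import MaskInputs

    rng = _rng(config.seed, _TAG_MASK)
    shape = (config.ny, config.nx)
    tree_cover = np.clip(0.25 + 0.2 * _smooth_field(rng, shape, 5.0), 0.0, 1.0)
    tall = _smooth_field(rng, shape, 5.0) > 0.8
    loss = rng.random(shape) < 0.06
    gain = rng.random(shape) < 0.06
    landcover = np.zeros(shape, dtype=int)
    lc_field = _smooth_field(rng, shape, 4.0)
    landcover[lc_field > 1.7] = 1
    landcover[lc_field < -1.9] = 2
    landcover[(lc_field > 1.2) & (lc_field <= 1.7)] = 3
    return MaskInputs(tree_cover=tree_cover, tall=tall, loss=loss, gain=gain, landcover=landcover)


def default_config(seed: int = 0, **overrides) -> LandscapeConfig:
    """The stated toy-subcontinent study design.

    Three active drivers shape cover change — a negative burned-area trend
    effect, positive rainfall- and temperature-trend effects — plus a
    hump-shaped population-growth response and three zero-effect null
    covariates; coefficient magnitudes are set so per-pixel cover changes
    span roughly +-0.3 over the 30-year record, the spatially variable
    regime the method targets.
    """
    covariates = (
        CovariateSpec("rain", mean=650.0, mean_field_sd=150.0, trend=1.0, trend_field_sd=10.0, corr_length=8.0),
        CovariateSpec("temp", mean=24.0, mean_field_sd=2.0, trend=0.02, trend_field_sd=0.05, corr_length=10.0),
        CovariateSpec("fire", mean=0.25, mean_field_sd=0.10, trend=-0.002, trend_field_sd=0.010, corr_length=6.0),
        CovariateSpec("pop", mean=20.0, mean_field_sd=10.0, trend=0.3, trend_field_sd=0.5, corr_length=5.0),
        CovariateSpec("wind", mean=3.0, mean_field_sd=0.5, trend=0.0, trend_field_sd=0.01, corr_length=7.0),
        CovariateSpec("evap", mean=5.0, mean_field_sd=1.0, trend=0.0, trend_field_sd=0.02, corr_length=7.0),
        CovariateSpec("soil_sand", role="facilitator", mean=55.0, mean_field_sd=12.0, time_varying=False),
    )
    cfg = dict(
        covariates=covariates,
        # forcing units: fraction yr^-1 before the cover*(1-cover) factor;
        # magnitudes chosen for a net cover change near +0.08 over the three
        # decades with spatially variable sign (gains ~3x as widespread as
        # losses) and minimal saturation at the [0, 1] bounds
        trend_coefs={"rain": 0.003, "temp": 0.5, "fire": -2.5},
        quad_trend_coefs={"pop": -0.02},
        initial_cover_mean=0.40,
        initial_cover_sd=0.15,
        initial_cover_fine_sd=0.10,
        seed=seed,
    )
    cfg.update(overrides)
    return LandscapeConfig(**cfg)


def save_config(config: LandscapeConfig, path) -> None:
    """Serialize a landscape configuration to YAML."""
    import yaml
    from dataclasses import asdict
    from pathlib import Path

    doc = asdict(config)
    doc["epochs"] = [list(e) for e in config.epochs]
    doc["covariates"] = [asdict(c) for c in config.covariates]
    doc["obs"]["sensor_by_epoch"] = list(config.obs.sensor_by_epoch)
    doc["obs"]["sensor_coefficients"] = {
        s: {b: list(gb) for b, gb in bands.items()}
        for s, bands in config.obs.sensor_coefficients.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> LandscapeConfig:
    """Load a landscape configuration from YAML (inverse of save_config)."""
    import yaml
    from pathlib import Path

    doc = yaml.safe_load(Path(path).read_text())
    obs = doc.pop("obs")
    obs["sensor_by_epoch"] = tuple(obs["sensor_by_epoch"])
    obs["sensor_coefficients"] = {
        s: {b: tuple(gb) for b, gb in bands.items()}
        for s, bands in obs["sensor_coefficients"].items()
    }
    doc["obs"] = ObservationSpec(**obs)
    doc["epochs"] = tuple(tuple(e) for e in doc["epochs"])
    doc["covariates"] = tuple(CovariateSpec(**c) for c in doc["covariates"])
    return LandscapeConfig(**doc)


def generate_driver_table(
    n_cells: int = 400,
    seed: int = 0,
    noise_sd: float = 0.25,
    include_facilitators: bool = False,
):
    """Coarse-grid stated world for driver attribution.

    Builds a cell table with three signed active drivers (fire trend
    negative, rainfall and temperature trends positive), a hump-shaped
    population-growth term, and three null covariates, then the response

        y = 1.0*rain_trend + 0.6*temp_trend - 0.8*fire_trend
            + 0.5*pop_trend - 0.7*pop_trend**2 + noise

    on standardized predictors.  Returns ``(CovariateTable, truth dict)``
    where the truth records the generating coefficients, the active/null
    split and the noise level.  Quality weights are drawn uniform in
    [0.5, 1.5] and are independent of the response.
    """
    from .covariates import CovariateTable

    rng = _rng(seed, 7)
    side = int(np.sqrt(n_cells))
    coefs = {"rain_trend": 1.0, "temp_trend": 0.6, "fire_trend": -0.8}
    quad = {"pop_trend": (0.5, -0.7)}
    nulls = ["wind_trend", "evap_trend", "soilmoist_trend"]
    cols = {}
    for name in list(coefs) + list(quad) + nulls:
        cols[name] = rng.standard_normal(n_cells)
    y = noise_sd * rng.standard_normal(n_cells)
    for name, b in coefs.items():
        y = y + b * cols[name]
    for name, (a, b) in quad.items():
        y = y + a * cols[name] + b * cols[name] ** 2
    roles = {name: "driver" for name in cols}
    if include_facilitators:
        for name, b in (("rain_mean", 0.4), ("soil_sand", -0.3), ("elevation", 0.0)):
            cols[name] = rng.standard_normal(n_cells)
            y = y + b * cols[name]
            roles[name] = "facilitator"
    data = pd.DataFrame(cols)
    data.insert(0, "x", np.arange(n_cells) % max(side, 1))
    data.insert(1, "y_coord", np.arange(n_cells) // max(side, 1))
    data["cover_change"] = y
    data["weight"] = rng.uniform(0.5, 1.5, n_cells)
    table = CovariateTable(data=data, roles=roles, provenance={k: "observed" for k in roles})
    truth = {
        "coefs": coefs,
        "quad": quad,
        "active": list(coefs) + list(quad),
        "null": nulls,
        "noise_sd": noise_sd,
        "response": "cover_change",
        "weight": "weight",
    }
    return table, truth
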