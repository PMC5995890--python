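import numpy as np
import pytest

from woodycover.synthetic import (
    CovariateSpec,
    LandscapeConfig,
    ObservationSpec,
    default_config,
    generate_covariates,
    generate_driver_table,
    generate_true_cover,
    sample_quadrats,
    simulate_scenes,
)


@pytest.fixture(scope="session")
def small_config():
    """Compact landscape (32x32, 8 obs/epoch) for unit-level pipeline tests."""
    return default_config(seed=7, ny=32, nx=32, cell_size=8, obs=ObservationSpec(n_per_epoch=8))


@pytest.fixture(scope="session")
def small_state(small_config):
    cov = generate_covariates(small_config)
    return generate_true_cover(cov, small_config)


@pytest.fixture(scope="session")
def small_stack(small_state):
    return simulate_scenes(small_state)


@pytest.fixture(scope="session")
def small_cube(small_stack, small_config):
    from woodycover.metrics import build_metric_cube

    return build_metric_cube(small_stack, small_config.epochs)


@pytest.fixture(scope="session")
def small_training(small_state, small_cube, small_config):
    from woodycover.cover import assemble_training

    q = sample_quadrats(small_state, 800, seed=13)
    return assemble_training(q, small_cube, small_config.epochs, small_config.obs.sensor_by_epoch)


@pytest.fixture(scope="session")
def driver_table():
    """Coarse-grid driver-attribution world with known coefficients."""
    return generate_driver_table(n_cells=400, seed=3)


def noiseless_config(seed=5, **kw):
    """A tiny landscape with every stochastic term switched off."""
    covs = (
        CovariateSpec("rain", mean=600.0, mean_field_sd=100.0, trend=2.0, trend_field_sd=3.0, corr_length=4.0),
        CovariateSpec("temp", mean=24.0, mean_field_sd=1.0, trend=0.0, trend_field_sd=0.0, corr_length=4.0),
    )
    base = dict(
        ny=16,
        nx=16,
        cell_size=4,
        covariates=covs,
        trend_coefs={"rain": 0.01},
        cover_noise_sd=0.0,
        initial_cover_fine_sd=0.0,
        obs=ObservationSpec(n_per_epoch=6, cloud_prob=0.0, noise_sd=0.0),
        seed=seed,
    )
    base.update(kw)
    return LandscapeConfig(**base)
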