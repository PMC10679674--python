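import numpy as np
import pytest

from cottonvit import RunConfig, SimConfig, build_dataset, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_sim_config(**overrides) -> SimConfig:
    """A desk-scale study: 2 plates x 9 seeds, 60 bands over the full range."""
    base = dict(
        n_plates=2, seeds_per_plate=9, n_bands=60,
        wavelength_start_nm=391.0, wavelength_step_nm=11.0,
        absorption_bands=[(500.0, 30.0, 0.018), (700.0, 30.0, 0.015),
                          (900.0, 30.0, 0.012)],
        cell_px=20, rng_seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


def small_run_config(**overrides) -> RunConfig:
    base = dict(sim=small_sim_config(), spa_max_vars=5, spa_val_fraction=0.75,
                cars_n_mc=30, cars_cv_folds=3, rng_seed=11)
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    sim = simulate_dataset(small_sim_config())
    return sim, build_dataset(sim)


@pytest.fixture(scope="session")
def default_dataset():
    """The full default study (8 plates x 25 seeds x 520 bands, seed 42)."""
    sim = simulate_dataset(SimConfig())
    return sim, build_dataset(sim)
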