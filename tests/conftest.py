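import warnings

import numpy as np
import pytest

from vpdfire.config import (ClimateTruth, LogisticTruth, SyntheticConfig)

warnings.filterwarnings("ignore", category=FutureWarning)


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A tiny 2-ecoregion configuration used across unit tests."""
    base = dict(
        grid_shape=(4, 4),
        n_ecoregions=2,
        years=(1979, 2020),
        climate=[
            ClimateTruth(t_mean_c=20.0, rh_mean_pct=40.0, t_seasonal_amp_c=9.0,
                         rh_seasonal_amp_pct=15.0, ar1=0.6, t_noise_sd_c=3.0,
                         rh_noise_sd_pct=10.0),
            ClimateTruth(t_mean_c=14.0, rh_mean_pct=50.0, t_seasonal_amp_c=9.0,
                         rh_seasonal_amp_pct=15.0, ar1=0.6, t_noise_sd_c=3.0,
                         rh_noise_sd_pct=10.0),
        ],
        fire={
            "human": [LogisticTruth(alpha_vpd=2.0, beta_vpd=1.4),
                      LogisticTruth(alpha_vpd=2.0, beta_vpd=1.6)],
            "lightning": [LogisticTruth(alpha_vpd=2.0, beta_vpd=2.1),
                          LogisticTruth(alpha_vpd=2.0, beta_vpd=2.3)],
        },
        ignition_rates={"human": [40.0, 40.0], "lightning": [20.0, 20.0]},
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def synthetic_bundle():
    """Climate, covariates and a catalog from one small seeded config."""
    from vpdfire.synthetic import (generate_climate_grid, generate_covariates,
                                   generate_fire_catalog)

    config = small_config(seed=7)
    climate = generate_climate_grid(config)
    covariates = generate_covariates(config)
    catalog = generate_fire_catalog(climate, covariates, config)
    return config, climate, covariates, catalog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
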