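"""Configuration objects for synthetic data generation and pipeline runs.

All randomness in the package flows from a single integer seed through named
substreams (see :mod:`vpdfire.random`), so any stage can be re-run in
isolation and still reproduce its output byte-for-byte.
"""
from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

IgnitionType = Literal["human", "lightning"]
IGNITION_TYPES: tuple[str, str] = ("human", "lightning")


class ClimateTruth(BaseModel):
    """Per-ecoregion generative parameters for daily temperature and humidity.

    Temperature follows mean + seasonal cycle + linear trend + AR(1) noise;
    relative humidity is analogous with its seasonal cycle in antiphase
    (driest in summer) and a possibly negative trend.
    """

    model_config = ConfigDict(extra="forbid")

    t_mean_c: float
    rh_mean_pct: float = Field(gt=0.0, le=100.0)
    t_seasonal_amp_c: float = Field(ge=0.0)
    rh_seasonal_amp_pct: float = Field(ge=0.0)
    t_trend_c_per_decade: float = 0.0
    rh_trend_pct_per_decade: float = 0.0
    ar1: float = Field(default=0.0, ge=0.0, lt=1.0)
    t_noise_sd_c: float = Field(default=0.0, ge=0.0)
    rh_noise_sd_pct: float = Field(default=0.0, ge=0.0)


class LogisticTruth(BaseModel):
    """True logistic parameters for one ecoregion x ignition type stratum.

    ``alpha`` is the steepness (1/units of x) and ``beta`` the midpoint
    (units of x): large-fire probability for a single factor is
    ``1 / (1 + exp(-alpha * (x - beta)))``.  Signs follow the mechanism:
    drier air (VPD) and more fuel (NPP) raise the probability, denser
    population (suppression proxy) lowers it.
    """

    model_config = ConfigDict(extra="forbid")

    alpha_vpd: float = Field(gt=0.0)
    beta_vpd: float
    alpha_npp: float = Field(default=1.0, gt=0.0)
    beta_npp: float = -10.0
    alpha_pd: float = Field(default=-1.0, lt=0.0)
    beta_pd: float = 10.0


class EsmTruth(BaseModel):
    """Generative parameters for the pseudo-ESM forcing ensembles.

    Forced responses are regional-mean flammable-day trajectories (days/yr):
    GHG and OANT are linear ramps, NAT is a sinusoid (volcanic/solar
    analogue).  ALL = GHG + OANT + NAT by construction.  Members add AR(1)
    internal variability; control runs are pure internal variability.
    """

    model_config = ConfigDict(extra="forbid")

    ghg_trend_days_per_year: float = 0.4
    oant_trend_days_per_year: float = 0.35
    oant_curvature_days_per_year2: float = -0.008
    nat_sin_amp_days: float = 3.0
    nat_sin_period_years: float = 11.0
    nat_trend_days_per_year: float = 0.0
    n_models: int = Field(default=9, ge=1)
    n_members: int = Field(default=3, ge=1)
    n_controls: int = Field(default=19, ge=1)
    control_length_years: int = Field(default=420, ge=10)
    internal_ar1: float = Field(default=0.3, ge=0.0, lt=1.0)
    internal_sd_days: float = Field(default=2.5, gt=0.0)


class SyntheticConfig(BaseModel):
    """Everything needed to generate a fully synthetic study with known truth."""

    model_config = ConfigDict(extra="forbid")

    grid_shape: tuple[int, int] = (6, 8)
    n_ecoregions: int = Field(default=3, ge=1)
    years: tuple[int, int] = (1979, 2020)
    climate: list[ClimateTruth]
    fire: dict[str, list[LogisticTruth]]
    ignition_rates: dict[str, list[float]]
    unknown_cause_fraction: float = Field(default=0.085, ge=0.0, lt=1.0)
    one_day_duration_fraction: float = Field(default=0.79, ge=0.0, le=1.0)
    esm: EsmTruth = EsmTruth()
    seed: int = 0

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if self.years[1] < self.years[0]:
            raise ValueError("end year precedes start year")
        if self.n_years < 4:
            raise ValueError("need at least 4 years of data")
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid_shape entries must be positive")
        if self.grid_shape[0] < self.n_ecoregions:
            raise ValueError("need at least one grid row per ecoregion")
        if len(self.climate) != self.n_ecoregions:
            raise ValueError("climate truth must list one entry per ecoregion")
        for kind in IGNITION_TYPES:
            if kind not in self.fire or len(self.fire[kind]) != self.n_ecoregions:
                raise ValueError(f"fire truth missing or wrong length for {kind!r}")
            if kind not in self.ignition_rates or len(self.ignition_rates[kind]) != self.n_ecoregions:
                raise ValueError(f"ignition_rates missing or wrong length for {kind!r}")
        return self


class McmcConfig(BaseModel):
    """Sampler settings for the hierarchical logistic fit."""

    model_config = ConfigDict(extra="forbid")

    walkers: int = Field(default=32, ge=8)
    warmup: int = Field(default=1000, ge=10)
    draws: int = Field(default=1000, ge=10)
    thin: int = Field(default=1, ge=1)
    rhat_limit: float = Field(default=1.1, gt=1.0)


class RofConfig(BaseModel):
    """Settings for the regularized optimal fingerprinting stage."""

    model_config = ConfigDict(extra="forbid")

    window_years: int = Field(default=42, ge=4)
    mc_draws: int = Field(default=1000, ge=100)
    pooling: Literal["multimodel"] = "multimodel"


class RunConfig(BaseModel):
    """Configuration of one end-to-end pipeline run."""

    model_config = ConfigDict(extra="forbid")

    synthetic: SyntheticConfig
    percentile: float = Field(default=0.10, gt=0.0, le=0.5)
    p_level: float = Field(default=0.9, gt=0.0, lt=1.0)
    vpd_convention: Literal["start_date", "duration_mean"] = "start_date"
    label_source: Literal["size_percentile", "truth"] = "size_percentile"
    anomaly_baseline: Optional[tuple[int, int]] = None
    designs: list[Literal["one_signal", "three_signal"]] = ["one_signal", "three_signal"]
    fit_factors: tuple[str, ...] = ("vpd", "npp", "pd")
    mcmc: McmcConfig = McmcConfig(warmup=1500, draws=1000, thin=5)
    rof: RofConfig = RofConfig()
    seed: int = 0
    outdir: str = "vpdfire_run"


def default_synthetic_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A realistic western-US-analogue default: 3 ecoregions on a 6x8 grid,
    42 years, human thresholds lower than lightning in every ecoregion.
    """
    climate = [
        ClimateTruth(t_mean_c=22.0, rh_mean_pct=35.0, t_seasonal_amp_c=8.0,
                     rh_seasonal_amp_pct=12.0, t_trend_c_per_decade=0.35,
                     rh_trend_pct_per_decade=-0.5, ar1=0.7,
                     t_noise_sd_c=2.5, rh_noise_sd_pct=8.0),
        ClimateTruth(t_mean_c=16.0, rh_mean_pct=45.0, t_seasonal_amp_c=9.0,
                     rh_seasonal_amp_pct=14.0, t_trend_c_per_decade=0.35,
                     rh_trend_pct_per_decade=-0.5, ar1=0.7,
                     t_noise_sd_c=2.5, rh_noise_sd_pct=8.0),
        ClimateTruth(t_mean_c=10.0, rh_mean_pct=55.0, t_seasonal_amp_c=10.0,
                     rh_seasonal_amp_pct=16.0, t_trend_c_per_decade=0.35,
                     rh_trend_pct_per_decade=-0.5, ar1=0.7,
                     t_noise_sd_c=2.5, rh_noise_sd_pct=8.0),
    ]
    # Truth thresholds at p = 0.9 are beta + ln(9)/alpha: human ~ (3.0, 2.5, 2.0)
    # minus ln9/2.5 offsets => VPD_t(hm) ~= 2.1/1.6/1.1, VPD_t(ltn) ~= 2.8/2.3/1.8.
    fire = {
        "human": [
            LogisticTruth(alpha_vpd=2.5, beta_vpd=2.1 - 0.8789, alpha_npp=1.5,
                          beta_npp=-1.5, alpha_pd=-1.5, beta_pd=2.0),
            LogisticTruth(alpha_vpd=2.5, beta_vpd=1.6 - 0.8789, alpha_npp=1.5,
                          beta_npp=-1.5, alpha_pd=-1.5, beta_pd=2.0),
            LogisticTruth(alpha_vpd=2.5, beta_vpd=1.1 - 0.8789, alpha_npp=1.5,
                          beta_npp=-1.5, alpha_pd=-1.5, beta_pd=2.0),
        ],
        "lightning": [
            LogisticTruth(alpha_vpd=3.0, beta_vpd=2.8 - 0.7324, alpha_npp=1.5,
                          beta_npp=-1.5, alpha_pd=-1.5, beta_pd=2.0),
            LogisticTruth(alpha_vpd=3.0, beta_vpd=2.3 - 0.7324, alpha_npp=1.5,
                          beta_npp=-1.5, alpha_pd=-1.5, beta_pd=2.0),
            LogisticTruth(alpha_vpd=3.0, beta_vpd=1.8 - 0.7324, alpha_npp=1.5,
                          beta_npp=-1.5, alpha_pd=-1.5, beta_pd=2.0),
        ],
    }
    rates = {"human": [120.0, 120.0, 120.0], "lightning": [60.0, 60.0, 60.0]}
    base = dict(climate=climate, fire=fire, ignition_rates=rates, seed=seed)
    base.update(overrides)
    return SyntheticConfig(**base)


def demo_run_config(seed: int = 0, outdir: str = "vpdfire_demo") -> RunConfig:
    """A small end-to-end configuration that runs in a few minutes:
    4x4 grid, 2 ecoregions, reduced ignition rates and sampler length."""
    full = default_synthetic_config(seed=seed)
    syn = SyntheticConfig(
        grid_shape=(4, 4), n_ecoregions=2, years=full.years,
        climate=full.climate[:2],
        fire={k: v[:2] for k, v in full.fire.items()},
        ignition_rates={"human": [60.0, 60.0], "lightning": [30.0, 30.0]},
        seed=seed,
    )
    # the three-factor joint posterior mixes slowly under the ensemble
    # sampler, so the demo thins a longer chain instead of shortening it
    return RunConfig(synthetic=syn, seed=seed, outdir=outdir,
                     mcmc=McmcConfig(walkers=32, warmup=2000, draws=800, thin=9),
                     rof=RofConfig(mc_draws=300))
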