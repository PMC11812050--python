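"""Synthetic inputs with known ground truth.

Everything the pipeline consumes is generated here: daily climate grids
(gridded-meteorology analogue), annual fuel/suppression covariates, fire
catalogs whose large/small labels are drawn from a known logistic truth,
and pseudo-ESM forcing ensembles with preindustrial-style control runs.
The exact parameters used — including the analytically derived true VPD
thresholds — are recorded in a serializable truth manifest so that every
downstream stage can be tested as a recovery problem.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter

from .climate import vpd_from_t_rh
from .config import IGNITION_TYPES, SyntheticConfig
from .random import substream

_SEASON_PEAK_DOY = 196  # mid-July temperature (and VPD) maximum
_LIGHTNING_KAPPA = 2.0  # concentration of the summer ignition season


def ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], phi: float,
              sd: float, axis: int = -1) -> np.ndarray:
    """AR(1) noise with marginal standard deviation ``sd`` along ``axis``."""
    if sd == 0.0:
        return np.zeros(shape)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=shape)
    out = lfilter([1.0], [1.0, -phi], eps, axis=axis)
    return out


def _seasonal(doy: np.ndarray) -> np.ndarray:
    return np.cos(2.0 * np.pi * (doy - _SEASON_PEAK_DOY) / 365.25)


def ecoregion_map(config: SyntheticConfig) -> xr.DataArray:
    """Integer ecoregion raster: contiguous latitude bands, one id per band."""
    n_lat, n_lon = config.grid_shape
    rows = (np.arange(n_lat) * config.n_ecoregions) // n_lat
    grid = np.repeat(rows[:, None], n_lon, axis=1).astype(np.int32)
    lat = np.linspace(31.0, 49.0, n_lat)
    lon = np.linspace(-125.0, -102.0, n_lon)
    return xr.DataArray(grid, dims=("lat", "lon"), coords={"lat": lat, "lon": lon},
                        name="ecoregion")


def generate_climate_grid(config: SyntheticConfig) -> xr.Dataset:
    """Daily temperature (degC) and relative humidity (%) for every cell.

    Each cell follows its ecoregion's mean + seasonal cycle + linear trend +
    AR(1) noise, plus a small fixed cell offset (scaled by the noise sd so a
    zero-noise configuration is exactly the ecoregion mean).  RH is clipped
    to [1, 100] so VPD stays defined and non-negative.
    """
    rng = substream(config.seed, "climate")
    eco = ecoregion_map(config)
    n_lat, n_lon = config.grid_shape
    y0, y1 = config.years
    times = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    n_t = len(times)
    doy = times.dayofyear.to_numpy(dtype=float)
    # trend advances in annual steps so calendar-year means are exactly
    # linear in year regardless of leap days
    t_years = (times.year.to_numpy() - y0).astype(float)
    season = _seasonal(doy)

    tas = np.empty((n_t, n_lat, n_lon))
    hurs = np.empty((n_t, n_lat, n_lon))
    eco_ids = eco.values
    for e, truth in enumerate(config.climate):
        mask = eco_ids == e
        n_cells = int(mask.sum())
        if n_cells == 0:
            continue
        base_t = (truth.t_mean_c + truth.t_seasonal_amp_c * season
                  + truth.t_trend_c_per_decade / 10.0 * t_years)
        base_rh = (truth.rh_mean_pct - truth.rh_seasonal_amp_pct * season
                   + truth.rh_trend_pct_per_decade / 10.0 * t_years)
        off_t = rng.normal(0.0, 0.2 * truth.t_noise_sd_c, size=n_cells) if truth.t_noise_sd_c else np.zeros(n_cells)
        off_rh = rng.normal(0.0, 0.2 * truth.rh_noise_sd_pct, size=n_cells) if truth.rh_noise_sd_pct else np.zeros(n_cells)
        noise_t = ar1_noise(rng, (n_t, n_cells), truth.ar1, truth.t_noise_sd_c, axis=0)
        noise_rh = ar1_noise(rng, (n_t, n_cells), truth.ar1, truth.rh_noise_sd_pct, axis=0)
        tas[:, mask] = base_t[:, None] + off_t[None, :] + noise_t
        hurs[:, mask] = base_rh[:, None] + off_rh[None, :] + noise_rh
    hurs = np.clip(hurs, 1.0, 100.0)

    ds = xr.Dataset(
        {
            "tas": (("time", "lat", "lon"), tas, {"units": "degC", "long_name": "surface air temperature"}),
            "hurs": (("time", "lat", "lon"), hurs, {"units": "%", "long_name": "relative humidity"}),
            "ecoregion": eco,
        },
        coords={"time": times, "lat": eco["lat"], "lon": eco["lon"]},
    )
    return ds


def generate_covariates(config: SyntheticConfig) -> xr.Dataset:
    """Annual fuel-availability (NPP proxy) and suppression (population
    density proxy) fields: a static per-cell base plus small interannual
    noise, on an approximately standardized scale."""
    rng = substream(config.seed, "covariates")
    eco = ecoregion_map(config)
    n_lat, n_lon = config.grid_shape
    years = np.arange(config.years[0], config.years[1] + 1)
    base_npp = rng.normal(0.0, 1.0, size=(n_lat, n_lon))
    base_pd = rng.normal(0.0, 1.0, size=(n_lat, n_lon))
    npp = base_npp[None, :, :] + rng.normal(0.0, 0.2, size=(len(years), n_lat, n_lon))
    popdens = base_pd[None, :, :] + rng.normal(0.0, 0.2, size=(len(years), n_lat, n_lon))
    return xr.Dataset(
        {
            "npp": (("year", "lat", "lon"), npp, {"long_name": "fuel availability proxy (standardized)"}),
            "popdens": (("year", "lat", "lon"), popdens, {"long_name": "suppression proxy (standardized)"}),
            "ecoregion": eco,
        },
        coords={"year": years, "lat": eco["lat"], "lon": eco["lon"]},
    )


def _logistic(x, alpha, beta):
    return 1.0 / (1.0 + np.exp(-alpha * (x - beta)))


def generate_fire_catalog(climate: xr.Dataset, covariates: xr.Dataset,
                          config: SyntheticConfig) -> pd.DataFrame:
    """Fire event records drawn from the logistic truth.

    Ignition counts are Poisson per ecoregion-year-type; lightning ignition
    dates are concentrated in summer (von-Mises-like day-of-year weights),
    human ignitions spread uniformly over the year.  Each ignition is
    labelled large with probability F = f(VPD) * f(NPP) * f(PD) evaluated at
    the truth parameters for that cell and date.  A configurable fraction of
    records has the ignition cause withheld; sizes are decorative lognormals
    (the downstream model consumes only the label).
    """
    rng = substream(config.seed, "catalog")
    eco_ids = climate["ecoregion"].values
    times = pd.DatetimeIndex(climate["time"].values)
    years = times.year.to_numpy()
    year_list = np.arange(config.years[0], config.years[1] + 1)
    year_start_idx = {int(y): int(np.searchsorted(years, y)) for y in year_list}
    year_len = {int(y): int((years == y).sum()) for y in year_list}

    tas = climate["tas"].values
    hurs = climate["hurs"].values
    npp = covariates["npp"].values
    popdens = covariates["popdens"].values

    records = []
    for e in range(config.n_ecoregions):
        cells = np.argwhere(eco_ids == e)
        if len(cells) == 0:
            raise ValueError(f"ecoregion {e} has no grid cells")
        for kind in IGNITION_TYPES:
            truth = config.fire[kind][e]
            rate = config.ignition_rates[kind][e]
            n = rng.poisson(rate * config.n_years)
            if n == 0:
                continue
            yr = rng.choice(year_list, size=n)
            # day-of-year: summer-peaked for lightning, uniform for human
            doy_grid = np.arange(1, 367, dtype=float)
            if kind == "lightning":
                w = np.exp(_LIGHTNING_KAPPA * np.cos(2 * np.pi * (doy_grid - _SEASON_PEAK_DOY) / 365.25))
            else:
                w = np.ones_like(doy_grid)
            w /= w.sum()
            doy = rng.choice(doy_grid, size=n, p=w).astype(int)
            lens = np.array([year_len[int(y)] for y in yr])
            doy = np.minimum(doy, lens)  # clamp Dec 32 analogues in non-leap years
            t_idx = np.array([year_start_idx[int(y)] for y in yr]) + doy - 1
            cell_idx = cells[rng.integers(0, len(cells), size=n)]
            li, lo = cell_idx[:, 0], cell_idx[:, 1]
            y_idx = np.searchsorted(year_list, yr)

            vpd = vpd_from_t_rh(tas[t_idx, li, lo], hurs[t_idx, li, lo])
            x_npp = npp[y_idx, li, lo]
            x_pd = popdens[y_idx, li, lo]
            prob = (_logistic(vpd, truth.alpha_vpd, truth.beta_vpd)
                    * _logistic(x_npp, truth.alpha_npp, truth.beta_npp)
                    * _logistic(x_pd, truth.alpha_pd, truth.beta_pd))
            large = rng.random(n) < prob
            size = np.exp(rng.normal(np.where(large, 2.5, 0.0), 0.8))
            duration = np.where(rng.random(n) < config.one_day_duration_fraction,
                                1, 1 + rng.geometric(0.5, size=n))
            dates = times[t_idx]
            rec = pd.DataFrame({
                "cause": kind,
                "discovery_date": dates,
                "lat_idx": li.astype(np.int32),
                "lon_idx": lo.astype(np.int32),
                "ecoregion_id": np.int32(e),
                "large_label": large.astype(np.int8),
                "size": size,
                "duration_days": duration.astype(np.int16),
            })
            records.append(rec)

    catalog = pd.concat(records, ignore_index=True)
    if config.unknown_cause_fraction > 0:
        mask = rng.random(len(catalog)) < config.unknown_cause_fraction
        catalog.loc[mask, "cause"] = "unknown"
    catalog = catalog.sort_values(
        ["discovery_date", "ecoregion_id", "lat_idx", "lon_idx", "size"]
    ).reset_index(drop=True)
    catalog.insert(0, "event_id", np.arange(len(catalog), dtype=np.int64))
    return catalog


@dataclass
class ForcingEnsemble:
    """Pseudo-ESM regional-mean flammable-day series per forcing.

    ``members`` maps forcing name (ALL/GHG/NAT) to an array of shape
    (n_models, n_members, n_years); ``trajectories`` holds the noise-free
    forced responses including the derived OANT; ``controls`` are unforced
    internal-variability runs.
    """

    years: np.ndarray
    members: dict[str, np.ndarray]
    trajectories: dict[str, np.ndarray]
    controls: list[np.ndarray] = field(default_factory=list)

    def member_count(self, forcing: str) -> float:
        """Total members behind the multimodel-mean response of a forcing.

        OANT is derived as ALL - NAT - GHG, so its sampling noise combines
        the three ensembles: 1/n_eff = 1/n_ALL + 1/n_GHG + 1/n_NAT.
        """
        if forcing == "OANT":
            inv = sum(1.0 / self.member_count(f) for f in ("ALL", "GHG", "NAT"))
            return 1.0 / inv
        arr = self.members[forcing]
        return float(arr.shape[0] * arr.shape[1])

    def ensemble_mean(self, forcing: str) -> pd.Series:
        """Multimodel ensemble-mean series; OANT from the ALL/GHG/NAT means."""
        if forcing == "OANT":
            vals = (self.ensemble_mean("ALL").values
                    - self.ensemble_mean("GHG").values
                    - self.ensemble_mean("NAT").values)
        else:
            vals = self.members[forcing].mean(axis=(0, 1))
        return pd.Series(vals, index=pd.Index(self.years, name="year"))


def forced_trajectories(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Noise-free forced responses (days/yr) on the analysis years."""
    esm = config.esm
    t = np.arange(config.n_years, dtype=float)
    ghg = esm.ghg_trend_days_per_year * t
    # other-anthropogenic response flattens late in the record
    # (aerosol-like), which also keeps it distinguishable from GHG
    oant = esm.oant_trend_days_per_year * t + esm.oant_curvature_days_per_year2 * t * t
    nat = (esm.nat_sin_amp_days * np.sin(2 * np.pi * t / esm.nat_sin_period_years)
           + esm.nat_trend_days_per_year * t)
    return {"GHG": ghg, "OANT": oant, "NAT": nat, "ALL": ghg + oant + nat}


def generate_esm_ensemble(config: SyntheticConfig,
                          rng: Optional[np.random.Generator] = None) -> ForcingEnsemble:
    """Forcing ensembles plus control runs with AR(1) internal variability."""
    if rng is None:
        rng = substream(config.seed, "esm")
    esm = config.esm
    traj = forced_trajectories(config)
    years = np.arange(config.years[0], config.years[1] + 1)
    members = {}
    for forcing in ("ALL", "GHG", "NAT"):
        noise = ar1_noise(rng, (esm.n_models, esm.n_members, config.n_years),
                          esm.internal_ar1, esm.internal_sd_days, axis=-1)
        members[forcing] = traj[forcing][None, None, :] + noise
    controls = [ar1_noise(rng, (esm.control_length_years,), esm.internal_ar1,
                          esm.internal_sd_days)
                for _ in range(esm.n_controls)]
    return ForcingEnsemble(years=years, members=members, trajectories=traj,
                           controls=controls)


def make_pseudo_observations(config: SyntheticConfig,
                             scaling: Optional[dict[str, float]] = None,
                             rng: Optional[np.random.Generator] = None) -> pd.Series:
    """Observed-series analogue: scaled forced responses + internal noise."""
    if rng is None:
        rng = substream(config.seed, "observations")
    if scaling is None:
        scaling = {"GHG": 1.0, "OANT": 1.0, "NAT": 1.0}
    traj = forced_trajectories(config)
    esm = config.esm
    y = sum(scaling[f] * traj[f] for f in scaling)
    y = y + ar1_noise(rng, (config.n_years,), esm.internal_ar1, esm.internal_sd_days)
    years = np.arange(config.years[0], config.years[1] + 1)
    return pd.Series(y, index=pd.Index(years, name="year"))


def true_vpd_threshold(alpha: float, beta: float, p: float = 0.9) -> float:
    """Closed-form threshold: x with f(x) = p, i.e. beta + ln(p/(1-p))/alpha."""
    if not 0.0 < p < 1.0:
        raise ValueError("probability level must lie in (0, 1)")
    return beta + math.log(p / (1.0 - p)) / alpha


@dataclass
class TruthRecord:
    """Exact parameters behind a generated dataset, for recovery tests."""

    config: dict
    vpd_thresholds: dict[str, list[float]]
    p_level: float
    true_scaling: dict[str, float]
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


def truth_manifest(config: SyntheticConfig, p_level: float = 0.9,
                   true_scaling: Optional[dict[str, float]] = None) -> TruthRecord:
    """All truth parameters, including the derived true VPD_t per stratum."""
    thresholds = {
        kind: [true_vpd_threshold(t.alpha_vpd, t.beta_vpd, p_level)
               for t in config.fire[kind]]
        for kind in IGNITION_TYPES
    }
    if true_scaling is None:
        true_scaling = {"GHG": 1.0, "OANT": 1.0, "NAT": 1.0}
    return TruthRecord(config=json.loads(config.model_dump_json()),
                       vpd_thresholds=thresholds, p_level=p_level,
                       true_scaling=dict(true_scaling), seed=config.seed)
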