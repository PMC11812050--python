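"""Deterministic climate transforms.

Vapor pressure deficit from temperature and humidity, annual anomalies,
cosine-latitude regional means, and the non-overlapping 2-year reduction
used to shrink covariance dimensions before attribution.
"""
from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
import xarray as xr


def vpd_from_t_rh(t_c, rh_pct):
    """Vapor pressure deficit (kPa) from air temperature (degC) and RH (%).

    Uses the Tetens saturation-vapor-pressure form::

        VPD = 0.611 * exp(17.27 T / (T + 237.3)) * (1 - RH/100)

    Elementwise over numpy arrays or xarray objects; RH must lie in [0, 100],
    so the result is non-negative, zero exactly at saturation.
    """
    rh_vals = rh_pct.values if isinstance(rh_pct, xr.DataArray) else np.asarray(rh_pct)
    if np.any(rh_vals < 0.0) or np.any(rh_vals > 100.0):
        raise ValueError("relative humidity must lie in [0, 100] percent")
    es = 0.611 * np.exp(17.27 * t_c / (t_c + 237.3))
    return es * (1.0 - rh_pct / 100.0)


def add_vpd(ds: xr.Dataset) -> xr.Dataset:
    """Attach a ``vpd`` variable (kPa) computed from ``tas`` and ``hurs``."""
    out = ds.copy()
    vpd = vpd_from_t_rh(ds["tas"], ds["hurs"])
    vpd.attrs = {"units": "kPa", "long_name": "vapor pressure deficit"}
    out["vpd"] = vpd
    return out


def annual_anomalies(series: pd.Series, baseline_years: Optional[Iterable[int]] = None) -> pd.Series:
    """Subtract the mean over ``baseline_years`` (default: all years)."""
    if baseline_years is None:
        baseline_years = series.index
    baseline_years = list(baseline_years)
    if len(baseline_years) == 0:
        raise ValueError("baseline is empty")
    missing = set(baseline_years) - set(series.index)
    if missing:
        raise ValueError(f"baseline years not in series: {sorted(missing)}")
    return series - series.loc[baseline_years].mean()


def cosine_latitude_weights(lat: xr.DataArray | np.ndarray) -> np.ndarray:
    """Area weights proportional to cos(latitude in degrees)."""
    return np.cos(np.deg2rad(np.asarray(lat, dtype=float)))


def regional_mean(panel: xr.DataArray, weights: Optional[xr.DataArray] = None) -> pd.Series:
    """Weighted spatial mean of an annual (year, lat, lon) panel.

    Default weights are cos(latitude).  Returns a year-indexed Series.
    """
    if weights is None:
        w = xr.DataArray(cosine_latitude_weights(panel["lat"]), dims=("lat",),
                         coords={"lat": panel["lat"]})
    else:
        w = weights
    wv = np.asarray(w)
    if np.any(wv < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(wv > 0):
        raise ValueError("weights must not all be zero")
    mean = panel.weighted(w).mean(dim=[d for d in panel.dims if d != "year"])
    return pd.Series(mean.values, index=pd.Index(panel["year"].values, name="year"))


def two_year_means(series: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Non-overlapping means of consecutive pairs; halves the length.

    Odd-length input is an error: the caller must trim explicitly so the
    dropped year is a visible analysis decision, not a silent default.
    """
    values = np.asarray(series, dtype=float)
    if values.shape[-1] % 2 != 0:
        raise ValueError("two_year_means requires an even-length series; trim first")
    reduced = values.reshape(values.shape[:-1] + (-1, 2)).mean(axis=-1)
    if isinstance(series, pd.Series):
        years = np.asarray(series.index)
        return pd.Series(reduced, index=pd.Index(years[::2], name=series.index.name))
    return reduced
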