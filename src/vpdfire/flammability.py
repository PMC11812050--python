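"""Flammable-day counting and autocorrelation-robust trend statistics.

A day is flammable when its VPD strictly exceeds the ecoregion's threshold
for the given ignition type; annual counts per cell form the F_hm / F_ltn
panels.  Trends use the Theil-Sen slope with a Mann-Kendall test whose
variance is inflated by a rank-based effective-sample-size factor computed
from the lags whose autocorrelation is significant at 5% (the series is
detrended with the Sen slope before the rank autocorrelations are taken).
Group comparisons use the two-sided Wilcoxon rank-sum test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

logger = logging.getLogger(__name__)

MIN_MK_LENGTH = 8  # below this the effective-sample-size correction is meaningless


def count_flammable_days(vpd: xr.DataArray, thresholds: Mapping[int, float],
                         ecoregion: xr.DataArray) -> xr.DataArray:
    """Annual count of days with VPD strictly above the ecoregion threshold.

    ``vpd`` is daily (time, lat, lon); ``thresholds`` maps ecoregion id to a
    VPD_t in kPa.  The time axis must be contiguous daily with no gaps.
    """
    times = pd.DatetimeIndex(vpd["time"].values)
    if len(times) > 1:
        deltas = np.diff(times.values).astype("timedelta64[D]").astype(int)
        if np.any(deltas != 1):
            raise ValueError("daily time axis has gaps; cannot count flammable days")
    eco_ids = ecoregion.values
    max_id = max(int(eco_ids.max()), max(int(k) for k in thresholds))
    lookup = np.full(max_id + 1, np.nan)
    for k, v in thresholds.items():
        lookup[int(k)] = v
    thr_map = lookup[eco_ids]
    if np.any(np.isnan(thr_map)):
        missing = sorted(set(eco_ids.ravel()) - set(int(k) for k in thresholds))
        raise KeyError(f"no threshold for ecoregions {missing}")
    flam = vpd > xr.DataArray(thr_map, dims=("lat", "lon"),
                              coords={"lat": vpd["lat"], "lon": vpd["lon"]})
    counts = flam.groupby("time.year").sum("time")
    counts.name = "flammable_days"
    counts.attrs["units"] = "days/year"
    return counts


def theil_sen_trend(series: pd.Series | np.ndarray,
                    x: Optional[np.ndarray] = None) -> float:
    """Theil-Sen slope: the median of all pairwise slopes."""
    y = np.asarray(series, dtype=float)
    if isinstance(series, pd.Series) and x is None:
        x = np.asarray(series.index, dtype=float)
    elif x is None:
        x = np.arange(len(y), dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("time axis is constant")
    slope, _, _, _ = stats.theilslopes(y, x)
    return float(slope)


def _mk_s_and_var(y: np.ndarray) -> tuple[float, float]:
    """Mann-Kendall S and its tie-corrected variance under independence."""
    n = len(y)
    sgn = np.sign(y[None, :] - y[:, None])
    s = float(np.triu(sgn, k=1).sum())
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    return s, float(var)


def _rank_autocorr(r: np.ndarray, lag: int) -> float:
    n = len(r)
    r0 = r - r.mean()
    denom = float(np.sum(r0 * r0))
    if denom == 0:
        return 0.0
    return float(np.sum(r0[: n - lag] * r0[lag:]) / denom)


def variance_correction_factor(y: np.ndarray, sig_level: float = 0.05) -> float:
    """Effective-sample-size factor n/n* from significant rank autocorrelations.

    Computed on the ranks of the Sen-detrended series; only lags whose
    autocorrelation falls outside the two-sided normal band are included.
    A non-positive factor (pathological strong negative autocorrelation)
    falls back to 1.
    """
    n = len(y)
    x = np.arange(n, dtype=float)
    slope, _, _, _ = stats.theilslopes(y, x)
    detrended = y - slope * x
    r = stats.rankdata(detrended)
    z_crit = stats.norm.ppf(1.0 - sig_level / 2.0)
    total = 0.0
    for lag in range(1, n - 2):
        rho = _rank_autocorr(r, lag)
        if abs(rho) > z_crit / np.sqrt(n):
            total += (n - lag) * (n - lag - 1) * (n - lag - 2) * rho
    factor = 1.0 + 2.0 / (n * (n - 1) * (n - 2)) * total
    if factor <= 0:
        logger.warning("non-positive variance correction factor; falling back to 1")
        return 1.0
    return factor


@dataclass
class TrendResult:
    """Theil-Sen slope with the variance-corrected Mann-Kendall test."""

    slope: float
    s: float
    var_s: float
    correction_factor: float
    z: float
    p: float
    p_uncorrected: float
    significant: bool
    n: int


def mann_kendall_corrected(series: pd.Series | np.ndarray,
                           sig_level: float = 0.05) -> TrendResult:
    """Monotonic-trend test robust to serial autocorrelation.

    Requires at least 8 points.  Returns the S statistic, the tie-corrected
    variance, the effective-sample-size correction factor, the
    continuity-corrected Z, and two-sided p-values with and without the
    correction.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < MIN_MK_LENGTH:
        raise ValueError(f"need at least {MIN_MK_LENGTH} points for the corrected test")
    s, var = _mk_s_and_var(y)
    factor = variance_correction_factor(y, sig_level)
    var_corr = var * factor

    def _p(vv: float) -> tuple[float, float]:
        if vv <= 0:
            return 0.0, 1.0
        if s > 0:
            z = (s - 1.0) / np.sqrt(vv)
        elif s < 0:
            z = (s + 1.0) / np.sqrt(vv)
        else:
            z = 0.0
        return z, float(2.0 * stats.norm.sf(abs(z)))

    z, p = _p(var_corr)
    _, p0 = _p(var)
    slope = theil_sen_trend(y)
    return TrendResult(slope=slope, s=s, var_s=var, correction_factor=factor,
                       z=z, p=p, p_uncorrected=p0,
                       significant=bool(p < sig_level), n=n)


def wilcoxon_compare(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two samples of cells.

    Exact null distribution for small untied samples, tie-corrected normal
    approximation otherwise.  If every value across both groups is tied the
    test is vacuous and p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        logger.warning("all values tied across both groups; p = 1 by convention")
        return float(len(a) * len(b) / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def anomaly_correlation(series_a: pd.Series, series_b: pd.Series) -> tuple[float, float]:
    """Pearson correlation of annual anomalies over the common years."""
    common = series_a.index.intersection(series_b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common years")
    a = series_a.loc[common].to_numpy(dtype=float)
    b = series_b.loc[common].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(a - a.mean(), b - b.mean())
    return float(r), float(p)


def trend_map(panel: xr.DataArray, sig_level: float = 0.05) -> xr.Dataset:
    """Per-cell Theil-Sen slope and corrected Mann-Kendall p over years."""
    years = panel["year"].values
    ny, nlat, nlon = panel.shape
    slope = np.empty((nlat, nlon))
    pval = np.empty((nlat, nlon))
    for i in range(nlat):
        for j in range(nlon):
            res = mann_kendall_corrected(pd.Series(panel.values[:, i, j], index=years))
            slope[i, j] = res.slope
            pval[i, j] = res.p
    return xr.Dataset(
        {
            "slope": (("lat", "lon"), slope, {"units": "days/year per year"}),
            "p": (("lat", "lon"), pval),
            "significant": (("lat", "lon"), pval < sig_level),
        },
        coords={"lat": panel["lat"], "lon": panel["lon"]},
    )
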