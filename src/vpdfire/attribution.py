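"""Regularized optimal fingerprinting (ROF) attribution.

Observed flammable-day anomalies Y are modelled as a linear combination of
forced responses X_i (estimated from finite ensembles, hence noisy) plus
internal climate noise:  Y = sum_i beta_i (X_i - eps_i) + eps.  Internal
variability is estimated from unforced control runs split into two disjoint
pools: C1 (regularized by Ledoit-Wolf linear shrinkage toward a scaled
identity) prewhitens the series, C2 drives the Monte-Carlo confidence
intervals of the scaling factors.  Scaling factors come from total least
squares on the whitened series, with each forced response scaled by the
square root of its member count so its sampling noise is whitened too.

Detection rules: a forcing is detectable when the 5-95% interval of its
scaling factor lies above zero; the forced response is consistent with
observations when the interval contains one.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf

from .climate import annual_anomalies, two_year_means
from .flammability import theil_sen_trend
from .synthetic import ForcingEnsemble

logger = logging.getLogger(__name__)

THREE_SIGNAL_FORCINGS = ("GHG", "OANT", "NAT")


class NonIdentifiableError(RuntimeError):
    """Raised when the TLS smallest singular value is (numerically) tied."""


def build_control_subseries(controls: Sequence[np.ndarray], window_years: int = 42
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Split control runs into two disjoint pools of reduced subseries.

    Each control is cut into consecutive non-overlapping windows of
    ``window_years``; windows alternate between the two pools so each run
    contributes half to each (an odd extra window goes to the first pool,
    favouring the prewhitening estimate).  Each window is reduced to
    non-overlapping 2-year means and centred to zero mean.
    """
    pool1, pool2 = [], []
    for k, run in enumerate(controls):
        run = np.asarray(run, dtype=float)
        n_win = len(run) // window_years
        if n_win < 1:
            logger.warning("control run %d shorter than one window; excluded", k)
            continue
        for w in range(n_win):
            seg = run[w * window_years:(w + 1) * window_years]
            if window_years % 2:
                seg = seg[:-1]
            reduced = two_year_means(seg)
            reduced = reduced - reduced.mean()
            (pool1 if w % 2 == 0 else pool2).append(reduced)
    if not pool1 or not pool2:
        raise ValueError("controls too short to populate both covariance pools")
    return np.asarray(pool1), np.asarray(pool2)


def estimate_regularized_covariance(pool: np.ndarray) -> tuple[np.ndarray, float]:
    """Ledoit-Wolf linear shrinkage toward a scaled identity.

    Returns the regularized covariance (positive definite whenever the pool
    is non-degenerate) and the shrinkage weight actually used.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.ndim != 2 or pool.shape[0] < 2:
        raise ValueError("need at least two subseries to estimate a covariance")
    cov, shrinkage = ledoit_wolf(pool, assume_centered=True)
    mu = float(np.trace(cov)) / cov.shape[0]
    if mu <= 0:
        raise ValueError("degenerate pool: zero total variance")
    # a degenerate pool (e.g. one subseries repeated) yields zero estimated
    # shrinkage; floor it so the result is always positive definite
    if np.linalg.eigvalsh(cov).min() <= 1e-10 * mu:
        sample = pool.T @ pool / pool.shape[0]
        shrinkage = max(shrinkage, 1e-3)
        cov = (1.0 - shrinkage) * sample + shrinkage * (np.trace(sample) / len(sample)) * np.eye(len(sample))
    return cov, float(shrinkage)


def _inverse_sqrt(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if np.any(vals <= 0):
        raise np.linalg.LinAlgError("covariance is not positive definite")
    return (vecs / np.sqrt(vals)) @ vecs.T


def prewhiten(series: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    """Multiply by the inverse symmetric square root of the covariance."""
    series = np.asarray(series, dtype=float)
    if covariance.shape[0] != series.shape[-1]:
        raise ValueError("covariance dimension does not match series length")
    return series @ _inverse_sqrt(covariance).T


def tls_scaling_factors(y: np.ndarray, x_list: Sequence[np.ndarray],
                        member_counts: Sequence[float]) -> np.ndarray:
    """Total-least-squares scaling factors on whitened series.

    Each X_i is scaled by sqrt(n_i) so that its ensemble-mean sampling noise
    has unit variance like the observation noise; the solution is the right
    singular vector of the smallest singular value of the augmented matrix,
    renormalized back to the original X scale.
    """
    y = np.asarray(y, dtype=float)
    xs = [np.asarray(x, dtype=float) for x in x_list]
    ns = np.asarray(member_counts, dtype=float)
    if len(xs) != len(ns):
        raise ValueError("one member count per forced response required")
    for x in xs:
        if x.shape != y.shape:
            raise ValueError("all series must share the observation length")
    z = np.column_stack([x * np.sqrt(n) for x, n in zip(xs, ns)] + [y])
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0.0 or (len(s) > 1 and (s[-2] - s[-1]) <= 1e-12 * s[0]):
        raise NonIdentifiableError("tied smallest singular values; scaling factors not identifiable")
    v = vt[-1]
    if v[-1] == 0:
        raise NonIdentifiableError("degenerate TLS solution (zero observation component)")
    beta_scaled = -v[:-1] / v[-1]
    return beta_scaled * np.sqrt(ns)


@dataclass
class AttributionResults:
    """Scaling factors with uncertainties, detection flags and trends."""

    design: str
    forcings: tuple[str, ...]
    beta: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    detected: np.ndarray
    consistent_with_one: np.ndarray
    forced_trends: np.ndarray
    attributable: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "forcing": list(self.forcings),
            "beta": self.beta, "lo": self.ci_lo, "hi": self.ci_hi,
            "detected": self.detected,
            "consistent_with_one": self.consistent_with_one,
            "forced_trend": self.forced_trends,
            "attributable_trend": self.attributable["trend"].to_numpy(),
            "attributable_lo": self.attributable["lo"].to_numpy(),
            "attributable_hi": self.attributable["hi"].to_numpy(),
        })

    def to_json(self) -> str:
        payload = {
            "design": self.design,
            "forcings": list(self.forcings),
            "beta": self.beta.tolist(),
            "ci": {"lo": self.ci_lo.tolist(), "hi": self.ci_hi.tolist()},
            "detected": [bool(d) for d in self.detected],
            "consistent_with_one": [bool(c) for c in self.consistent_with_one],
            "forced_trends": self.forced_trends.tolist(),
            "attributable_trends": {
                "trend": self.attributable["trend"].tolist(),
                "lo": self.attributable["lo"].tolist(),
                "hi": self.attributable["hi"].tolist(),
                "undetectable": [bool(u) for u in self.attributable["undetectable"]],
            },
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str, bool))},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def scaling_factor_ci(y_w: np.ndarray, x_w: list[np.ndarray],
                      member_counts: Sequence[float], noise_cov_w: np.ndarray,
                      mc_draws: int = 1000,
                      rng: Optional[np.random.Generator] = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo 5-95% interval of the scaling factors.

    Perturbs the whitened observation with noise of covariance C2 (expressed
    in whitened coordinates) and each whitened forced response with the same
    noise scaled by 1/sqrt(n_i), re-solving the TLS problem per draw.
    """
    if mc_draws < 100:
        raise ValueError("fewer than 100 Monte-Carlo draws gives unstable percentiles")
    rng = rng or np.random.default_rng()
    chol = np.linalg.cholesky(noise_cov_w + 1e-12 * np.eye(len(noise_cov_w)))
    ns = np.asarray(member_counts, dtype=float)
    betas = np.empty((mc_draws, len(x_w)))
    for d in range(mc_draws):
        yp = y_w + chol @ rng.standard_normal(len(y_w))
        xp = [x + (chol @ rng.standard_normal(len(y_w))) / np.sqrt(n)
              for x, n in zip(x_w, ns)]
        try:
            betas[d] = tls_scaling_factors(yp, xp, ns)
        except NonIdentifiableError:
            betas[d] = np.nan
    betas = betas[~np.isnan(betas).any(axis=1)]
    lo, hi = np.percentile(betas, [5, 95], axis=0)
    return lo, hi


def attributable_trends(beta: np.ndarray, ci_lo: np.ndarray, ci_hi: np.ndarray,
                        forced_series: list[pd.Series],
                        detected: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-forcing observed-trend contribution: beta x forced-response trend.

    Interval endpoints are the monotone image of the scaling-factor interval
    (swapped when the forced trend is negative).  A forcing whose scaling
    interval covers zero is flagged undetectable.
    """
    trends = np.array([theil_sen_trend(s) for s in forced_series])
    point = beta * trends
    lo = np.where(trends >= 0, ci_lo * trends, ci_hi * trends)
    hi = np.where(trends >= 0, ci_hi * trends, ci_lo * trends)
    table = pd.DataFrame({"trend": point, "lo": lo, "hi": hi,
                          "undetectable": ~np.asarray(detected, dtype=bool)})
    return trends, table


class AttributionModel:
    """ROF regression of observed anomalies on forced responses.

    Parameters
    ----------
    y_obs : year-indexed annual series of regional-mean flammable days.
    ensemble : pseudo-ESM forcing ensembles and control runs.
    design : ``"one_signal"`` (regress on ALL) or ``"three_signal"``
        (GHG, OANT, NAT).
    window_years : control subseries window; must equal the observation span.
    baseline : years for the anomaly baseline (default: all years).
    """

    def __init__(self, y_obs: pd.Series, ensemble: ForcingEnsemble,
                 design: str = "three_signal", window_years: int = 42,
                 baseline: Optional[Sequence[int]] = None, mc_draws: int = 1000):
        if design not in ("one_signal", "three_signal"):
            raise ValueError(f"unknown design {design!r}")
        self.design = design
        self.forcings = ("ALL",) if design == "one_signal" else THREE_SIGNAL_FORCINGS
        for f in self.forcings:
            if f != "OANT" and f not in ensemble.members:
                raise ValueError(f"ensemble is missing forcing {f!r}")
        self.y_obs = y_obs
        self.ensemble = ensemble
        self.window_years = window_years
        self.baseline = baseline
        self.mc_draws = mc_draws

    def _reduce(self, series: pd.Series) -> np.ndarray:
        anom = annual_anomalies(series, self.baseline)
        vals = anom.to_numpy(dtype=float)
        if len(vals) % 2:
            vals = vals[:-1]
        return two_year_means(vals)

    def fit(self, rng: Optional[np.random.Generator] = None) -> AttributionResults:
        rng = rng or np.random.default_rng()
        ens = self.ensemble
        n_years = len(self.y_obs)
        min_control = 2 * self.window_years
        if all(len(c) < min_control for c in ens.controls):
            raise ValueError("every control run is shorter than two windows")

        pool1, pool2 = build_control_subseries(ens.controls, self.window_years)
        c1, s1 = estimate_regularized_covariance(pool1)
        c2, s2 = estimate_regularized_covariance(pool2)
        whitener = _inverse_sqrt(c1)

        y_red = self._reduce(self.y_obs)
        if len(y_red) != c1.shape[0]:
            raise ValueError("observation length does not match the control window reduction")
        y_w = whitener @ y_red

        forced_series = [ens.ensemble_mean(f) for f in self.forcings]
        x_red = [self._reduce(s) for s in forced_series]
        x_w = [whitener @ x for x in x_red]
        ns = [ens.member_count(f) for f in self.forcings]

        beta = tls_scaling_factors(y_w, x_w, ns)
        noise_cov_w = whitener @ c2 @ whitener.T
        lo, hi = scaling_factor_ci(y_w, x_w, ns, noise_cov_w,
                                   mc_draws=self.mc_draws, rng=rng)
        detected = lo > 0
        consistent = (lo <= 1.0) & (1.0 <= hi)
        forced_trends, attr = attributable_trends(beta, lo, hi, forced_series, detected)
        diagnostics = {
            "shrinkage_c1": s1, "shrinkage_c2": s2,
            "n_pool1": int(pool1.shape[0]), "n_pool2": int(pool2.shape[0]),
            "reduced_dim": int(c1.shape[0]), "n_years": int(n_years),
            "mc_draws": int(self.mc_draws),
        }
        return AttributionResults(design=self.design, forcings=tuple(self.forcings),
                                  beta=beta, ci_lo=lo, ci_hi=hi, detected=detected,
                                  consistent_with_one=consistent,
                                  forced_trends=forced_trends, attributable=attr,
                                  diagnostics=diagnostics)


def run_attribution(y_obs: pd.Series, ensemble: ForcingEnsemble, design: str,
                    window_years: int = 42, baseline=None, mc_draws: int = 1000,
                    rng: Optional[np.random.Generator] = None) -> AttributionResults:
    """Functional wrapper over :class:`AttributionModel`."""
    return AttributionModel(y_obs, ensemble, design=design, window_years=window_years,
                            baseline=baseline, mc_draws=mc_draws).fit(rng=rng)
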