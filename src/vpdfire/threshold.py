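"""Ignition-type-specific VPD flammability thresholds.

The model: within ecoregion ``i``, each control factor ``x_ij`` (VPD, fuel
proxy, suppression proxy) limits large-fire probability through a logistic
``f(x) = 1 / (1 + exp(-alpha_ij (x - beta_ij)))``; the event-level large-fire
probability is the product over factors, and the observed large/small label
is Bernoulli in that probability.  Steepness signs are constrained by
mechanism (positive for VPD and fuel, negative for suppression), and the
per-ecoregion (alpha, beta) pairs are partially pooled through shared
hyper-distributions per factor.  Human- and lightning-ignited fires are fit
as separate models.

The flammability threshold VPD_t is the VPD at which the fitted VPD-only
logistic reaches a probability level p (default 0.9):
``VPD_t = beta_VPD + ln(p/(1-p)) / alpha_VPD`` per posterior draw.

Posterior inference uses an affine-invariant ensemble sampler with the
likelihood vectorized across walkers; convergence is checked with split-R
statistics treating walkers as chains, plus acceptance-fraction sanity
bounds.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import emcee
import numpy as np
import pandas as pd
import xarray as xr

from .climate import vpd_from_t_rh
from .config import McmcConfig

logger = logging.getLogger(__name__)

FACTOR_SIGNS = {"vpd": 1.0, "npp": 1.0, "pd": -1.0}
_FACTOR_COLS = {"vpd": "x_vpd", "npp": "x_npp", "pd": "x_pd"}


def logistic_response(x, alpha, beta):
    """Single-factor logistic limitation, overflow-safe, in (0, 1)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(~np.isfinite(alpha)) or np.any(alpha == 0.0):
        raise ValueError("alpha must be finite and nonzero")
    from scipy.special import expit

    return expit(alpha * (np.asarray(x, dtype=float) - beta))


def combined_probability(factor_probs: Sequence) -> np.ndarray | float:
    """Product of per-factor limitation probabilities."""
    probs = list(factor_probs)
    if len(probs) == 0:
        raise ValueError("need at least one factor probability")
    out = probs[0]
    for p in probs[1:]:
        out = out * p
    return out


def label_large_small(catalog: pd.DataFrame, percentile: float = 0.10) -> pd.DataFrame:
    """Balanced large/small labelling by size percentile within strata.

    Per ecoregion and known ignition cause: the largest ``percentile``
    fraction of events get label 1, an equal count of the smallest events of
    the same cause get label 0, and everything else is dropped.  Ties break
    by (size, event_id) so the labelling is deterministic.  Strata with
    fewer than 2 events are excluded with a warning.
    """
    if not 0.0 < percentile <= 0.5:
        raise ValueError("percentile must lie in (0, 0.5]")
    known = catalog[catalog["cause"].isin(("human", "lightning"))]
    pieces = []
    for (eco, cause), grp in known.groupby(["ecoregion_id", "cause"], sort=True):
        if len(grp) < 2:
            logger.warning("stratum (ecoregion %s, %s) has %d events; excluded",
                           eco, cause, len(grp))
            continue
        n_large = max(1, int(round(percentile * len(grp))))
        n_large = min(n_large, len(grp) // 2)
        ranked = grp.sort_values(["size", "event_id"], kind="mergesort")
        small = ranked.head(n_large).assign(large_label=np.int8(0))
        large = ranked.tail(n_large).assign(large_label=np.int8(1))
        pieces.append(pd.concat([small, large]))
    if not pieces:
        raise ValueError("no stratum had enough events to label")
    out = pd.concat(pieces).sort_values("event_id").reset_index(drop=True)
    return out


def attach_covariates(catalog: pd.DataFrame, climate: xr.Dataset,
                      covariates: xr.Dataset,
                      convention: str = "start_date") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the modelling table: per event VPD, fuel and suppression proxies.

    ``convention`` is ``"start_date"`` (VPD on the discovery date at the
    ignition cell — the default, since most fires last a single day) or
    ``"duration_mean"`` (mean VPD over the fire's duration).  Events whose
    dates fall outside the climate record are returned in a rejects frame.
    """
    if convention not in ("start_date", "duration_mean"):
        raise ValueError(f"unknown VPD convention {convention!r}")
    times = pd.DatetimeIndex(climate["time"].values)
    years = np.asarray(covariates["year"].values)
    tas = climate["tas"].values
    hurs = climate["hurs"].values
    npp = covariates["npp"].values
    popdens = covariates["popdens"].values

    dates = pd.DatetimeIndex(catalog["discovery_date"])
    li = catalog["lat_idx"].to_numpy()
    lo = catalog["lon_idx"].to_numpy()
    t_idx = times.searchsorted(dates)
    in_time = (dates >= times[0]) & (dates <= times[-1])
    yr = dates.year.to_numpy()
    y_idx = np.searchsorted(years, yr)
    in_year = (yr >= years[0]) & (yr <= years[-1])
    ok = np.asarray(in_time & in_year)

    rejects = catalog.loc[~ok].copy()
    if len(rejects):
        rejects["reject_reason"] = "date outside climate/covariate range"
    kept = catalog.loc[ok].copy()
    t_idx = t_idx[ok]
    y_idx = y_idx[ok]
    li, lo = li[ok], lo[ok]

    if convention == "start_date":
        x_vpd = vpd_from_t_rh(tas[t_idx, li, lo], hurs[t_idx, li, lo])
    else:
        dur = kept["duration_days"].to_numpy() if "duration_days" in kept else np.ones(len(kept), dtype=int)
        x_vpd = np.empty(len(kept))
        for k in range(len(kept)):
            stop = min(t_idx[k] + int(dur[k]), len(times))
            sl = slice(t_idx[k], stop)
            x_vpd[k] = float(np.mean(vpd_from_t_rh(tas[sl, li[k], lo[k]], hurs[sl, li[k], lo[k]])))
    table = kept.assign(x_vpd=x_vpd, x_npp=npp[y_idx, li, lo], x_pd=popdens[y_idx, li, lo])
    return table.reset_index(drop=True), rejects.reset_index(drop=True)


# ---------------------------------------------------------------------------
# hierarchical posterior


_LSD_MIN = math.log(0.05)  # lower truncation of group-scale hyper-parameters


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -z)


def _log1mexp(logp: np.ndarray) -> np.ndarray:
    # log(1 - exp(logp)) for logp <= 0; -expm1 is exact in both tails
    with np.errstate(divide="ignore"):
        return np.log(-np.expm1(logp))


@dataclass
class _Design:
    """Packed data and parameter layout for one ignition-type model."""

    factors: tuple[str, ...]
    ecoregions: np.ndarray           # sorted unique ecoregion ids
    eco_index: np.ndarray            # per-event index into ecoregions
    x: dict[str, np.ndarray]         # per-factor covariate (possibly standardized)
    y: np.ndarray
    scale: dict[str, tuple[np.ndarray, np.ndarray]]  # per-factor (center, spread) per ecoregion

    @property
    def n_eco(self) -> int:
        return len(self.ecoregions)

    @property
    def ndim(self) -> int:
        return 4 * len(self.factors) + 2 * len(self.factors) * self.n_eco

    def unpack(self, theta: np.ndarray, j: int):
        """Hyper and per-ecoregion blocks for factor ``j``; theta is (W, D).

        The sampled coordinates per factor are the log-steepness ``a`` and
        the linear-predictor intercept ``c`` (so z = sign * e^a * x + c):
        the logistic midpoint is beta = -c / alpha.  Sampling slope and
        intercept avoids the banana-shaped (alpha, beta) trade-off that
        appears whenever a factor's midpoint sits outside the data range.
        The per-ecoregion blocks are stored non-centred (standardized
        offsets from the hyper mean) so the hierarchy has no funnel sink.
        """
        h = theta[:, 4 * j:4 * j + 4]
        base = 4 * len(self.factors)
        e = self.n_eco
        za = theta[:, base + 2 * e * j: base + 2 * e * j + e]
        zc = theta[:, base + 2 * e * j + e: base + 2 * e * (j + 1)]
        return h[:, 0], h[:, 1], h[:, 2], h[:, 3], za, zc


def _log_posterior(theta: np.ndarray, design: _Design) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _log_posterior_impl(theta, design)


def _log_posterior_impl(theta: np.ndarray, design: _Design) -> np.ndarray:
    theta = np.atleast_2d(theta)
    W = theta.shape[0]
    logp = np.zeros(W)
    log_f_total = np.zeros((W, len(design.y)))
    for j, fac in enumerate(design.factors):
        mu_a, lsd_a, mu_c, lsd_c, za, zc = design.unpack(theta, j)
        sd_a = np.exp(lsd_a)
        sd_c = np.exp(lsd_c)
        x = design.x[fac]
        sx = float(np.std(x)) or 1.0
        mx = float(np.median(x))
        a0 = math.log(2.0 / sx)
        c0 = -FACTOR_SIGNS[fac] * math.exp(a0) * mx
        cs = math.exp(a0) * 2.0 * sx                      # intercept scale ~ alpha * covariate spread
        # hyper-priors: weakly-informative, scaled to the covariate
        logp += -0.5 * ((mu_a - a0) / 1.5) ** 2
        logp += -0.5 * (sd_a / 1.0) ** 2 + lsd_a          # HalfNormal(1) + Jacobian
        logp += -0.5 * ((mu_c - c0) / cs) ** 2
        logp += -0.5 * (sd_c / cs) ** 2 + lsd_c           # HalfNormal(cs) + Jacobian
        # centred partial pooling of per-ecoregion parameters; the group
        # scales are truncated below (sigma >= 0.05, i.e. effectively full
        # pooling) so the hierarchy has no funnel sink for the sampler
        a, c = za, zc
        logp = np.where((lsd_a < _LSD_MIN) | (lsd_c < _LSD_MIN + math.log(cs)), -np.inf, logp)
        logp += np.sum(-0.5 * ((a - mu_a[:, None]) / sd_a[:, None]) ** 2
                       - lsd_a[:, None], axis=1)
        logp += np.sum(-0.5 * ((c - mu_c[:, None]) / sd_c[:, None]) ** 2
                       - lsd_c[:, None], axis=1)
        alpha = FACTOR_SIGNS[fac] * np.exp(a)             # sign constraint by construction
        z = alpha[:, design.eco_index] * x[None, :] + c[:, design.eco_index]
        log_f_total += _log_sigmoid(np.minimum(z, 30.0))
    idx1 = design.y == 1
    loglik = log_f_total[:, idx1].sum(axis=1)
    loglik += _log1mexp(log_f_total[:, ~idx1]).sum(axis=1)
    out = logp + loglik
    out[~np.isfinite(out)] = -np.inf
    return out


@dataclass
class FireThresholdResults:
    """Posterior draws, diagnostics and threshold summaries for one model."""

    posterior: xr.Dataset
    diagnostics: dict
    factors: tuple[str, ...]
    ecoregions: np.ndarray
    ignition_type: Optional[str] = None
    failed: bool = False

    def _draws(self, var: str, factor: str) -> np.ndarray:
        """Flattened (draws, ecoregion) array for alpha or beta of a factor."""
        da = self.posterior[var].sel(factor=factor)
        return da.stack(sample=("chain", "draw")).transpose("sample", "ecoregion").values

    def threshold_draws(self, p_level: float = 0.9) -> np.ndarray:
        """Per-draw VPD_t = beta + ln(p/(1-p))/alpha, shape (draws, ecoregion)."""
        if not 0.0 < p_level < 1.0:
            raise ValueError("p_level must lie in (0, 1)")
        alpha = self._draws("alpha", "vpd")
        beta = self._draws("beta", "vpd")
        return beta + math.log(p_level / (1.0 - p_level)) / alpha

    def vpd_threshold(self, p_level: float = 0.9) -> pd.DataFrame:
        """Posterior median and 5-95% interval of VPD_t per ecoregion (kPa)."""
        thr = self.threshold_draws(p_level)
        lo, med, hi = np.percentile(thr, [5, 50, 95], axis=0)
        return pd.DataFrame({
            "ecoregion_id": self.ecoregions,
            "ignition_type": self.ignition_type,
            "vpd_t": med, "lo": lo, "hi": hi,
            "p_level": p_level,
        })

    def summary(self) -> pd.DataFrame:
        """Posterior medians and 5-95% intervals for all (factor, ecoregion)."""
        rows = []
        for fac in self.factors:
            for var in ("alpha", "beta"):
                draws = self._draws(var, fac)
                lo, med, hi = np.percentile(draws, [5, 50, 95], axis=0)
                for k, eco in enumerate(self.ecoregions):
                    rows.append({"factor": fac, "parameter": var,
                                 "ecoregion_id": eco, "median": med[k],
                                 "lo": lo[k], "hi": hi[k]})
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        ds = self.posterior.copy()
        ds.attrs["ignition_type"] = self.ignition_type or ""
        ds.attrs["failed"] = int(self.failed)
        for key, val in self.diagnostics.items():
            if np.isscalar(val):
                ds.attrs[f"diag_{key}"] = val
        ds.to_netcdf(path, engine="scipy")


class FireThresholdModel:
    """Hierarchical Bayesian logistic model for one ignition type.

    Parameters
    ----------
    table : DataFrame with columns ``x_vpd`` (kPa), ``x_npp``, ``x_pd``,
        ``ecoregion_id`` and ``large_label`` (0/1), for a single ignition
        type.  Fuel and suppression covariates are standardized per
        ecoregion at construction; VPD stays in kPa so thresholds are
        physical.
    factors : subset of ("vpd", "npp", "pd") to include in the product.
    """

    def __init__(self, table: pd.DataFrame, factors: Sequence[str] = ("vpd", "npp", "pd"),
                 ignition_type: Optional[str] = None):
        factors = tuple(factors)
        for fac in factors:
            if fac not in FACTOR_SIGNS:
                raise ValueError(f"unknown factor {fac!r}")
        if "vpd" not in factors:
            raise ValueError("the VPD factor is required to derive thresholds")
        if len(table) == 0:
            raise ValueError("empty modelling table")
        required = {"ecoregion_id", "large_label"} | {_FACTOR_COLS[f] for f in factors}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"modelling table missing columns: {sorted(missing)}")
        if table[list(required)].isna().any().any():
            raise ValueError("modelling table contains missing values")

        self.table = table.reset_index(drop=True)
        self.factors = factors
        self.ignition_type = ignition_type
        ecoregions = np.sort(table["ecoregion_id"].unique())
        eco_index = np.searchsorted(ecoregions, table["ecoregion_id"].to_numpy())
        x = {}
        scale = {}
        for fac in factors:
            col = table[_FACTOR_COLS[fac]].to_numpy(dtype=float)
            if fac == "vpd":
                center = np.zeros(len(ecoregions))
                spread = np.ones(len(ecoregions))
            else:
                center = np.array([col[eco_index == k].mean() for k in range(len(ecoregions))])
                spread = np.array([col[eco_index == k].std() or 1.0 for k in range(len(ecoregions))])
            x[fac] = (col - center[eco_index]) / spread[eco_index]
            scale[fac] = (center, spread)
        self._design = _Design(factors=factors, ecoregions=ecoregions,
                               eco_index=eco_index, x=x,
                               y=table["large_label"].to_numpy(dtype=np.int8),
                               scale=scale)

    @classmethod
    def from_catalog(cls, catalog: pd.DataFrame, climate: xr.Dataset,
                     covariates: xr.Dataset, ignition_type: str,
                     factors: Sequence[str] = ("vpd", "npp", "pd"),
                     convention: str = "start_date") -> "FireThresholdModel":
        sub = catalog[catalog["cause"] == ignition_type]
        table, rejects = attach_covariates(sub, climate, covariates, convention)
        if len(rejects):
            logger.warning("%d events rejected while attaching covariates", len(rejects))
        return cls(table, factors=factors, ignition_type=ignition_type)

    def _map_laplace(self, theta0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mode and a Laplace covariance factor for initialization.

        Gradients and the Hessian use batched central differences through the
        vectorized log-posterior, so the optimization stays cheap even with
        thousands of events.
        """
        from scipy.optimize import minimize

        d = self._design
        h = 1e-5

        def neg_logp(t):
            return -float(_log_posterior(t[None, :], d)[0])

        def neg_grad(t):
            pts = np.concatenate([t[None, :] + h * np.eye(d.ndim),
                                  t[None, :] - h * np.eye(d.ndim)])
            vals = _log_posterior(pts, d)
            with np.errstate(invalid="ignore"):
                g = -(vals[:d.ndim] - vals[d.ndim:]) / (2 * h)
            return np.nan_to_num(g, nan=0.0, posinf=1e8, neginf=-1e8)

        # The group-scale coordinates are bounded away from zero: the joint
        # mode of a centred hierarchy degenerates at sd -> 0 (the funnel),
        # while the posterior itself is proper.
        lsd_idx = {4 * j + 1 for j in range(len(d.factors))}
        lsd_idx |= {4 * j + 3 for j in range(len(d.factors))}
        bounds = [(math.log(0.1), math.log(10.0)) if k in lsd_idx else (-30.0, 30.0)
                  for k in range(d.ndim)]
        opt = minimize(neg_logp, theta0, jac=neg_grad, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 500})
        mode = opt.x
        # Hessian of -logp by differencing the gradient, batched per column
        eye = np.eye(d.ndim)
        hess = np.empty((d.ndim, d.ndim))
        for k in range(d.ndim):
            hess[:, k] = (neg_grad(mode + h * eye[k]) - neg_grad(mode - h * eye[k])) / (2 * h)
        hess = 0.5 * (hess + hess.T)
        vals, vecs = np.linalg.eigh(hess)
        floor = 1e-3 * float(np.median(np.abs(vals))) or 1.0
        vals = np.maximum(vals, floor)
        cov_factor = vecs / np.sqrt(vals)               # H^{-1/2}
        return mode, cov_factor

    def _initial_state(self, nwalkers: int, rng: np.random.Generator) -> np.ndarray:
        d = self._design
        theta0 = np.empty(d.ndim)
        for j, fac in enumerate(d.factors):
            x = d.x[fac]
            sx = float(np.std(x)) or 1.0
            a0 = math.log(2.0 / sx)
            c0 = -FACTOR_SIGNS[fac] * math.exp(a0) * float(np.median(x))
            cs = math.exp(a0) * sx
            theta0[4 * j:4 * j + 4] = [a0, math.log(0.5), c0, math.log(0.5 * cs)]
            base = 4 * len(d.factors)
            e = d.n_eco
            theta0[base + 2 * e * j: base + 2 * e * j + e] = a0
            for k in range(e):
                xe = x[d.eco_index == k]
                theta0[base + 2 * e * j + e + k] = -FACTOR_SIGNS[fac] * math.exp(a0) * float(np.median(xe))
        try:
            mode, cov_factor = self._map_laplace(theta0)
            p0 = mode[None, :] + rng.standard_normal((nwalkers, d.ndim)) @ cov_factor.T
        except Exception:                                # pragma: no cover - fallback
            logger.warning("Laplace initialization failed; falling back to jittered start")
            p0 = theta0[None, :] + 0.1 * rng.standard_normal((nwalkers, d.ndim))
        # keep group-scale coordinates above their truncation bound
        for j, fac in enumerate(d.factors):
            x = d.x[fac]
            sx = float(np.std(x)) or 1.0
            cs = math.exp(math.log(2.0 / sx)) * 2.0 * sx
            p0[:, 4 * j + 1] = np.maximum(p0[:, 4 * j + 1], _LSD_MIN + 0.1)
            p0[:, 4 * j + 3] = np.maximum(p0[:, 4 * j + 3], _LSD_MIN + math.log(cs) + 0.1)
        return p0

    def fit(self, config: Optional[McmcConfig] = None, seed: int = 0) -> FireThresholdResults:
        """Sample the posterior; returns results with convergence diagnostics.

        A fit whose worst split-R exceeds the configured limit is flagged
        failed but still returned so the caller can inspect it.
        """
        config = config or McmcConfig()
        d = self._design
        ndim = d.ndim
        nwalkers = max(config.walkers, 2 * ndim + 2)
        if nwalkers % 2:
            nwalkers += 1
        rng = np.random.default_rng(seed)
        p0 = self._initial_state(nwalkers, rng)
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(nwalkers, ndim, _log_posterior,
                                        args=(d,), vectorize=True, moves=moves)
        sampler.random_state = np.random.RandomState(seed % (2**31 - 1)).get_state()
        state = sampler.run_mcmc(p0, config.warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, config.draws * config.thin, progress=False)
        chain = sampler.get_chain()[::config.thin]       # (draws, walkers, dim)
        chain = np.moveaxis(chain, 0, 1)                 # (walkers, draws, dim)

        base = 4 * len(d.factors)
        e = d.n_eco
        alpha = np.empty((nwalkers, config.draws, len(d.factors), e))
        beta = np.empty_like(alpha)
        for j, fac in enumerate(d.factors):
            a = chain[:, :, base + 2 * e * j: base + 2 * e * j + e]
            c = chain[:, :, base + 2 * e * j + e: base + 2 * e * (j + 1)]
            center, spread = d.scale[fac]
            alpha_std = FACTOR_SIGNS[fac] * np.exp(a)
            beta_std = -c / alpha_std                    # logistic midpoint from slope/intercept
            # un-standardize: x_std = (x - center)/spread
            alpha[:, :, j, :] = alpha_std / spread[None, None, :]
            beta[:, :, j, :] = center[None, None, :] + spread[None, None, :] * beta_std

        posterior = xr.Dataset(
            {
                "alpha": (("chain", "draw", "factor", "ecoregion"), alpha),
                "beta": (("chain", "draw", "factor", "ecoregion"), beta),
            },
            coords={
                "chain": np.arange(nwalkers), "draw": np.arange(config.draws),
                "factor": list(d.factors), "ecoregion": d.ecoregions,
            },
        )
        diagnostics = self._diagnose(sampler, posterior, config)
        return FireThresholdResults(posterior=posterior, diagnostics=diagnostics,
                                    factors=d.factors, ecoregions=d.ecoregions,
                                    ignition_type=self.ignition_type,
                                    failed=bool(diagnostics["failed"]))

    @staticmethod
    def _diagnose(sampler, posterior: xr.Dataset, config: McmcConfig) -> dict:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.from_dict(posterior={
                "alpha": posterior["alpha"].values,
                "beta": posterior["beta"].values,
            })
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        max_rhat = float(max(rhat["alpha"].max(), rhat["beta"].max()))
        min_ess = float(min(ess["alpha"].min(), ess["beta"].min()))
        acc = float(np.mean(sampler.acceptance_fraction))
        failed = (max_rhat > config.rhat_limit) or (acc < 0.05)
        if failed:
            logger.warning("fit flagged failed: max rhat %.3f, acceptance %.3f",
                           max_rhat, acc)
        return {"max_rhat": max_rhat, "min_ess": min_ess,
                "acceptance_fraction": acc, "failed": failed}


def fit_hierarchical_model(table: pd.DataFrame,
                           factors: Sequence[str] = ("vpd", "npp", "pd"),
                           config: Optional[McmcConfig] = None, seed: int = 0,
                           ignition_type: Optional[str] = None) -> FireThresholdResults:
    """Functional wrapper: build a :class:`FireThresholdModel` and fit it."""
    return FireThresholdModel(table, factors=factors,
                              ignition_type=ignition_type).fit(config=config, seed=seed)


def compare_thresholds(res_human: FireThresholdResults,
                       res_lightning: FireThresholdResults,
                       p_level: float = 0.9) -> pd.DataFrame:
    """Per-ecoregion lightning-minus-human threshold difference.

    Pairs posterior draws from the two (independently fitted) models and
    reports the median difference, its 5-95% interval, and the posterior
    probability that the lightning threshold exceeds the human one.
    Ecoregions present in only one model are excluded with a warning.
    """
    common = np.intersect1d(res_human.ecoregions, res_lightning.ecoregions)
    dropped = set(res_human.ecoregions) ^ set(res_lightning.ecoregions)
    if dropped:
        logger.warning("ecoregions present in only one model excluded: %s", sorted(dropped))
    thr_h = res_human.threshold_draws(p_level)
    thr_l = res_lightning.threshold_draws(p_level)
    idx_h = np.searchsorted(res_human.ecoregions, common)
    idx_l = np.searchsorted(res_lightning.ecoregions, common)
    n = min(thr_h.shape[0], thr_l.shape[0])
    diff = thr_l[:n, idx_l] - thr_h[:n, idx_h]
    lo, med, hi = np.percentile(diff, [5, 50, 95], axis=0)
    return pd.DataFrame({
        "ecoregion_id": common,
        "diff_ltn_minus_hm": med, "lo": lo, "hi": hi,
        "prob_positive": (diff > 0).mean(axis=0),
        "p_level": p_level,
    })
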