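"""Generator contracts: degeneracy, determinism, and truth recovery."""
import json

import numpy as np
import pandas as pd
import pytest

from vpdfire.climate import add_vpd
from vpdfire.config import ClimateTruth, LogisticTruth
from vpdfire.synthetic import (TruthRecord, ar1_noise,
                               forced_trajectories, generate_climate_grid,
                               generate_covariates, generate_esm_ensemble,
                               generate_fire_catalog, make_pseudo_observations,
                               true_vpd_threshold, truth_manifest)

from conftest import small_config


def _flat_climate(**kw):
    return ClimateTruth(t_mean_c=kw.pop("t_mean_c", 20.0), rh_mean_pct=40.0,
                        t_seasonal_amp_c=0.0, rh_seasonal_amp_pct=0.0, **kw)


class TestClimateGrid:
    def test_degenerate_generator_yields_constant_temperature(self):
        config = small_config(climate=[_flat_climate(), _flat_climate(t_mean_c=14.0)])
        ds = generate_climate_grid(config)
        eco = ds["ecoregion"].values
        assert np.allclose(ds["tas"].values[:, eco == 0], 20.0)
        assert np.allclose(ds["tas"].values[:, eco == 1], 14.0)

    def test_same_seed_is_bit_identical(self):
        a = generate_climate_grid(small_config(seed=3))
        b = generate_climate_grid(small_config(seed=3))
        assert (a["tas"].values == b["tas"].values).all()
        assert (a["hurs"].values == b["hurs"].values).all()

    def test_noise_free_trend_recovered_exactly(self):
        truth = _flat_climate(t_trend_c_per_decade=0.5)
        config = small_config(climate=[truth, truth])
        ds = generate_climate_grid(config)
        annual = ds["tas"].groupby("time.year").mean(("time", "lat", "lon"))
        years = annual["year"].values.astype(float)
        slope = np.polyfit(years, annual.values, 1)[0]
        assert slope == pytest.approx(0.05, abs=1e-9)

    def test_humidity_clipped_to_valid_range(self, synthetic_bundle):
        _, climate, _, _ = synthetic_bundle
        h = climate["hurs"].values
        assert h.min() >= 1.0 and h.max() <= 100.0

    def test_larger_trend_gives_larger_vpd_trend(self):
        def vpd_trend(t_trend):
            truth = _flat_climate(t_trend_c_per_decade=t_trend)
            ds = add_vpd(generate_climate_grid(small_config(climate=[truth, truth])))
            annual = ds["vpd"].groupby("time.year").mean(("time", "lat", "lon"))
            return np.polyfit(annual["year"].values.astype(float), annual.values, 1)[0]

        assert vpd_trend(0.8) > vpd_trend(0.4) > vpd_trend(0.0)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            small_config(grid_shape=(1, 4))  # fewer rows than ecoregions


class TestFireCatalog:
    def test_saturated_logistic_labels_everything_large(self, synthetic_bundle):
        config, climate, covariates, _ = synthetic_bundle
        steep = config.model_copy(update={"fire": {
            kind: [LogisticTruth(alpha_vpd=500.0, beta_vpd=0.01) for _ in range(2)]
            for kind in ("human", "lightning")
        }, "unknown_cause_fraction": 0.0})
        catalog = generate_fire_catalog(climate, covariates, steep)
        # all but the rare saturated-air ignition sit far above the midpoint
        assert catalog["large_label"].mean() > 0.995

    def test_midpoint_ignitions_are_bernoulli_half(self, rng):
        # direct check of the labelling law at VPD == beta
        from vpdfire.synthetic import _logistic
        p = _logistic(np.full(10000, 1.7), 2.0, 1.7)
        labels = rng.random(10000) < p
        assert abs(labels.mean() - 0.5) < 3 * 0.5 / np.sqrt(10000)

    def test_label_frequency_matches_logistic_truth(self):
        # empirical large-fire fraction converges to the product probability
        config = small_config(seed=13, ignition_rates={
            "human": [150.0, 150.0], "lightning": [150.0, 150.0]},
            unknown_cause_fraction=0.0)
        climate = generate_climate_grid(config)
        covariates = generate_covariates(config)
        catalog = generate_fire_catalog(climate, covariates, config)
        ds = add_vpd(climate)
        times = pd.DatetimeIndex(ds["time"].values)
        for kind in ("human", "lightning"):
            sub = catalog[catalog["cause"] == kind]
            assert len(sub) > 10000
            idx = times.searchsorted(pd.DatetimeIndex(sub["discovery_date"]))
            vpd = ds["vpd"].values[idx, sub["lat_idx"], sub["lon_idx"]]
            expected = np.zeros(len(sub))
            for e in (0, 1):
                mask = (sub["ecoregion_id"] == e).to_numpy()
                t = config.fire[kind][e]
                expected[mask] = 1.0 / (1.0 + np.exp(-t.alpha_vpd * (vpd[mask] - t.beta_vpd)))
            p = expected.mean()
            half_width = 3.0 * np.sqrt(p * (1 - p) / len(sub))
            assert abs(sub["large_label"].mean() - p) < half_width

    def test_lightning_season_is_drier_than_human(self, synthetic_bundle):
        config, climate, covariates, catalog = synthetic_bundle
        ds = add_vpd(climate)
        times = pd.DatetimeIndex(ds["time"].values)
        idx = times.searchsorted(pd.DatetimeIndex(catalog["discovery_date"]))
        vpd = ds["vpd"].values[idx, catalog["lat_idx"], catalog["lon_idx"]]
        catalog = catalog.assign(vpd=vpd)
        by_cause = catalog.groupby("cause")["vpd"].mean()
        assert by_cause["lightning"] > by_cause["human"]

    def test_unknown_cause_fraction_emitted(self, synthetic_bundle):
        config, _, _, catalog = synthetic_bundle
        frac = (catalog["cause"] == "unknown").mean()
        assert frac == pytest.approx(config.unknown_cause_fraction, abs=0.02)

    def test_catalog_deterministic(self, synthetic_bundle):
        config, climate, covariates, catalog = synthetic_bundle
        again = generate_fire_catalog(climate, covariates, config)
        pd.testing.assert_frame_equal(catalog, again)


class TestEsmEnsemble:
    def test_zero_noise_members_equal_trajectory(self):
        config = small_config()
        config = config.model_copy(update={"esm": config.esm.model_copy(
            update={"internal_sd_days": 1e-12})})
        ens = generate_esm_ensemble(config)
        traj = forced_trajectories(config)
        for forcing in ("ALL", "GHG", "NAT"):
            assert np.allclose(ens.members[forcing], traj[forcing], atol=1e-9)

    def test_forcing_additivity_exact_at_trajectory_level(self):
        traj = forced_trajectories(small_config())
        assert np.allclose(traj["ALL"], traj["GHG"] + traj["OANT"] + traj["NAT"])

    def test_oant_mean_converges_to_trajectory(self):
        config = small_config()
        config = config.model_copy(update={"esm": config.esm.model_copy(
            update={"n_models": 30, "n_members": 10, "n_controls": 1,
                    "control_length_years": 84})})
        ens = generate_esm_ensemble(config)
        traj = forced_trajectories(config)
        err = np.abs(ens.ensemble_mean("OANT").values - traj["OANT"])
        assert err.mean() < 0.5  # 300 members shrink the AR(1) noise

    def test_control_autocorrelation_matches_truth(self, rng):
        x = ar1_noise(rng, (420,), 0.5, 1.0)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.5, abs=0.05)

    def test_oant_effective_member_count(self):
        ens = generate_esm_ensemble(small_config())
        n = ens.member_count("ALL")
        assert ens.member_count("OANT") == pytest.approx(n / 3)


class TestTruthManifest:
    def test_threshold_closed_form_at_09(self):
        assert true_vpd_threshold(2.0, 1.5, 0.9) == pytest.approx(2.599, abs=1e-3)

    def test_midpoint_probability_recovers_beta(self):
        assert true_vpd_threshold(3.7, 1.23, 0.5) == 1.23

    def test_round_trip(self):
        manifest = truth_manifest(small_config(seed=9))
        again = TruthRecord.from_json(manifest.to_json())
        assert again == manifest
        assert again.seed == 9

    def test_pseudo_observations_follow_scaling(self):
        config = small_config()
        config = config.model_copy(update={"esm": config.esm.model_copy(
            update={"internal_sd_days": 1e-12})})
        y = make_pseudo_observations(config, scaling={"GHG": 2.0, "OANT": 0.0, "NAT": 0.0})
        traj = forced_trajectories(config)
        assert np.allclose(y.values, 2.0 * traj["GHG"], atol=1e-9)
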