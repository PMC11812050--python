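"""Regularized optimal fingerprinting: pools, shrinkage, whitening, TLS."""
import numpy as np
import pandas as pd
import pytest

from vpdfire.attribution import (AttributionModel, NonIdentifiableError,
                                 build_control_subseries,
                                 estimate_regularized_covariance, prewhiten,
                                 run_attribution, scaling_factor_ci,
                                 tls_scaling_factors, attributable_trends,
                                 _inverse_sqrt)
from vpdfire.synthetic import generate_esm_ensemble, make_pseudo_observations
from conftest import small_config


class TestControlSubseries:
    def test_420_year_control_yields_ten_windows_split_five_five(self):
        pool1, pool2 = build_control_subseries([np.random.default_rng(0).normal(size=420)],
                                               window_years=42)
        assert pool1.shape == (5, 21)
        assert pool2.shape == (5, 21)

    def test_84_year_control_yields_one_per_pool(self):
        pool1, pool2 = build_control_subseries([np.zeros(84) + np.arange(84)],
                                               window_years=42)
        assert pool1.shape[0] == 1 and pool2.shape[0] == 1

    def test_each_subseries_centred(self, rng):
        pool1, pool2 = build_control_subseries([rng.normal(size=420)], 42)
        assert np.allclose(pool1.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(pool2.mean(axis=1), 0.0, atol=1e-12)

    def test_short_controls_excluded_then_error(self, rng):
        with pytest.raises(ValueError):
            build_control_subseries([rng.normal(size=30)], 42)
        # one usable control among short ones still works
        pool1, pool2 = build_control_subseries(
            [rng.normal(size=30), rng.normal(size=84)], 42)
        assert pool1.shape[0] == 1


class TestRegularizedCovariance:
    def test_duplicated_subseries_sample_singular_but_regularized_invertible(self):
        row = np.random.default_rng(1).normal(size=21)
        row = row - row.mean()
        pool = np.tile(row, (8, 1))
        sample = pool.T @ pool / 8
        assert np.linalg.matrix_rank(sample) == 1
        reg, shrink = estimate_regularized_covariance(pool)
        assert shrink > 0
        assert np.all(np.linalg.eigvalsh(reg) > 0)

    def test_shrinkage_narrows_eigenvalue_spread(self, rng):
        pool = rng.normal(size=(12, 21))
        pool = pool - pool.mean(axis=1, keepdims=True)
        sample = pool.T @ pool / pool.shape[0]
        reg, _ = estimate_regularized_covariance(pool)
        assert np.ptp(np.linalg.eigvalsh(reg)) < np.ptp(np.linalg.eigvalsh(sample))

    def test_consistency_with_many_subseries(self, rng):
        # non-spherical truth, otherwise the shrinkage target already equals it
        scales = np.sqrt(np.linspace(1.0, 5.0, 10))
        pool = rng.normal(size=(500, 10)) * scales
        reg, shrink = estimate_regularized_covariance(pool)
        _, shrink_small = estimate_regularized_covariance(pool[:50])
        sample = pool.T @ pool / 500
        assert shrink < shrink_small          # weight vanishes with pool size
        assert np.linalg.norm(reg - sample) / np.linalg.norm(sample) < 0.05

    def test_minimum_pool_size(self):
        with pytest.raises(ValueError):
            estimate_regularized_covariance(np.ones((1, 5)))


class TestPrewhiten:
    def test_identity_covariance_is_noop(self, rng):
        x = rng.normal(size=8)
        assert np.allclose(prewhiten(x, np.eye(8)), x)

    def test_scalar_covariance_scales(self, rng):
        x = rng.normal(size=6)
        assert np.allclose(prewhiten(x, 4.0 * np.eye(6)), x / 2.0)

    def test_round_trip(self, rng):
        a = rng.normal(size=(9, 9))
        cov = a @ a.T + 9 * np.eye(9)
        x = rng.normal(size=9)
        w = prewhiten(x, cov)
        sqrt = np.linalg.inv(_inverse_sqrt(cov))
        assert np.allclose(sqrt @ w, x, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            prewhiten(rng.normal(size=5), np.eye(4))

    def test_whitened_controls_have_unit_variance(self, rng):
        cov_true = np.diag(np.linspace(1, 5, 12))
        draws = rng.multivariate_normal(np.zeros(12), cov_true, size=4000)
        w = prewhiten(draws, cov_true)
        assert np.allclose(np.var(w, axis=0), 1.0, atol=0.15)


class TestTls:
    def test_self_regression_is_unity(self, rng):
        x = rng.normal(size=21)
        beta = tls_scaling_factors(x, [x], [1000.0])
        assert beta[0] == pytest.approx(1.0, abs=1e-12)

    def test_doubled_observation_scales(self, rng):
        x = rng.normal(size=21)
        beta = tls_scaling_factors(2.0 * x, [x], [1000.0])
        assert beta[0] == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_two_signal_recovery(self):
        t = np.arange(20.0)
        x1 = np.cos(2 * np.pi * t / 20)
        x2 = np.sin(2 * np.pi * t / 20)
        y = x1 + 0.5 * x2
        beta = tls_scaling_factors(y, [x1, x2], [50.0, 50.0])
        assert np.allclose(beta, [1.0, 0.5], atol=1e-10)

    def test_noise_free_limit_matches_ols(self, rng):
        x1, x2 = rng.normal(size=(2, 30))
        y = 1.3 * x1 - 0.4 * x2
        beta = tls_scaling_factors(y, [x1, x2], [1e9, 1e9])
        ols, *_ = np.linalg.lstsq(np.column_stack([x1, x2]), y, rcond=None)
        assert np.allclose(beta, ols, atol=1e-8)

    def test_degenerate_spectrum_flagged(self):
        with pytest.raises(NonIdentifiableError):
            tls_scaling_factors(np.zeros(5), [np.zeros(5)], [1.0])

    def test_member_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            tls_scaling_factors(rng.normal(size=5), [rng.normal(size=5)], [1.0, 2.0])


class TestScalingFactorCi:
    def test_refuses_too_few_draws(self, rng):
        with pytest.raises(ValueError):
            scaling_factor_ci(rng.normal(size=5), [rng.normal(size=5)], [1.0],
                              np.eye(5), mc_draws=50)

    def test_near_zero_noise_interval_collapses(self, rng):
        x = rng.normal(size=21)
        lo, hi = scaling_factor_ci(1.5 * x, [x], [1e6], 1e-18 * np.eye(21),
                                   mc_draws=200, rng=rng)
        assert hi[0] - lo[0] < 1e-4
        assert lo[0] <= 1.5 + 1e-9 and hi[0] >= 1.5 - 1e-9


class TestAttributableTrends:
    def test_multiplicative_identity(self):
        years = pd.Index(range(1979, 2021), name="year")
        forced = pd.Series(0.4 * np.arange(42.0), index=years)
        trends, table = attributable_trends(np.array([1.2]), np.array([0.5]),
                                            np.array([1.5]), [forced],
                                            np.array([True]))
        assert trends[0] == pytest.approx(0.4)
        assert table["trend"].iloc[0] == pytest.approx(0.48)
        assert table["lo"].iloc[0] == pytest.approx(0.2)
        assert table["hi"].iloc[0] == pytest.approx(0.6)

    def test_negative_trend_swaps_interval_endpoints(self):
        years = pd.Index(range(2000, 2010), name="year")
        forced = pd.Series(-1.0 * np.arange(10.0), index=years)
        _, table = attributable_trends(np.array([1.0]), np.array([0.5]),
                                       np.array([1.5]), [forced], np.array([True]))
        assert table["lo"].iloc[0] < table["hi"].iloc[0]

    def test_undetectable_flag_follows_detection(self):
        years = pd.Index(range(2000, 2010), name="year")
        forced = pd.Series(np.arange(10.0), index=years)
        _, table = attributable_trends(np.array([0.2]), np.array([-0.5]),
                                       np.array([0.9]), [forced], np.array([False]))
        assert bool(table["undetectable"].iloc[0])


class TestRunAttribution:
    def test_one_signal_on_exact_ensemble_mean_is_unity(self):
        config = small_config(seed=4)
        ens = generate_esm_ensemble(config)
        y = ens.ensemble_mean("ALL")
        res = run_attribution(y, ens, "one_signal", mc_draws=150,
                              rng=np.random.default_rng(0))
        assert res.beta[0] == pytest.approx(1.0, abs=1e-8)

    def test_three_signal_recovery_with_noise(self):
        config = small_config(seed=8)
        ens = generate_esm_ensemble(config)
        y = make_pseudo_observations(config)
        res = run_attribution(y, ens, "three_signal", mc_draws=400,
                              rng=np.random.default_rng(1))
        for i in range(3):
            assert res.ci_lo[i] <= 1.0 <= res.ci_hi[i]

    def test_doubled_ghg_contribution_detected_above_one(self):
        config = small_config(seed=9)
        ens = generate_esm_ensemble(config)
        y = make_pseudo_observations(config, scaling={"GHG": 2.0, "OANT": 1.0, "NAT": 1.0})
        res = run_attribution(y, ens, "three_signal", mc_draws=400,
                              rng=np.random.default_rng(2))
        ghg = list(res.forcings).index("GHG")
        assert res.ci_lo[ghg] > 1.0
        for i in range(3):
            if i != ghg:
                assert res.ci_lo[i] <= 1.0 <= res.ci_hi[i]

    def test_detection_flag_definition(self):
        config = small_config(seed=10)
        ens = generate_esm_ensemble(config)
        res = run_attribution(make_pseudo_observations(config), ens,
                              "three_signal", mc_draws=200,
                              rng=np.random.default_rng(3))
        assert (res.detected == (res.ci_lo > 0)).all()
        assert (res.ci_lo <= res.ci_hi).all()

    def test_unknown_design_and_missing_forcing_rejected(self):
        config = small_config(seed=11)
        ens = generate_esm_ensemble(config)
        y = make_pseudo_observations(config)
        with pytest.raises(ValueError, match="design"):
            AttributionModel(y, ens, design="two_signal")
        del ens.members["NAT"]
        with pytest.raises(ValueError, match="NAT"):
            AttributionModel(y, ens, design="three_signal")

    def test_summary_and_json_round_trip(self):
        import json
        config = small_config(seed=12)
        ens = generate_esm_ensemble(config)
        res = run_attribution(make_pseudo_observations(config), ens,
                              "three_signal", mc_draws=150,
                              rng=np.random.default_rng(4))
        payload = json.loads(res.to_json())
        assert payload["forcings"] == ["GHG", "OANT", "NAT"]
        assert len(payload["beta"]) == 3
        tab = res.summary()
        assert list(tab["forcing"]) == ["GHG", "OANT", "NAT"]
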