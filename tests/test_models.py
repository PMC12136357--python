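"""Trend models: linear predictor, priors, recovery, LASSO, summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cprtrends as ct
from cprtrends.models import (ConvergenceWarning, ModelConfig,
                              PlanktonTrendModel, TrendResults,
                              linear_predictor)
from tests.conftest import fast_config
from tests.test_synthetic import flat_params


class TestLinearPredictor:
    BASE = {"month_effects": np.zeros(12), "lat_gradient": 0.0, "trend": 0.0,
            "mean_latitude": 50.0}

    def test_all_zero_effects(self):
        row = {"month": 4, "lat_band": 52.5, "year": 1980}
        assert linear_predictor(self.BASE, row) == 0.0

    def test_hand_arithmetic(self):
        params = {"month_effects": np.ones(12), "lat_gradient": 0.1,
                  "trend": 0.01, "mean_latitude": 50.0,
                  "anomaly_effect": 0.0}
        row = {"month": 2, "lat_band": 52.5, "year": 1970}
        # 1 + 0.1*2.5 + 0.01*10 + 0 = 1.35
        assert linear_predictor(params, row, anomaly=3.0) == pytest.approx(1.35)

    def test_missing_anomaly_rejected(self):
        params = dict(self.BASE, anomaly_effect=0.5)
        with pytest.raises(ValueError, match="anomaly"):
            linear_predictor(params, {"month": 1, "lat_band": 50, "year": 1970})

    def test_ts_with_zero_steps_equals_tst_with_zero_phi(self):
        rng = np.random.default_rng(3)
        month_effects = rng.normal(size=12)
        common = {"month_effects": month_effects, "lat_gradient": 0.07,
                  "trend": -0.013, "mean_latitude": 55.0}
        tst = dict(common, anomaly_effect=0.0)
        ts = dict(common, decade_effects=np.zeros(3),
                  decades=[1960, 1970, 1980])
        for month in (1, 6, 12):
            row = {"month": month, "lat_band": 57.5, "year": 1975,
                   "decade": 1970}
            assert linear_predictor(tst, row, anomaly=1.7) == \
                pytest.approx(linear_predictor(ts, row))


class TestModelConfig:
    def test_retained_draw_count(self):
        cfg = ModelConfig()
        assert (cfg.chains, cfg.iterations, cfg.burn_in, cfg.thinning) == \
            (3, 10_000, 4_000, 10)
        assert cfg.n_draws == 3 * 600

    def test_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(burn_in=10_000, iterations=10_000)
        with pytest.raises(ValueError):
            ModelConfig(thinning=0)
        with pytest.raises(ValueError):
            ModelConfig(ig_shape=-1)

    def test_yaml_round_trip(self, tmp_path):
        cfg = ModelConfig(chains=2, iterations=800, burn_in=100, seed=7)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert ModelConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestModelValidation:
    def test_requires_two_provinces_and_years(self, sim):
        _, _, bins, anoms = sim
        one_prov = bins[bins["province"] == "NECS"]
        with pytest.raises(ValueError, match="provinces"):
            PlanktonTrendModel(one_prov, anomalies=anoms)
        one_year = bins[bins["year"] == 1990]
        with pytest.raises(ValueError, match="years"):
            PlanktonTrendModel(one_year, anomalies=anoms)

    def test_tst_requires_anomalies(self, sim):
        _, _, bins, _ = sim
        with pytest.raises(ValueError, match="anomal"):
            PlanktonTrendModel(bins, variant="time-space-temperature")

    def test_missing_anomaly_keys_reported(self, sim):
        _, _, bins, anoms = sim
        with pytest.raises(ValueError, match="missing anomaly"):
            PlanktonTrendModel(bins, anomalies=anoms.iloc[:-10])

    def test_unknown_response_or_variant(self, sim):
        _, _, bins, anoms = sim
        with pytest.raises(ValueError):
            PlanktonTrendModel(bins, response="chlorophyll", anomalies=anoms)
        with pytest.raises(ValueError):
            PlanktonTrendModel(bins, variant="time-only", anomalies=anoms)


class TestPriorSampling:
    """With no data the Gibbs chain must sample the joint prior."""

    @pytest.fixture(scope="class")
    def prior_draws(self, empty_bins_class):
        cfg = ModelConfig(chains=2, iterations=40_000, burn_in=4_000,
                          thinning=40, seed=9)
        tst = PlanktonTrendModel(empty_bins_class, variant="time-space-temperature").fit(cfg)
        ts = PlanktonTrendModel(empty_bins_class, variant="time-space").fit(cfg)
        return tst, ts

    @pytest.fixture(scope="class")
    def empty_bins_class(self):
        cols = ["province", "lat_band", "year", "month", "decade",
                "diatom_ugC", "dinoflagellate_ugC", "h"]
        return pd.DataFrame(columns=cols)

    def test_month_effect_marginal_matches_prior(self, prior_draws):
        tst, _ = prior_draws
        rng = np.random.default_rng(123)
        s2 = 0.1 / rng.gamma(0.1, 1.0, 4000)
        direct = rng.normal(0.0, np.sqrt(s2))
        p = stats.ks_2samp(tst.stacked("theta")[:, 0, 0], direct).pvalue
        assert p > 0.01

    def test_sigma_marginal_is_uniform(self, prior_draws):
        tst, _ = prior_draws
        p = stats.ks_1samp(tst.stacked("sigma")[:, 0],
                           stats.uniform(0, 10).cdf).pvalue
        assert p > 0.01

    def test_lasso_scales_match_priors(self, prior_draws):
        _, ts = prior_draws
        xi = ts.stacked("xi")[:, 0]
        assert stats.ks_1samp(xi, stats.uniform(0, 2).cdf).pvalue > 0.01
        lam = ts.stacked("lam")
        assert stats.ks_1samp(lam, stats.gamma(1, scale=1).cdf).pvalue > 0.01
        assert np.all((xi > 0) & (xi < 2))


class TestRecovery:
    def test_two_province_trend_recovery(self):
        """gamma = +0.02 and -0.01 with sigma = 0.3 over 40 years x 4 bands
        x 12 months: medians within 0.005, 95% CIs cover truth."""
        p = flat_params(years=(1960, 1999))
        p.provinces = ("NADR", "NECS")
        p.lat_ranges = {"NADR": (42.5, 52.5), "NECS": (47.5, 57.5)}
        truth = {"NADR": 0.02, "NECS": -0.01}
        p.month_effects["diatom"] = {pr: np.full(12, 8.0) for pr in p.provinces}
        p.trend["diatom"] = dict(truth)
        p.resid_sd["diatom"] = {pr: 0.3 for pr in p.provinces}
        p.sst_resid_sd = {pr: 1.0 for pr in p.provinces}
        sst = ct.simulate_sst(p, seed=21)
        bins = ct.aggregate.impute_zeros(ct.simulate_bins(p, sst, seed=21))
        anoms = sst.assign(anomaly=sst["anomaly_true"])[
            ["province", "lat_band", "year", "month", "anomaly"]]
        res = PlanktonTrendModel(bins, response="log_diatom",
                                 anomalies=anoms).fit(fast_config(seed=22))
        g = res.stacked("gamma")
        lo, hi = np.quantile(g, [0.025, 0.975], axis=0)
        med = np.median(g, axis=0)
        for i, prov in enumerate(res.model.provinces):
            assert lo[i] <= truth[prov] <= hi[i]
            assert med[i] == pytest.approx(truth[prov], abs=0.005)

    def test_index_anomaly_effect_recovery(self):
        """phi = -0.10 on the logit index recovered at ~2,000 bins."""
        p = flat_params(years=(1980, 2000))
        p.provinces = ("NADR", "NECS")
        p.lat_ranges = {"NADR": (42.5, 52.5), "NECS": (47.5, 57.5)}
        for g, phi, sd in (("diatom", 0.25, 0.6), ("dinoflagellate", 0.35, 0.6)):
            p.month_effects[g] = {pr: np.full(12, 8.0) for pr in p.provinces}
            p.anomaly_effect[g] = {pr: phi for pr in p.provinces}
            p.resid_sd[g] = {pr: sd for pr in p.provinces}
        p.sst_resid_sd = {pr: 1.0 for pr in p.provinces}
        sst = ct.simulate_sst(p, seed=31)
        bins = ct.aggregate.impute_zeros(ct.simulate_bins(p, sst, seed=31))
        anoms = sst.assign(anomaly=sst["anomaly_true"])[
            ["province", "lat_band", "year", "month", "anomaly"]]
        res = PlanktonTrendModel(bins, response="logit_index",
                                 anomalies=anoms).fit(fast_config(seed=32))
        med = np.median(res.stacked("phi"), axis=0)
        assert np.all((-0.15 <= med) & (med <= -0.05))


class TestVariants:
    @pytest.fixture(scope="class")
    def ts_fit(self, sim):
        _, _, bins, _ = sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            return PlanktonTrendModel(bins, response="log_diatom",
                                      variant="time-space").fit(fast_config(seed=41))

    def test_shared_effects_have_overlapping_cis(self, sim, ts_fit, fit_diatom):
        for name in ("gamma", "eta"):
            a = fit_diatom.stacked(name)
            b = ts_fit.stacked(name)
            lo_a, hi_a = np.quantile(a, [0.025, 0.975], axis=0)
            lo_b, hi_b = np.quantile(b, [0.025, 0.975], axis=0)
            assert np.all((lo_a <= hi_b) & (lo_b <= hi_a))

    def test_temperature_variant_tightens_trend_ci(self, ts_fit, fit_diatom):
        """The anomaly covariate absorbs residual variance, so the trend's
        CI should not be wider on average than under the decade model."""
        wa = np.diff(np.quantile(fit_diatom.stacked("gamma"),
                                 [0.025, 0.975], axis=0), axis=0)
        wb = np.diff(np.quantile(ts_fit.stacked("gamma"),
                                 [0.025, 0.975], axis=0), axis=0)
        assert wa.mean() <= wb.mean()

    def test_null_decades_cluster_on_zero(self, ts_fit):
        d = ts_fit.stacked("delta")
        lo, hi = np.quantile(d, [0.025, 0.975], axis=0)
        frac_cover = np.mean((lo <= 0) & (0 <= hi))
        assert frac_cover >= 0.9

    def test_lasso_detects_single_large_step(self):
        p = flat_params(years=(1960, 1999))
        p.month_effects["diatom"] = {pr: np.full(12, 8.0) for pr in p.provinces}
        p.resid_sd["diatom"] = {pr: 0.5 for pr in p.provinces}
        p.decade_effects["diatom"]["NADR"][2] = 0.5
        sst = ct.simulate_sst(p, seed=51)
        bins = ct.aggregate.impute_zeros(ct.simulate_bins(p, sst, seed=51))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = PlanktonTrendModel(bins, response="log_diatom",
                                     variant="time-space").fit(fast_config(seed=52))
        med = np.median(res.stacked("delta"), axis=0)
        inj = med[res.model.provinces.index("NADR"), 2]
        others = np.abs(med).ravel()
        others = np.delete(others,
                           res.model.provinces.index("NADR") * med.shape[1] + 2)
        assert abs(inj) > 2.0 * others.max()


class TestResults:
    def test_draw_shapes_and_positivity(self, fit_diatom):
        res = fit_diatom
        cfg = res.config
        per_chain = (cfg.iterations - cfg.burn_in) // cfg.thinning
        assert res.draws["gamma"].shape == (cfg.chains, per_chain, 5)
        assert res.draws["theta"].shape == (cfg.chains, per_chain, 5, 12)
        assert res.n_draws == cfg.n_draws
        assert np.all(res.stacked("sigma") > 0)

    def test_slope_summary_quantile_nesting(self, fit_diatom):
        tab = fit_diatom.slope_summary()
        assert (tab["q2.5"] <= tab["q17"]).all()
        assert (tab["q17"] <= tab["median"]).all()
        assert (tab["median"] <= tab["q83"]).all()
        assert (tab["q83"] <= tab["q97.5"]).all()
        assert set(tab["effect"]) == {"trend", "latitude", "anomaly", "month"}

    def test_slope_summary_degenerate_draws(self, empty_bins):
        model = PlanktonTrendModel(empty_bins, variant="time-space-temperature")
        P, c = 2, 0.37
        draws = {"theta": np.full((2, 10, P, 12), 1.5),
                 "eta": np.full((2, 10, P), -0.1),
                 "gamma": np.full((2, 10, P), c),
                 "phi": np.full((2, 10, P), 0.0),
                 "sigma": np.ones((2, 10, P)),
                 "s2_theta": np.ones(20).reshape(2, 10)}
        res = TrendResults(model, fast_config(), draws)
        tab = res.slope_summary()
        trend = tab[tab["effect"] == "trend"]
        for col in ("median", "q2.5", "q17", "q83", "q97.5"):
            assert (trend[col] == c).all()

    def test_summary_text_mentions_key_facts(self, fit_diatom):
        text = fit_diatom.summary()
        assert "log_diatom" in text
        assert "time-space-temperature" in text
        assert "trend" in text

    def test_nonconvergence_is_flagged_not_silent(self, sim):
        _, _, bins, _ = sim
        cfg = ModelConfig(chains=2, iterations=60, burn_in=10, thinning=1,
                          seed=61)
        with pytest.warns(ConvergenceWarning):
            res = PlanktonTrendModel(bins, response="log_diatom",
                                     variant="time-space").fit(cfg)
        assert res.converged is False
        assert {"parameter", "rhat_max", "ess_min"} <= set(res.convergence.columns)

    def test_save_load_round_trip(self, fit_diatom, tmp_path):
        fit_diatom.save(tmp_path / "fit")
        back = TrendResults.load(tmp_path / "fit")
        np.testing.assert_allclose(back.stacked("gamma"),
                                   fit_diatom.stacked("gamma"))
        assert back.model.response == "log_diatom"
        assert back.model.provinces == fit_diatom.model.provinces
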