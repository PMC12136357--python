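"""Generator determinism, stated noise models, and pipeline round trips."""

import numpy as np
import pandas as pd
import pytest

import cprtrends as ct
from cprtrends.aggregate import prepare_bins
from cprtrends.biomass import community_biomass, impute_missing_size
from cprtrends.synthetic import (GenerativeParams, generate_taxon_table,
                                 simulate_abundance, simulate_bins,
                                 simulate_sst)


def flat_params(**overrides):
    """Noise-free, signal-free baseline that tests can perturb."""
    p = GenerativeParams(years=overrides.pop("years", (1960, 1999)))
    for g in ("diatom", "dinoflagellate"):
        p.month_effects[g] = {pr: np.full(12, 8.0) for pr in p.provinces}
        p.lat_gradient[g] = {pr: 0.0 for pr in p.provinces}
        p.trend[g] = {pr: 0.0 for pr in p.provinces}
        p.anomaly_effect[g] = {pr: 0.0 for pr in p.provinces}
        p.resid_sd[g] = {pr: 0.0 for pr in p.provinces}
        p.zero_inflation[g] = {pr: 0.0 for pr in p.provinces}
    p.sst_month_effects = {pr: np.full(12, 10.0) for pr in p.provinces}
    p.sst_lat_gradient = {pr: 0.0 for pr in p.provinces}
    p.sst_trend = {pr: 0.0 for pr in p.provinces}
    p.sst_resid_sd = {pr: 0.0 for pr in p.provinces}
    for k, v in overrides.items():
        setattr(p, k, v)
    return p


class TestTaxonTable:
    def test_minimal_case(self):
        t = generate_taxon_table(1, 1, seed=1)
        assert len(t) == 2
        assert (t["volume_um3"] > 0).all()

    def test_seed_determinism(self):
        a = generate_taxon_table(5, 5, seed=7)
        b = generate_taxon_table(5, 5, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_geometric_means_near_group_medians(self):
        t = generate_taxon_table(50, 50, seed=3)
        for group, median in (("diatom", 1e3), ("dinoflagellate", 1e4)):
            v = t.loc[(t["group"] == group) & t["volume_um3"].notna(),
                      "volume_um3"]
            gm = np.exp(np.mean(np.log(v)))
            assert median / 2 < gm < median * 2

    def test_one_missing_volume_per_group(self):
        t = generate_taxon_table(5, 5, seed=1)
        assert t.groupby("group")["volume_um3"].apply(
            lambda s: s.isna().sum()).eq(1).all()

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            generate_taxon_table(0, 3, seed=1)


class TestSimulateSST:
    def test_noise_free_linear_trend(self):
        p = flat_params(years=(1960, 2010))
        p.sst_trend = {pr: 0.02 for pr in p.provinces}
        sst = simulate_sst(p, seed=1)
        sub = sst[(sst["province"] == "NADR") & (sst["month"] == 6)]
        band = sub["lat_band"].iloc[0]
        sub = sub[sub["lat_band"] == band].set_index("year")
        assert sub.loc[2010, "sst"] - sub.loc[1960, "sst"] == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_latitudinal_gradient(self):
        p = flat_params()
        p.sst_lat_gradient = {pr: -0.5 for pr in p.provinces}
        sst = simulate_sst(p, seed=1)
        sub = sst[(sst["province"] == "NECS") & (sst["month"] == 1)
                  & (sst["year"] == 1980)].sort_values("lat_band")
        diffs = np.diff(sub["sst"].to_numpy())
        np.testing.assert_allclose(diffs, -1.25, atol=1e-12)

    def test_residual_sd_matches_noise_model(self):
        sst = simulate_sst(GenerativeParams(), seed=5)  # sd 1.0, n > 10,000
        assert len(sst) >= 10_000
        assert sst["anomaly_true"].std() == pytest.approx(1.0, abs=0.05)

    def test_full_factorial_coverage(self):
        p = GenerativeParams(years=(1990, 1992))
        sst = simulate_sst(p, seed=2)
        for prov in p.provinces:
            sub = sst[sst["province"] == prov]
            assert len(sub) == len(p.bands(prov)) * 3 * 12

    def test_empty_years_rejected(self):
        with pytest.raises(ValueError):
            simulate_sst(GenerativeParams(), seed=1, years=[])


class TestSimulateAbundance:
    def test_degenerate_inflation_removes_group(self):
        p = flat_params(years=(1990, 1994))
        p.zero_inflation["dinoflagellate"] = {pr: 1.0 for pr in p.provinces}
        traits = generate_taxon_table(2, 2, seed=1)
        sst = simulate_sst(p, seed=1)
        rec = simulate_abundance(p, traits, sst, seed=1)
        assert (rec["group"] == "diatom").all()

    def test_noise_free_round_trip_recovers_mu_exactly(self):
        p = flat_params(years=(1990, 1994))
        for g in ("diatom", "dinoflagellate"):
            p.month_effects[g] = {pr: np.linspace(7.0, 9.0, 12)
                                  for pr in p.provinces}
            p.lat_gradient[g] = {pr: 0.05 for pr in p.provinces}
            p.trend[g] = {pr: 0.01 for pr in p.provinces}
        traits = generate_taxon_table(1, 1, seed=2, with_missing=False)
        sst = simulate_sst(p, seed=2)
        rec = simulate_abundance(p, traits, sst, seed=2)
        bins = prepare_bins(community_biomass(rec, impute_missing_size(traits)))
        for prov in ("ARCT", "NECS"):
            sub = bins[bins["province"] == prov]
            lbar = p.mean_latitude(prov)
            mu = (np.linspace(7.0, 9.0, 12)[sub["month"] - 1]
                  + 0.05 * (sub["lat_band"] - lbar)
                  + 0.01 * (sub["year"] - 1960))
            np.testing.assert_allclose(np.log(sub["diatom_ugC"]), mu, atol=1e-9)

    def test_seed_determinism_and_divergence(self):
        p = GenerativeParams(years=(1995, 1999))
        traits = generate_taxon_table(3, 3, seed=4)
        sst = simulate_sst(p, seed=4)
        a = simulate_abundance(p, traits, sst, seed=4)
        b = simulate_abundance(p, traits, sst, seed=4)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_abundance(p, traits, sst, seed=5)
        assert not a["abundance"].equals(c["abundance"])

    def test_missing_volume_taxon_excluded_from_partition(self):
        p = GenerativeParams(years=(1995, 1996))
        traits = generate_taxon_table(3, 3, seed=4)  # one NaN per group
        rec = simulate_abundance(p, traits, simulate_sst(p, seed=4), seed=4)
        missing = traits.loc[traits["volume_um3"].isna(), "taxon"]
        assert not rec["taxon"].isin(set(missing)).any()

    def test_traits_must_cover_both_groups(self):
        p = GenerativeParams(years=(1995, 1996))
        traits = generate_taxon_table(2, 2, seed=1)
        only_diatoms = traits[traits["group"] == "diatom"]
        with pytest.raises(ValueError, match="both groups"):
            simulate_abundance(p, only_diatoms, simulate_sst(p, seed=1), seed=1)


class TestZeroStructure:
    def test_zero_fractions_match_configuration(self, sim):
        p, sst, _, _ = sim
        raw = simulate_bins(p, sst, seed=101)
        # cells where both groups are zero are dropped from the output, so
        # count zeros as grid cells without a positive record of the group
        for prov in p.provinces:
            sub = raw[raw["province"] == prov]
            total = len(sst[sst["province"] == prov])
            frac = 1.0 - (sub["dinoflagellate_ugC"] > 0).sum() / total
            assert frac == pytest.approx(
                p.zero_inflation["dinoflagellate"][prov], abs=0.01)

    def test_zeros_are_the_lowest_biomass_cells(self, sim):
        p, sst, _, _ = sim
        raw = simulate_bins(p, sst, seed=101)
        sub = raw[raw["province"] == "NECS"]
        zero_present = sub[sub["dinoflagellate_ugC"] == 0]
        assert len(zero_present) > 0

    def test_truth_yaml_round_trip(self, tmp_path, default_params):
        path = tmp_path / "truth.yaml"
        default_params.to_yaml(path)
        back = GenerativeParams.from_yaml(path)
        assert back.trend == default_params.trend
        np.testing.assert_allclose(
            back.month_effects["diatom"]["NECS"],
            default_params.month_effects["diatom"]["NECS"])
        assert back.resid_corr == default_params.resid_corr


class TestIndexEffects:
    def test_index_truth_is_group_difference(self, default_params):
        p = default_params
        eff = p.index_effects("SARC")
        d, f = "diatom", "dinoflagellate"
        assert eff["trend"] == pytest.approx(
            p.trend[d]["SARC"] - p.trend[f]["SARC"])
        np.testing.assert_allclose(
            eff["month_effects"],
            np.asarray(p.month_effects[d]["SARC"])
            - np.asarray(p.month_effects[f]["SARC"]))

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError):
            p = GenerativeParams()
            p.zero_inflation["diatom"]["NECS"] = 1.5
            p.validate()
        with pytest.raises(ValueError):
            p = GenerativeParams()
            p.resid_corr = 2.0
            p.validate()
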