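import json

import numpy as np
import pandas as pd
import pytest

import sarc1066 as s
from sarc1066.synthetic_data import (ConfigurationError, SiteProfile,
                                     apply_missingness, default_profiles,
                                     default_truth, simulate_cohort)


class TestConfigValidation:
    def test_no_profiles_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cohort([], seed=0)

    def test_zero_n_rejected_before_sampling(self):
        prof = default_profiles()[0]
        prof.n = 0
        with pytest.raises(ConfigurationError, match="n must be"):
            simulate_cohort([prof], seed=0)

    def test_bad_probabilities_rejected(self):
        prof = default_profiles()[0]
        prof.age_band_probs = (0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ConfigurationError, match="summing to 1"):
            simulate_cohort([prof], seed=0)

    def test_duplicate_sites_rejected(self):
        p = default_profiles()[0]
        with pytest.raises(ConfigurationError, match="duplicate"):
            simulate_cohort([p, p], seed=0)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        profiles = default_profiles(n=300)[:2]
        a = simulate_cohort(profiles, seed=5)
        b = simulate_cohort(profiles, seed=5)
        pd.testing.assert_frame_equal(a.df, b.df)
        assert a.provenance == b.provenance

    def test_same_seed_byte_identical_files(self, tmp_path):
        profiles = default_profiles(n=200)[:2]
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        s.write_cohort(simulate_cohort(profiles, seed=9), pa)
        s.write_cohort(simulate_cohort(profiles, seed=9), pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seed_differs(self):
        profiles = default_profiles(n=200)[:1]
        a = simulate_cohort(profiles, seed=1)
        b = simulate_cohort(profiles, seed=2)
        assert not a.df["height"].equals(b.df["height"])


class TestGeneratedCohort:
    @pytest.fixture(scope="class")
    def big(self):
        profiles = default_profiles(n=5000, weight_missing=False)
        return simulate_cohort(profiles, seed=23), profiles

    def test_output_is_a_valid_cohort(self, big):
        table, profiles = big
        assert len(table) == sum(p.n for p in profiles)
        assert len(table.rejects) == 0

    def test_marginal_calibration_within_3se(self, big):
        """Generated categorical prevalences match profile targets (n=5000)."""
        table, profiles = big
        for p in profiles[:4]:
            sub = table.df[table.df.site == p.site]
            n = len(sub)
            for value, target in [
                ((sub.sex == "female").mean(), p.female_prob),
                ((sub.smoking == "ever").mean(), p.smoking_ever),
                ((sub.alcohol == "moderate").mean(), p.alcohol_moderate),
                ((sub.phys_activity == "high").mean(), p.activity_high),
                (sub.dementia.mean(), p.dementia),
            ]:
                se = np.sqrt(max(target * (1 - target), 1e-4) / n)
                assert abs(value - target) <= 3 * se, (p.site, value, target)

    def test_smi_quintile_cutoffs_in_published_ranges(self, big):
        table, profiles = big
        eth = {p.site: p.ethnicity for p in profiles}
        d = s.add_derived(table.df, eth)
        cuts = s.derive_cutoffs(d, "low_smi")
        women = cuts[cuts.sex == "female"]["threshold"]
        men = cuts[cuts.sex == "male"]["threshold"]
        assert women.between(0.505, 0.585).all()
        assert men.between(0.875, 0.975).all()

    def test_gait_slows_with_age_and_quickens_with_height(self, big):
        table, _ = big
        df = table.df
        speed = 10.0 / df["walk_time_10m"]
        assert np.corrcoef(speed, df["age"])[0, 1] < -0.2
        assert np.corrcoef(speed, df["height"])[0, 1] > 0.1

    def test_derived_smi_matches_structural_linear_model(self, big):
        """The inversion reproduces the embedded linear SMI model: a per-gender
        OLS on the true covariate set recovers the default truth slopes."""
        table, profiles = big
        truth = default_truth()
        eth = {p.site: p.ethnicity for p in profiles}
        d = s.add_derived(table.df, eth)
        sub = d[d.sex == "female"]
        X = pd.DataFrame({
            "const": 1.0,
            "age": sub.age - 75.0,
            "pbf": sub.pbf - 36.0,
            "assets": sub.assets - 5.0,
        })
        for site in sorted(sub.site.unique()):
            X[f"site_{site}"] = (sub.site == site).astype(float)
        X = X.drop(columns=["const"])
        import statsmodels.api as sm
        res = sm.OLS(sub.smi.to_numpy(), sm.add_constant(X)).fit()
        assert res.params["pbf"] == pytest.approx(
            truth.smi_effects["female"]["pbf"], abs=3 * res.bse["pbf"])
        assert res.params["age"] == pytest.approx(
            truth.smi_effects["female"]["age"], abs=3 * res.bse["age"])

    def test_provenance_records_seed_and_diagnostics(self, big):
        table, _ = big
        prov = json.loads(table.provenance)
        assert prov["seed"] == 23
        assert prov["diagnostics"]["propensity_clip_fraction"] < 0.02
        assert prov["diagnostics"]["height_clamp_fraction"] < 0.001


class TestMissingness:
    def test_zero_rate_removes_nothing(self):
        prof = default_profiles(n=500, weight_missing=False)[0]
        table = simulate_cohort([prof], seed=2)
        out = apply_missingness(table, [prof], seed=3)
        assert out.df["weight"].notna().all()

    def test_rate_one_empties_one_site_only(self):
        profiles = default_profiles(n=300, weight_missing=False)[:2]
        table = simulate_cohort(profiles, seed=2)
        profiles[0].weight_missing_rate = 1.0
        out = apply_missingness(table, profiles, seed=3)
        assert out.df.loc[out.df.site == profiles[0].site, "weight"].isna().all()
        other = out.df.loc[out.df.site == profiles[1].site]
        assert other["weight"].notna().all()
        non_weight = [c for c in out.df.columns if c != "weight"]
        pd.testing.assert_frame_equal(out.df[non_weight], table.df[non_weight])

    def test_observed_missing_fraction_matches_rate(self):
        """rate 0.30, no MAR slopes, n = 10,000 -> fraction 0.30 +- 0.01."""
        prof = default_profiles(weight_missing=False)[1]
        prof.n = 10_000
        table = simulate_cohort([prof], seed=4)
        prof.weight_missing_rate = 0.30
        out = apply_missingness(table, [prof], seed=5)
        assert out.df["weight"].isna().mean() == pytest.approx(0.30, abs=0.01)

    def test_positive_age_slope_concentrates_missingness_in_old(self):
        prof = default_profiles(weight_missing=False)[1]
        prof.n = 10_000
        table = simulate_cohort([prof], seed=6)
        prof.weight_missing_rate = 0.25
        prof.mar_age_slope = 0.06
        out = apply_missingness(table, [prof], seed=7)
        df = out.df
        old = df[df.age >= 80]["weight"].isna().mean()
        young = df[df.age <= 69]["weight"].isna().mean()
        assert old > young

    def test_simulate_applies_default_missingness_sites(self):
        profiles = default_profiles(n=800)
        table = simulate_cohort(profiles, seed=8)
        frac = table.df.groupby("site")["weight"].apply(lambda x: x.isna().mean())
        assert frac["cuba"] > 0.15
        assert frac["puerto_rico"] > 0.12
        assert frac["peru_urban"] == 0.0
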