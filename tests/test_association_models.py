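import numpy as np
import pandas as pd
import pytest

import sarc1066 as s
from sarc1066.association_models import (ModelSpec, build_design, default_spec,
                                         fit_linear_smi, fit_logistic_case,
                                         fit_over_imputations)

from conftest import make_raw_frame


def _two_by_two(a, b, c, d):
    """Exposed cases a / exposed non-cases b / unexposed c / unexposed d."""
    rows = ([{"smoking": "ever"}] * (a + b) + [{"smoking": "never"}] * (c + d))
    df = make_raw_frame(rows)
    df["sarcopenia"] = ([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
    return df


class TestLogisticOracle:
    def test_single_binary_covariate_matches_cross_product_or(self):
        # OR = (20*90)/(80*10) = 2.25; SE = sqrt(1/20+1/80+1/10+1/90)
        df = _two_by_two(20, 80, 10, 90)
        spec = ModelSpec(outcome="sarcopenia", covariates=("smoking",),
                         adjustments=())
        fit = fit_logistic_case(df, "cuba", spec)
        assert fit.ok
        row = fit.params[fit.params["term"] == "smoking[ever]"]
        assert np.exp(row["estimate"].iloc[0]) == pytest.approx(2.25, rel=1e-6)
        assert row["se"].iloc[0] == pytest.approx(
            np.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90), rel=1e-6)

    def test_zero_case_level_is_separation_flagged(self):
        df = _two_by_two(0, 100, 30, 70)
        spec = ModelSpec(outcome="sarcopenia", covariates=("smoking",),
                         adjustments=())
        fit = fit_logistic_case(df, "cuba", spec)
        assert fit.flags.get("separation")
        row = fit.params[fit.params["term"] == "smoking[ever]"]
        assert np.isinf(row["se"].iloc[0])   # excluded from any pool

    def test_too_few_cases_flagged(self):
        df = _two_by_two(2, 98, 3, 97)
        spec = ModelSpec(outcome="sarcopenia", covariates=("smoking",),
                         adjustments=())
        fit = fit_logistic_case(df, "cuba", spec)
        assert not fit.ok
        assert fit.flags["insufficient_cases"]

    def test_full_spec_recovers_embedded_male_log_odds(self):
        """Parameter recovery at one site, n = 5000, truth log(2.8)."""
        prof = s.default_profiles(weight_missing=False)[3]
        prof.n = 5000
        table = s.simulate_cohort([prof], seed=19)
        d = s.add_derived(table.df, {prof.site: prof.ethnicity})
        d, _ = s.add_strata(d)
        flags = s.flag_cases(d, s.derive_all_cutoffs(d))
        fit = fit_logistic_case(flags, prof.site, default_spec("sarcopenia"))
        row = fit.params[fit.params["term"] == "sex[male]"]
        est, se = row["estimate"].iloc[0], row["se"].iloc[0]
        assert est == pytest.approx(np.log(2.8), abs=3 * se)


class TestLinearOracle:
    @pytest.fixture(scope="class")
    def site_flags(self, three_site_flags):
        return three_site_flags

    def test_ols_matches_normal_equations(self, site_flags):
        site = site_flags["site"].iloc[0]
        fit = fit_linear_smi(site_flags, site, "female")
        sub = site_flags[(site_flags.site == site) & (site_flags.sex == "female")]
        sub = sub.dropna(subset=["smi"] + [c for c in default_spec("smi").terms()])
        X = build_design(sub, default_spec("smi").terms())
        X = X[[t for t in fit.params["term"]]]
        beta = np.linalg.solve(X.T @ X, X.T @ sub["smi"].to_numpy())
        assert np.allclose(fit.params["estimate"].to_numpy(), beta, atol=1e-8)

    def test_row_duplication_keeps_coefficients_halves_variance(self, site_flags):
        site = site_flags["site"].iloc[0]
        fit1 = fit_linear_smi(site_flags, site, "male")
        doubled = pd.concat([site_flags, site_flags], ignore_index=True)
        doubled["pid"] = [f"r{i}" for i in range(len(doubled))]
        fit2 = fit_linear_smi(doubled, site, "male")
        assert np.allclose(fit1.params["estimate"], fit2.params["estimate"], atol=1e-10)
        ratio = fit2.params["se"].to_numpy() / fit1.params["se"].to_numpy()
        # exactly sqrt((n-p)/(2n-p)) with the dof correction; -> 1/sqrt(2) as n grows
        n, p = fit1.n, len(fit1.params)
        assert np.allclose(ratio, np.sqrt((n - p) / (2 * n - p)), rtol=1e-6)
        assert np.allclose(ratio, 1 / np.sqrt(2), rtol=0.05)

    def test_constant_outcome_flagged(self):
        df = make_raw_frame([{}] * 40)
        df["smi"] = 0.6
        df["pbf"] = np.random.default_rng(0).normal(40, 4, 40)
        spec = ModelSpec(outcome="smi", covariates=("age", "pbf"), adjustments=())
        fit = fit_linear_smi(df, "cuba", "female", spec)
        assert not fit.ok
        assert fit.flags["constant_outcome"]

    def test_degenerate_category_dropped_with_warning(self, site_flags):
        site = site_flags["site"].iloc[0]
        df = site_flags.copy()
        df.loc[df.site == site, "smoking"] = "never"   # empty 'ever' level
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_linear_smi(df, site, "female")
        assert "smoking[ever]" in fit.flags["dropped_terms"]
        assert "smoking[ever]" not in set(fit.params["term"])

    def test_too_small_stratum_raises(self, site_flags):
        tiny = site_flags.head(10)
        with pytest.raises(ValueError, match="complete cases"):
            fit_linear_smi(tiny, tiny["site"].iloc[0], "female")


class TestFitOverImputations:
    def test_identical_copies_equal_single_fit(self, three_site_flags):
        site = three_site_flags["site"].iloc[0]
        single = fit_linear_smi(three_site_flags, site, "female")
        pooled = fit_over_imputations([three_site_flags] * 3,
                                      fit_linear_smi, site, "female")
        assert np.allclose(pooled.params["estimate"], single.params["estimate"])
        # B = 0: pooled SE equals the within-imputation SE
        assert np.allclose(pooled.params["se"], single.params["se"], rtol=1e-9)

    def test_pooled_se_at_least_mean_within_se(self, three_site_flags):
        site = three_site_flags["site"].iloc[0]
        rng = np.random.default_rng(5)
        tables = []
        for _ in range(4):
            t = three_site_flags.copy()
            jitter = rng.normal(0, 0.002, len(t))
            t["smi"] = t["smi"] + jitter
            tables.append(t)
        pooled = fit_over_imputations(tables, fit_linear_smi, site, "female")
        singles = [fit_linear_smi(t, site, "female") for t in tables]
        mean_within = np.mean([f.params["se"].to_numpy() for f in singles], axis=0)
        assert (pooled.params["se"].to_numpy() >= mean_within - 1e-12).all()

    def test_all_failures_raise(self, three_site_flags):
        site = three_site_flags["site"].iloc[0]
        bad = three_site_flags.copy()
        bad["smi"] = 0.5
        with pytest.raises(RuntimeError, match="fewer than 2"):
            with pytest.warns(UserWarning):
                fit_over_imputations([bad, bad], fit_linear_smi, site, "female")
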