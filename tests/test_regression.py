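"""Count GLMs and Tukey contrasts: closed-form cases, an independent
statsmodels cross-check, and a numeric-integration oracle for the
studentized-range tail."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate, stats

from seedset import fit_negbin_glm, fit_poisson_glm, tukey_contrasts
from seedset.regression import contrast_table


def intercept_only(counts):
    return pd.DataFrame(
        {"treatment": ["only"] * len(counts), "seeds_produced": counts}
    )


def three_level(counts_by_level):
    rows = [
        {"treatment": lv, "seeds_produced": c}
        for lv, counts in counts_by_level.items()
        for c in counts
    ]
    return pd.DataFrame(rows)


class TestPoisson:
    def test_intercept_only_mle_is_log_mean(self):
        fit = fit_poisson_glm(intercept_only([1, 2, 3]))
        assert np.exp(fit.coefficients["Intercept"]) == pytest.approx(2.0, abs=1e-10)

    def test_intercept_only_deviance(self):
        """2 * sum[y ln(y / mu) - (y - mu)] at mu = 2 for y = 1, 2, 3."""
        y = np.array([1.0, 2.0, 3.0])
        oracle = 2.0 * np.sum(y * np.log(y / 2.0) - (y - 2.0))
        fit = fit_poisson_glm(intercept_only([1, 2, 3]))
        assert fit.residual_deviance == pytest.approx(oracle, abs=1e-10)
        assert fit.residual_deviance == pytest.approx(1.0465, abs=5e-5)

    def test_zero_counts_handled_in_deviance(self):
        fit = fit_poisson_glm(intercept_only([0, 0, 4]))
        assert np.isfinite(fit.residual_deviance)

    def test_residual_df_for_treatment_only_model(self, retained):
        sub = retained[retained.plant_id.isin(retained.plant_id.unique()[:37])]
        assert len(sub) == 111
        fit = fit_poisson_glm(sub)
        assert fit.residual_df == 108

    def test_matches_statsmodels(self, retained):
        fit = fit_poisson_glm(retained)
        X = pd.get_dummies(retained["treatment"]).astype(float)[["open", "outcrossed"]]
        X.insert(0, "const", 1.0)
        ref = sm.GLM(
            retained["seeds_produced"], X, family=sm.families.Poisson()
        ).fit()
        np.testing.assert_allclose(
            list(fit.coefficients.values()), ref.params.to_numpy(), atol=1e-8
        )
        assert fit.residual_deviance == pytest.approx(ref.deviance, abs=1e-6)
        np.testing.assert_allclose(
            list(fit.standard_errors.values()), ref.bse.to_numpy(), atol=1e-6
        )


class TestNegBin:
    def test_intercept_only_mle_is_sample_mean(self):
        counts = [3, 9, 14, 2, 41, 7, 7]
        fit = fit_negbin_glm(intercept_only(counts))
        assert np.exp(fit.coefficients["Intercept"]) == pytest.approx(
            np.mean(counts), abs=1e-8
        )

    def test_matches_statsmodels_at_fitted_theta(self, retained):
        fit = fit_negbin_glm(retained)
        X = pd.get_dummies(retained["treatment"]).astype(float)[["open", "outcrossed"]]
        X.insert(0, "const", 1.0)
        ref = sm.GLM(
            retained["seeds_produced"],
            X,
            family=sm.families.NegativeBinomial(alpha=1.0 / fit.theta),
        ).fit()
        np.testing.assert_allclose(
            list(fit.coefficients.values()), ref.params.to_numpy(), atol=1e-6
        )

    def test_poisson_limit_when_no_overdispersion(self):
        rng = np.random.default_rng(17)
        df = three_level(
            {
                "autonomous": rng.poisson(30, 60),
                "open": rng.poisson(35, 60),
                "outcrossed": rng.poisson(32, 60),
            }
        )
        nb = fit_negbin_glm(df)
        po = fit_poisson_glm(df)
        assert nb.theta == pytest.approx(1e6)
        assert any("Poisson-equivalent" in w for w in nb.warnings)
        for term in po.coefficients:
            assert nb.coefficients[term] == pytest.approx(
                po.coefficients[term], abs=1e-6
            )

    def test_loglik_beats_poisson_on_overdispersed_counts(self, retained):
        nb = fit_negbin_glm(retained)
        po = fit_poisson_glm(retained)
        assert np.isfinite(nb.log_likelihood) and np.isfinite(po.log_likelihood)
        assert nb.log_likelihood > po.log_likelihood


class TestTukey:
    @staticmethod
    def studentized_range_tail_oracle(q, k):
        """P(range of k iid N(0,1) exceeds q) by numeric integration."""
        f = lambda z: (
            k
            * stats.norm.pdf(z)
            * (stats.norm.cdf(z + q) - stats.norm.cdf(z)) ** (k - 1)
        )
        cdf, _ = integrate.quad(f, -12, 12)
        return 1.0 - cdf

    def test_p_tukey_matches_integration_oracle(self):
        oracle = self.studentized_range_tail_oracle(1.96 * np.sqrt(2.0), 3)
        got = float(stats.studentized_range.sf(1.96 * np.sqrt(2.0), 3, np.inf))
        assert got == pytest.approx(oracle, abs=1e-6)
        assert oracle == pytest.approx(0.1223, abs=5e-5)

    def test_null_contrast_and_monotonicity(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(20, 50)
        df = three_level(
            {"autonomous": base, "open": base, "outcrossed": rng.poisson(25, 50)}
        )
        fit = fit_poisson_glm(df)
        contrasts = tukey_contrasts(fit)
        by_pair = {c.pair: c for c in contrasts}
        null = by_pair[("autonomous", "open")]
        assert null.estimate == pytest.approx(0.0, abs=1e-10)
        assert null.p_tukey == pytest.approx(1.0, abs=1e-9)
        for c in contrasts:
            assert c.p_tukey >= c.p_unadjusted - 1e-12

    def test_contrast_antisymmetry_under_relabeling(self):
        """Reversing the alphabetical order of two levels flips the pair and
        negates the estimate, with identical p-values."""
        rng = np.random.default_rng(4)
        counts = {"a_lvl": rng.poisson(20, 40), "b_lvl": rng.poisson(30, 40)}
        df1 = three_level(counts)
        df2 = df1.replace({"a_lvl": "z_lvl"})
        c1 = {c.pair: c for c in tukey_contrasts(fit_poisson_glm(df1))}
        c2 = {c.pair: c for c in tukey_contrasts(fit_poisson_glm(df2))}
        fwd, rev = c1[("a_lvl", "b_lvl")], c2[("b_lvl", "z_lvl")]
        assert rev.estimate == pytest.approx(-fwd.estimate, abs=1e-8)
        assert rev.p_tukey == pytest.approx(fwd.p_tukey, abs=1e-10)
        assert rev.p_unadjusted == pytest.approx(fwd.p_unadjusted, abs=1e-10)

    def test_single_level_factor_rejected(self):
        fit = fit_poisson_glm(intercept_only([1, 2, 3]))
        with pytest.raises(ValueError, match="levels"):
            tukey_contrasts(fit)

    def test_contrast_table_shape(self, retained):
        tab = contrast_table(tukey_contrasts(fit_negbin_glm(retained)))
        assert len(tab) == 3
        assert set(tab.columns) >= {"estimate", "se", "z", "p_unadjusted", "p_tukey"}
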