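"""Interaction regression, simple slopes, and nested model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst
from scipy import stats

from wsw.inference import (
    CueRegressionModel,
    FitError,
    fit_covariate_model,
    fit_interaction_model,
    nested_model_comparison,
)

# the published coefficient pattern of the scar ~ race * sex regression,
# used as a convenient exactly-recoverable surface
B0, B_RACE, B_SEX, B_INT = -0.11, -0.32, -0.15, -0.51


def _surface_scores(n_side=9):
    """Noise-free scores lying exactly on the interaction surface."""
    race, sex = np.meshgrid(
        np.linspace(-1, 1, n_side), np.linspace(-1, 1, n_side)
    )
    race, sex = race.ravel(), sex.ravel()
    scar = B0 + B_RACE * race + B_SEX * sex + B_INT * race * sex
    return pd.DataFrame(
        {
            "participant_id": np.arange(race.size),
            "race_score": race,
            "sex_score": sex,
            "scar_score": scar,
        }
    )


def _random_scores(rng, n=200, noise=0.3):
    race = rng.normal(0, 0.5, n)
    sex = rng.normal(0.3, 0.4, n)
    scar = B0 + B_RACE * race + B_SEX * sex + B_INT * race * sex + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "race_score": race,
            "sex_score": sex,
            "scar_score": scar,
        }
    )


class TestInteractionFit:
    def test_noise_free_surface_recovered_exactly(self):
        res = fit_interaction_model(_surface_scores())
        assert res.params["Intercept"] == pytest.approx(B0, abs=1e-12)
        assert res.params["race"] == pytest.approx(B_RACE, abs=1e-12)
        assert res.params["sex"] == pytest.approx(B_SEX, abs=1e-12)
        assert res.params["race:sex"] == pytest.approx(B_INT, abs=1e-12)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_has_vanishing_r2(self):
        rng = np.random.default_rng(4)
        n = 4000
        scores = pd.DataFrame(
            {
                "race_score": rng.normal(size=n),
                "sex_score": rng.normal(size=n),
                "scar_score": rng.normal(size=n),
            }
        )
        res = fit_interaction_model(scores)
        assert res.rsquared < 0.005
        assert res.f_pvalue > 0.001

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_normal_equations_and_statsmodels(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 21))
        scores = _random_scores(rng, n=n)
        res = fit_interaction_model(scores)

        X = np.column_stack(
            [
                np.ones(n),
                scores["race_score"],
                scores["sex_score"],
                scores["race_score"] * scores["sex_score"],
            ]
        )
        y = scores["scar_score"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # explicit normal equations
        assert np.allclose(res.params.to_numpy(), beta, rtol=1e-8, atol=1e-12)

        ref = sm.OLS(y, X).fit()
        assert np.allclose(res.params.to_numpy(), ref.params, rtol=1e-8)
        assert np.allclose(res.bse.to_numpy(), ref.bse, rtol=1e-8)
        assert res.rsquared == pytest.approx(ref.rsquared, rel=1e-10)
        assert res.fvalue == pytest.approx(ref.fvalue, rel=1e-8)
        assert np.allclose(res.pvalues.to_numpy(), ref.pvalues, atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        scores = _surface_scores()
        scores["race_score"] = 0.5  # constant predictor
        with pytest.raises(FitError):
            fit_interaction_model(scores)

    def test_too_few_rows_rejected(self):
        with pytest.raises(FitError):
            fit_interaction_model(_surface_scores().head(4))

    def test_nan_rows_deleted_listwise(self):
        scores = _random_scores(np.random.default_rng(0))
        scores.loc[:9, "scar_score"] = np.nan
        res = fit_interaction_model(scores)
        assert res.nobs == len(scores) - 10
        assert res.model.n_dropped == 10


class TestSimpleSlopes:
    def test_published_moderator_values_reproduce_published_slopes(self):
        res = fit_interaction_model(_surface_scores())
        levels = {"-1 SD (Low)": -0.146, "Mean": 0.289, "+1 SD (High)": 0.724}
        out = {}
        for label, v in levels.items():
            slope, _ = res.slope_at("sex", v)
            out[label] = round(slope, 2)
        assert out == {"-1 SD (Low)": -0.25, "Mean": -0.47, "+1 SD (High)": -0.69}

    def test_slope_is_exactly_linear_in_the_moderator(self):
        res = fit_interaction_model(_random_scores(np.random.default_rng(1)))
        b1, b3 = res.params["race"], res.params["race:sex"]
        for v in (-2.0, -0.146, 0.0, 0.289, 0.724, 3.5):
            slope, se = res.slope_at("sex", v)
            assert slope == b1 + b3 * v  # exact identity
        slope0, se0 = res.slope_at("sex", 0.0)
        assert slope0 == b1 and se0 == pytest.approx(res.bse["race"], rel=1e-15)

    def test_delta_method_se(self):
        res = fit_interaction_model(_random_scores(np.random.default_rng(2)))
        v = 0.7
        _, se = res.slope_at("sex", v)
        C = res.cov_params
        expected = np.sqrt(
            C.loc["race", "race"]
            + v**2 * C.loc["race:sex", "race:sex"]
            + 2 * v * C.loc["race", "race:sex"]
        )
        assert se == pytest.approx(expected, rel=1e-12)

    def test_default_levels_are_mean_plus_minus_sd(self):
        scores = _random_scores(np.random.default_rng(3))
        res = fit_interaction_model(scores)
        levels = res.moderator_levels("sex")
        m = scores["sex_score"].mean()
        s = scores["sex_score"].std(ddof=1)
        assert levels["Mean"] == pytest.approx(m)
        assert levels["-1 SD (Low)"] == pytest.approx(m - s)
        assert levels["+1 SD (High)"] == pytest.approx(m + s)

    @given(
        hst.floats(-2, 2), hst.floats(-2, 2), hst.integers(0, 50)
    )
    def test_contrast_t_equals_interaction_t(self, a, b, seed):
        if abs(a - b) < 1e-6:
            return
        res = fit_interaction_model(_random_scores(np.random.default_rng(seed), n=60))
        c = res.slope_contrast("sex", a, b)
        assert c.estimate == pytest.approx(res.params["race:sex"] * (b - a), rel=1e-12)
        assert abs(c.t) == pytest.approx(abs(res.tvalues["race:sex"]), rel=1e-9)

    def test_swapped_levels_flip_sign_only(self):
        res = fit_interaction_model(_random_scores(np.random.default_rng(5)))
        c1 = res.slope_contrast("sex", -0.146, 0.289)
        c2 = res.slope_contrast("sex", 0.289, -0.146)
        assert c1.estimate == -c2.estimate
        assert c1.se == c2.se and abs(c1.t) == abs(c2.t)

    def test_equal_levels_rejected(self):
        res = fit_interaction_model(_random_scores(np.random.default_rng(6)))
        with pytest.raises(FitError):
            res.slope_contrast("sex", 0.3, 0.3)

    def test_unknown_moderator_rejected(self):
        res = fit_interaction_model(_random_scores(np.random.default_rng(7)))
        with pytest.raises(FitError):
            res.simple_slopes("scar")


class TestNestedComparison:
    def test_model_compared_with_itself_is_null(self):
        res = fit_interaction_model(_random_scores(np.random.default_rng(8)))
        cmp = nested_model_comparison(res, res)
        assert cmp.delta_r2 == 0.0 and cmp.delta_f == 0.0 and cmp.p == 1.0

    def test_matches_rss_based_brute_force(self):
        rng = np.random.default_rng(9)
        scores = _random_scores(rng, n=80)
        scores["extra"] = rng.normal(size=80)
        full = CueRegressionModel(scores, extra_terms=["extra"]).fit()
        red = fit_interaction_model(scores)
        cmp = nested_model_comparison(full, red)

        # independent route: residual sums of squares
        def rss(res):
            X, y = res.model.exog, res.model.endog
            b = np.linalg.lstsq(X, y, rcond=None)[0]
            return float(((y - X @ b) ** 2).sum())

        q = 1
        df_full = full.df_resid
        expected_f = ((rss(red) - rss(full)) / q) / (rss(full) / df_full)
        assert cmp.delta_f == pytest.approx(expected_f, rel=1e-9)
        assert cmp.p == pytest.approx(stats.f.sf(expected_f, q, df_full), rel=1e-9)
        assert cmp.delta_r2 == pytest.approx(full.rsquared - red.rsquared, rel=1e-12)

    def test_noise_covariates_follow_null_f_distribution(self):
        """Incremental F for q junk covariates ~ F(q, df) under the null."""
        rng = np.random.default_rng(10)
        q, n, reps = 2, 120, 300
        fstats = []
        for _ in range(reps):
            scores = _random_scores(rng, n=n)
            scores["z1"] = rng.normal(size=n)
            scores["z2"] = rng.normal(size=n)
            full = CueRegressionModel(scores, extra_terms=["z1", "z2"]).fit()
            red = fit_interaction_model(scores)
            fstats.append(nested_model_comparison(full, red).delta_f)
        ks = stats.kstest(fstats, stats.f(q, n - 6).cdf)
        assert ks.pvalue > 0.01

    def test_non_nested_models_rejected(self):
        scores = _random_scores(np.random.default_rng(11))
        full = fit_interaction_model(scores)
        other = fit_interaction_model(scores, "race", ("scar", "sex"))
        with pytest.raises(FitError):
            nested_model_comparison(full, other)


class TestCovariateModel:
    def _covariates(self, rng, n):
        return pd.DataFrame(
            {
                "participant_id": np.arange(n),
                "exposure_frequency": rng.integers(1, 6, n),
                "acquaintance": rng.choice(["none", "family", "coworker"], n),
                "self_scar": rng.integers(0, 2, n),
                "age": rng.integers(18, 66, n),
            }
        )

    def test_constant_categorical_covariate_changes_nothing(self):
        rng = np.random.default_rng(12)
        scores = _random_scores(rng)
        cov = self._covariates(rng, len(scores))
        cov["acquaintance"] = "none"
        full = fit_covariate_model(scores, cov, extra_terms=["acquaintance"])
        base = fit_interaction_model(scores)
        assert np.allclose(full.params.to_numpy(), base.params.to_numpy())
        assert full.rsquared == pytest.approx(base.rsquared)

    def test_planted_covariate_effect_recovered(self):
        rng = np.random.default_rng(13)
        scores = _random_scores(rng, n=500)
        cov = self._covariates(rng, 500)
        beta = -0.08
        scores["scar_score"] += beta * cov["exposure_frequency"].to_numpy()
        res = fit_covariate_model(scores, cov, extra_terms=["exposure_frequency"])
        b = res.params["exposure_frequency"]
        se = res.bse["exposure_frequency"]
        assert b - 2 * se < beta < b + 2 * se

    def test_categorical_dummy_coding_against_mode(self):
        rng = np.random.default_rng(14)
        scores = _random_scores(rng, n=300)
        cov = self._covariates(rng, 300)
        res = fit_covariate_model(scores, cov, extra_terms=["acquaintance"])
        mode = cov["acquaintance"].mode().iloc[0]
        assert f"acquaintance_{mode}" not in res.params.index
        others = {f"acquaintance_{v}" for v in set(cov["acquaintance"]) - {mode}}
        assert others <= set(res.params.index)

    def test_age_by_exposure_interaction_null_p_uniform(self):
        rng = np.random.default_rng(15)
        pvals = []
        for _ in range(200):
            n = 150
            scores = _random_scores(rng, n=n)
            cov = self._covariates(rng, n)
            res = fit_covariate_model(
                scores,
                cov,
                extra_terms=["age", "exposure_frequency", "age:exposure_frequency"],
            )
            pvals.append(res.pvalues["age:exposure_frequency"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_subset_restricts_rows(self):
        rng = np.random.default_rng(16)
        scores = _random_scores(rng, n=400)
        cov = self._covariates(rng, 400)
        merged_ages = cov.set_index("participant_id")["age"]
        scores["age"] = merged_ages.loc[scores["participant_id"]].to_numpy()
        res = fit_covariate_model(
            scores, cov[["participant_id", "exposure_frequency"]],
            extra_terms=["exposure_frequency"], subset=scores["age"] >= 30,
        )
        assert res.nobs == int((scores["age"] >= 30).sum())

    def test_missing_participant_id_rejected(self):
        scores = _random_scores(np.random.default_rng(17))
        with pytest.raises(FitError):
            fit_covariate_model(scores, pd.DataFrame({"age": [1, 2]}))
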