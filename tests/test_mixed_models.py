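"""REML LMM, Laplace GLMM, repeatability and permutation inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.special import expit

from paceline.glmm import BinomialLogitMixedModel, SeparationError
from paceline.inference import (
    ModelSpec,
    association_models,
    permutation_pvalue_fixed_effect,
    repeatability,
)
from paceline.lmm import LinearMixedModel, SingularDesignError


def _one_factor_data(seed=0, n_ind=100, per=3, sd_u=0.7, slope=0.5):
    rng = np.random.default_rng(seed)
    ind = np.repeat(np.arange(n_ind), per)
    x = rng.normal(size=n_ind * per)
    u = rng.normal(0, sd_u, n_ind)
    y = 1.0 + slope * x + u[ind] + rng.normal(size=n_ind * per)
    return pd.DataFrame(dict(y=y, x=x, ind=ind))


class TestLinearMixedModel:
    def test_matches_statsmodels_single_factor(self):
        df = _one_factor_data()
        ours = LinearMixedModel.from_dataframe(df, "y", ["x"], ["ind"]).fit()
        ref = smf.mixedlm("y ~ x", df, groups=df["ind"]).fit(reml=True)
        assert ours.params == pytest.approx(np.asarray(ref.params)[:2], abs=1e-5)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-5)
        assert ours.vc["ind"] == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-4)
        assert ours.sigma2_resid == pytest.approx(ref.scale, abs=1e-4)

    def test_matches_statsmodels_crossed(self):
        rng = np.random.default_rng(3)
        df = _one_factor_data(seed=3)
        df["test"] = np.tile(np.arange(3), 100)
        df["y"] = df["y"] + rng.normal(0, 0.5, 3)[df["test"]]
        ours = LinearMixedModel.from_dataframe(df, "y", ["x"], ["ind", "test"]).fit()
        df["g"] = 1
        ref = smf.mixedlm("y ~ x", df, groups="g",
                          vc_formula={"ind": "0+C(ind)", "test": "0+C(test)"}).fit(reml=True)
        assert ours.params == pytest.approx(np.asarray(ref.params)[:2], abs=1e-4)
        assert sorted(ours.vc.values()) == pytest.approx(sorted(ref.vcomp), abs=1e-3)

    def test_balanced_anova_variance_components(self):
        df = _one_factor_data(seed=5)
        fit = LinearMixedModel.from_dataframe(df, "y", [], ["ind"]).fit()
        k = 3
        msb = k * df.groupby("ind")["y"].mean().var(ddof=1)
        msw = df.groupby("ind")["y"].var(ddof=1).mean()
        assert fit.vc["ind"] == pytest.approx((msb - msw) / k, abs=1e-6)
        assert fit.sigma2_resid == pytest.approx(msw, abs=1e-6)

    def test_zero_variance_reduces_to_ols(self):
        rng = np.random.default_rng(11)
        n = 1500
        df = pd.DataFrame(dict(
            x=rng.normal(size=n),
            ind=np.repeat(np.arange(n // 3), 3),
        ))
        df["y"] = 0.3 * df["x"] + rng.normal(size=n)  # no group effect
        model = LinearMixedModel.from_dataframe(df, "y", ["x"], ["ind"])
        fit = model.fit()
        assert fit.vc["ind"] < 0.02
        # at tau exactly 0, GLS equals OLS to numerical precision
        _, beta0, _, _ = model._profile(np.array([0.0]))
        X = np.column_stack([np.ones(n), df["x"]])
        ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert beta0 == pytest.approx(ols, abs=1e-10)

    def test_slope_recovery_over_replicates(self):
        est = []
        for rep in range(150):
            df = _one_factor_data(seed=1000 + rep, n_ind=250, per=2)
            est.append(LinearMixedModel.from_dataframe(df, "y", ["x"], ["ind"]).fit().params[1])
        assert np.mean(est) == pytest.approx(0.5, abs=0.05)

    def test_singular_design_names_columns(self):
        df = _one_factor_data()
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(SingularDesignError, match="x"):
            LinearMixedModel.from_dataframe(df, "y", ["x", "x2"], ["ind"])

    def test_blup_shrinks_group_means(self):
        df = _one_factor_data(seed=21)
        fit = LinearMixedModel.from_dataframe(df, "y", ["x"], ["ind"]).fit()
        u = fit.random_effects()[0]
        raw = df.assign(r=df["y"] - fit.fittedvalues).groupby("ind")["r"].mean()
        assert np.all(np.abs(u) <= np.abs(raw.to_numpy()) + 1e-9)
        assert np.corrcoef(u, raw)[0, 1] > 0.95


class TestBinomialGLMM:
    def test_zero_variance_matches_logistic_regression(self):
        rng = np.random.default_rng(1)
        n = 600
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.5 + x)).astype(float)
        df = pd.DataFrame(dict(y=y, x=x, ind=np.repeat(np.arange(n // 2), 2)))
        model = BinomialLogitMixedModel.from_dataframe(df, "y", ["x"], ["ind"])
        fit = model.fit(log_sigma_bounds=(-8.0, -7.999))  # pin sigma ~ 0
        ref = sm.GLM(y, np.column_stack([np.ones(n), x]),
                     family=sm.families.Binomial()).fit()
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert fit.params == pytest.approx(np.asarray(ref.params), abs=1e-4)

    def test_parameter_recovery_over_replicates(self):
        est = []
        rng = np.random.default_rng(17)
        for _ in range(100):
            n_groups, per = 250, 4
            n = n_groups * per
            ind = np.repeat(np.arange(n_groups), per)
            x = rng.normal(size=n)
            u = rng.normal(0, 1.0, n_groups)
            y = (rng.random(n) < expit(-0.5 + 1.0 * x + u[ind])).astype(float)
            df = pd.DataFrame(dict(y=y, x=x, ind=ind))
            fit = BinomialLogitMixedModel.from_dataframe(df, "y", ["x"], ["ind"]).fit()
            est.append(fit.params)
        mean = np.mean(est, axis=0)
        assert mean[0] == pytest.approx(-0.5, abs=0.15)
        assert mean[1] == pytest.approx(1.0, abs=0.15)

    def test_extreme_group_split_large_variance(self):
        # half the groups all successes, half all failures -> huge sigma,
        # intercept near 0
        n_groups, per = 40, 6
        ind = np.repeat(np.arange(n_groups), per)
        y = np.repeat([1.0, 0.0], n_groups // 2 * per)
        df = pd.DataFrame(dict(y=y, ind=ind))
        fit = BinomialLogitMixedModel.from_dataframe(df, "y", [], ["ind"]).fit()
        assert fit.vc["ind"] > 4.0
        assert abs(fit.params[0]) < 1.0

    def test_separation_raises_naming_covariate(self):
        n = 200
        x = np.linspace(-2, 2, n)
        y = (x > 0).astype(float)
        df = pd.DataFrame(dict(y=y, x=x, ind=np.repeat(np.arange(n // 2), 2)))
        with pytest.raises(SeparationError, match="x"):
            BinomialLogitMixedModel.from_dataframe(df, "y", ["x"], ["ind"]).fit()

    def test_requires_binary_response(self):
        df = pd.DataFrame(dict(y=[0.0, 0.5, 1.0, 1.0], ind=[0, 0, 1, 1]))
        with pytest.raises(ValueError):
            BinomialLogitMixedModel.from_dataframe(df, "y", [], ["ind"])


class TestRepeatability:
    def test_perfect_duplication_gives_r_near_one(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=30)
        df = pd.DataFrame(dict(y=np.repeat(vals, 2),
                               individual_id=np.repeat(np.arange(30), 2)))
        res = repeatability(ModelSpec(response="y"), df, n_perm=99, n_boot=30, seed=1)
        assert res.R > 0.99
        assert res.p_perm <= 2.0 / 100.0

    def test_iid_data_gives_r_near_zero(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(dict(y=rng.normal(size=120),
                               individual_id=np.repeat(np.arange(60), 2)))
        res = repeatability(ModelSpec(response="y"), df, n_perm=99, n_boot=30, seed=2)
        assert res.R < 0.2
        assert 0.0 < res.p_perm <= 1.0

    def test_binomial_latent_scale(self):
        rng = np.random.default_rng(12)
        n_ind = 120
        ind = np.repeat(np.arange(n_ind), 3)
        u = rng.normal(0, 2.0, n_ind)
        y = (rng.random(3 * n_ind) < expit(0.3 + u[ind])).astype(float)
        df = pd.DataFrame(dict(y=y, individual_id=ind))
        res = repeatability(ModelSpec(response="y", family="binomial-logit"), df,
                            n_perm=49, n_boot=20, seed=3)
        assert res.scale == "latent"
        # true latent R = 4 / (4 + pi^2/3) ~ 0.55
        assert res.R == pytest.approx(0.55, abs=0.25)

    def test_singletons_rejected(self):
        df = pd.DataFrame(dict(y=[1.0, 2.0, 3.0], individual_id=[0, 1, 2]))
        with pytest.raises(ValueError, match="undefined"):
            repeatability(ModelSpec(response="y"), df, n_perm=10, n_boot=5)


class TestFixedEffectPermutation:
    def test_deterministic_response_gives_minimal_p(self):
        df = pd.DataFrame(dict(
            x=np.linspace(-1, 1, 60),
            individual_id=np.repeat(np.arange(30), 2),
        ))
        df["y"] = 2.0 * df["x"]
        spec = ModelSpec(response="y", fixed_terms=["x"])
        p = permutation_pvalue_fixed_effect(spec, df, "x", n_perm=199, seed=5)
        assert p == pytest.approx(1.0 / 200.0)

    def test_absent_term_rejected(self):
        df = _one_factor_data().rename(columns={"ind": "individual_id"})
        spec = ModelSpec(response="y", fixed_terms=["x"])
        with pytest.raises(ValueError):
            permutation_pvalue_fixed_effect(spec, df, "zzz", n_perm=100)

    def test_low_count_warns(self):
        df = _one_factor_data(n_ind=20, per=2).rename(columns={"ind": "individual_id"})
        spec = ModelSpec(response="y", fixed_terms=["x"])
        with pytest.warns(UserWarning):
            permutation_pvalue_fixed_effect(spec, df, "x", n_perm=50, seed=6)


def test_association_models_shape(small_analysis):
    table = association_models(small_analysis, n_perm=100, seed=0)
    assert len(table) == 9
    assert set(table["behaviour"]) == {"entry", "distance", "exploration"}
    assert set(table["response"]) == {"rmr", "stress_max", "stress_integral"}
    assert table[["beta", "se", "p_perm"]].notna().all().all()
    assert ((table["p_perm"] > 0) & (table["p_perm"] <= 1)).all()
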