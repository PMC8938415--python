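"""Mixed-model fits: OLS collapse, marginal R2, AIC comparison guards."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

import meltflux as mf
from meltflux.lmm import mixed_loglik

from conftest import make_tables


def _tables_from_frame(df, response="gpp"):
    """Wrap a site/year/x/y frame into anomaly + melt tables for fit_lmm."""
    monthly = pd.DataFrame({
        "site_id": df["site_id"], "year": df["year"], "month": 6,
        "variable": response, "anomaly": df["y"], "n_weeks_used": 4})
    melt = pd.DataFrame({"site_id": df["site_id"], "year": df["year"],
                         "melt_anomaly": df["x"]})
    return monthly, melt


def _simulate(n_sites=6, ny=10, site_sd=0.0, beta=0.4, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        offset = rng.normal(0, site_sd)
        for y in range(ny):
            x = rng.standard_normal()
            rows.append(dict(site_id=f"s{s}", year=2000 + y, x=x,
                             y=beta * x + offset + rng.normal(0, noise)))
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_zero_site_effect_collapses_to_ols(self):
        df = _simulate(site_sd=0.0, seed=1)
        monthly, melt = _tables_from_frame(df)
        res = mf.fit_lmm(monthly, melt, "gpp", 6)
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert res.beta["melt_anomaly"] == pytest.approx(ols.params["x"],
                                                         abs=1e-6)
        assert res.singular  # zero random variance is flagged, not fatal

    def test_one_site_equals_simple_regression(self):
        df = _simulate(n_sites=1, ny=30, site_sd=0.0, seed=2)
        monthly, melt = _tables_from_frame(df)
        res = mf.fit_lmm(monthly, melt, "gpp", 6)
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert res.beta["melt_anomaly"] == pytest.approx(ols.params["x"],
                                                         abs=1e-8)

    def test_site_offsets_recovered_in_variance(self):
        df = _simulate(n_sites=10, ny=15, site_sd=2.0, beta=0.0, seed=3)
        monthly, melt = _tables_from_frame(df)
        res = mf.fit_lmm(monthly, melt, "gpp", 6)
        assert not res.singular
        assert res.var_random > 1.0          # true tau^2 = 4

    def test_loglik_matches_closed_form_reference(self):
        """Fitted llf equals the compound-symmetry MVN closed form."""
        df = _simulate(n_sites=5, ny=8, site_sd=1.0, seed=4)
        for reml in (False, True):
            fit = smf.mixedlm("y ~ x", df, groups=df["site_id"]).fit(reml=reml)
            X = np.column_stack([np.ones(len(df)), df["x"]])
            ours = mixed_loglik(df["y"].to_numpy(), X,
                                df["site_id"].to_numpy(),
                                fit.fe_params.to_numpy(),
                                float(np.asarray(fit.cov_re)[0, 0]),
                                float(fit.scale), reml=reml)
            assert ours == pytest.approx(fit.llf, abs=1e-6)

    def test_response_equal_predictor_r2_near_one(self):
        df = _simulate(seed=5)
        df["y"] = df["x"]
        monthly, melt = _tables_from_frame(df)
        res = mf.fit_lmm(monthly, melt, "gpp", 6)
        assert res.r2_marginal > 0.999
        assert res.var_resid < 1e-6

    def test_pipeline_fit_detects_coupling(self, balanced_world):
        _, _, _, _, monthly, melt = balanced_world
        res = mf.fit_lmm(monthly, melt, "gpp", 6)
        assert res.beta["melt_anomaly"] < 0
        assert res.p_fixed["melt_anomaly"] < 0.001
        assert 0 < res.r2_marginal < 1


class TestMarginalR2:
    def test_forced_arithmetic(self):
        assert mf.marginal_r2(2.0, 1.0, 1.0) == 0.5

    def test_no_fixed_variance_gives_zero(self):
        assert mf.marginal_r2(0.0, 1.0, 1.0) == 0.0

    def test_pure_fixed_gives_one(self):
        assert mf.marginal_r2(3.0, 0.0, 0.0) == 1.0

    def test_all_zero_flagged_undefined(self):
        assert np.isnan(mf.marginal_r2(0.0, 0.0, 0.0))

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            mf.marginal_r2(-1.0, 1.0, 1.0)

    def test_invariant_to_response_rescaling(self):
        df = _simulate(site_sd=1.0, seed=6)
        monthly, melt = _tables_from_frame(df)
        r2 = mf.fit_lmm(monthly, melt, "gpp", 6).r2_marginal
        df2 = df.assign(y=df["y"] * 7.5)
        monthly2, melt2 = _tables_from_frame(df2)
        r2_scaled = mf.fit_lmm(monthly2, melt2, "gpp", 6).r2_marginal
        assert r2_scaled == pytest.approx(r2, abs=1e-5)


class TestCompareModels:
    def _two_fits(self, seed=0, reml=False):
        df = _simulate(n_sites=6, ny=12, site_sd=1.0, beta=0.5, seed=seed)
        monthly, melt = _tables_from_frame(df)
        # second model adds a pure-noise fixed term
        rng = np.random.default_rng(seed + 1000)
        extra = monthly.copy()
        extra = pd.concat([extra, extra.assign(
            variable="junk", anomaly=rng.standard_normal(len(extra)))],
            ignore_index=True)
        small = mf.fit_lmm(extra, melt, "gpp", 6, reml=reml)
        big = mf.fit_lmm(extra, melt, "gpp", 6, reml=reml,
                         extra_fixed=["junk"])
        return small, big

    def test_duplicate_model_delta_zero(self):
        small, _ = self._two_fits()
        table = mf.compare_models([small, small])
        assert (table["delta_aic"] == 0).all()

    def test_reml_fits_rejected(self):
        small, big = self._two_fits(reml=True)
        with pytest.raises(ValueError, match="REML"):
            mf.compare_models([small, big])

    def test_mismatched_case_sets_rejected(self):
        df = _simulate(seed=7)
        monthly, melt = _tables_from_frame(df)
        a = mf.fit_lmm(monthly, melt, "gpp", 6, reml=False)
        b = mf.fit_lmm(monthly.iloc[:-5], melt, "gpp", 6, reml=False)
        with pytest.raises(ValueError, match="different complete-case"):
            mf.compare_models([a, b])

    def test_aic_prefers_true_smaller_model(self):
        """With a pure-noise extra term, AIC picks the smaller model at the
        textbook ~84% rate; require a clear majority over 40 replicates."""
        wins = 0
        for seed in range(40):
            small, big = self._two_fits(seed=seed)
            table = mf.compare_models([small, big])
            wins += table.iloc[0]["fixed"] == "melt_anomaly"
        assert wins >= 28          # 70% of 40

    def test_ml_deviance_never_increases_with_true_effect(self):
        for seed in range(5):
            df = _simulate(site_sd=1.0, beta=0.8, seed=seed)
            monthly, melt = _tables_from_frame(df)
            rng = np.random.default_rng(seed)
            with_x = mf.fit_lmm(monthly, melt, "gpp", 6, reml=False)
            null_melt = melt.assign(melt_anomaly=0.0)
            # intercept-only comparison via a zeroed predictor
            without = mf.fit_lmm(monthly, null_melt.assign(
                melt_anomaly=rng.normal(0, 1e-12, len(null_melt))),
                "gpp", 6, reml=False)
            assert with_x.llf >= without.llf - 1e-6
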