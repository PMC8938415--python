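"""Generator contracts: determinism, flux identities, known couplings."""

import numpy as np
import pandas as pd
import pytest

import meltflux as mf
from meltflux.errors import ConfigError
from meltflux.synth import ANOMALY_VARS

from conftest import NULL_COUPLING, NULL_CONTROLS


class TestGenerateWorld:
    def test_deterministic_for_fixed_seed(self, default_config):
        r1, m1 = mf.generate_world(default_config)
        r2, m2 = mf.generate_world(default_config)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_different_seeds_differ(self, default_config):
        r1, _ = mf.generate_world(default_config)
        r2, _ = mf.generate_world(default_config.replace(seed=43))
        assert not r1["gpp"].equals(r2["gpp"])

    def test_cohort_structure(self, default_config, default_world):
        records, snowmelt = default_world[:2]
        assert snowmelt.shape == (sum(default_config.years_per_site), 3)
        assert records["site_id"].nunique() == default_config.n_sites
        spans = snowmelt.groupby("site_id")["year"].count()
        assert sorted(spans) == sorted(default_config.years_per_site)

    def test_nee_identity_exact_before_missingness(self, default_config):
        records, _ = mf.generate_world(default_config.replace(missing_rate=0.0))
        assert np.array_equal(records["nee"].to_numpy(),
                              (records["er"] - records["gpp"]).to_numpy())

    def test_physical_bounds(self, default_world):
        records = default_world[0]
        for col in ("gpp", "er", "et", "precip", "vpd"):
            assert (records[col].dropna() >= 0).all()
        assert records["week"].between(1, 52).all()
        melt = default_world[1]
        assert melt["melt_doy"].between(60, 220).all()

    def test_null_noise_collapses_to_climatology(self):
        cfg = mf.GeneratorConfig(
            n_sites=3, years_per_site=[6, 6, 6],
            coupling=NULL_COUPLING, control_coupling=NULL_CONTROLS,
            noise_sd={v: 1e-9 for v in ANOMALY_VARS}, missing_rate=0.0)
        records, _ = mf.generate_world(cfg)
        spread = records.groupby(["site_id", "week"])["gpp"].std(ddof=0)
        assert spread.max() < 1e-6

    @pytest.mark.parametrize("field,value", [
        ("n_sites", 1),
        ("years_per_site", [2] * 11),
        ("missing_rate", 1.0),
        ("melt_spatial_corr", 1.0),
        ("snowmelt_sd_doy", 0.0),
    ])
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigError):
            mf.GeneratorConfig(**{field: value})

    def test_coupling_restricted_to_summer(self):
        with pytest.raises(ConfigError, match="June-August"):
            mf.GeneratorConfig(coupling={5: {"gpp": 0.1}})


class TestMissingness:
    def test_rate_zero_is_identity(self, default_config):
        records, _ = mf.generate_world(default_config.replace(missing_rate=0.0))
        out = mf.apply_missingness(records, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, records)

    def test_keys_never_removed_and_binomial_count(self, default_config):
        records, _ = mf.generate_world(default_config.replace(missing_rate=0.0))
        out = mf.apply_missingness(records, 0.3, seed=7)
        assert len(out) == len(records)
        assert out["site_id"].notna().all()
        n_vals = records.shape[0] * 11        # 11 value columns
        n_missing = int(out.isna().sum().sum() - records.isna().sum().sum())
        # 99% binomial interval around rate * n
        sd = np.sqrt(n_vals * 0.3 * 0.7)
        assert abs(n_missing - 0.3 * n_vals) < 2.58 * sd

    def test_mask_deterministic(self, default_config):
        records, _ = mf.generate_world(default_config.replace(missing_rate=0.0))
        a = mf.apply_missingness(records, 0.2, seed=5)
        b = mf.apply_missingness(records, 0.2, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_rate_rejected(self, default_world):
        with pytest.raises(ConfigError):
            mf.apply_missingness(default_world[0], 1.2, seed=0)

    def test_block_missingness_strikes_in_runs(self, default_config):
        records, _ = mf.generate_world(default_config.replace(missing_rate=0.0))
        out = mf.apply_missingness(records, 0.2, seed=3, block_length=8)
        gone = out["gpp"].isna().to_numpy()
        # overall rate preserved and runs are long: far fewer distinct
        # missing runs than missing values
        assert 0.1 < gone.mean() < 0.3
        starts = int((gone[1:] & ~gone[:-1]).sum()) + int(gone[0])
        assert starts < gone.sum() / 3


class TestPopulationPartialCorrelation:
    def test_zero_coupling_gives_zero(self):
        cfg = mf.GeneratorConfig(coupling=NULL_COUPLING)
        assert mf.population_partial_correlation(cfg, 6, "gpp") == 0.0

    def test_beta_equal_noise_gives_inverse_sqrt2(self):
        cfg = mf.GeneratorConfig(coupling={6: {"gpp": 0.8}},
                                 noise_sd={v: 0.8 for v in ANOMALY_VARS})
        r = mf.population_partial_correlation(cfg, 6, "gpp")
        assert r == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_matches_monte_carlo_oracle(self, default_config):
        # brute-force simulation of the weekly generative model at n = 1e6
        cfg = default_config
        rng = np.random.default_rng(123)
        n = 1_000_000
        beta = cfg.coupling[6]["gpp"]
        cc = cfg.control_coupling["gpp"]
        z = rng.standard_normal(n)
        controls = rng.standard_normal((n, 2))
        y = (beta * z + cc["rg"] * controls[:, 0] + cc["air_t"] * controls[:, 1]
             + rng.normal(0, cfg.noise_sd["gpp"], n))
        r_mc, _, _ = mf.partial_correlation(z, y, controls)
        r_closed = mf.population_partial_correlation(cfg, 6, "gpp")
        assert r_closed == pytest.approx(r_mc, abs=0.01)

    def test_nee_propagation_sign_pattern(self, default_config):
        # early season: later melt -> less uptake (positive); late: reversed
        assert mf.population_partial_correlation(default_config, 6, "nee") > 0
        assert mf.population_partial_correlation(default_config, 7, "nee") > 0
        assert mf.population_partial_correlation(default_config, 8, "nee") < 0

    def test_month_without_coupling_rejected(self):
        cfg = mf.GeneratorConfig(coupling={6: {"gpp": 0.2}})
        with pytest.raises(ConfigError):
            mf.population_partial_correlation(cfg, 7, "gpp")

    def test_sample_signs_follow_couplings(self, balanced_world, balanced_config):
        _, _, _, _, monthly, melt = balanced_world
        for month in (6, 8):
            res = mf.monthly_partial_correlations(monthly, melt, ["gpp"], month)
            pop = mf.population_partial_correlation(balanced_config, month, "gpp")
            assert np.sign(res[0].r) == np.sign(pop)
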