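"""Shared fixtures: small synthetic worlds and their derived anomaly tables."""

import warnings

import pytest

import meltflux as mf

# statsmodels emits boundary-fit warnings on anomaly data whose site effects
# are (by construction) near zero; the package flags these fits instead
warnings.filterwarnings("ignore", module="statsmodels")

NULL_COUPLING = {m: {v: 0.0 for v in ("gpp", "er", "et", "soil_moisture", "vpd")}
                 for m in (6, 7, 8)}
NULL_CONTROLS = {v: {"rg": 0.0, "air_t": 0.0}
                 for v in ("gpp", "er", "et", "soil_moisture", "vpd")}


def make_tables(config):
    """Run generator -> climatology -> monthly anomalies -> melt anomalies."""
    records, snowmelt = mf.generate_world(config)
    clim = mf.build_climatology(records)
    weekly = mf.weekly_standardized_anomalies(records, clim)
    monthly = mf.monthly_median_anomalies(weekly)
    melt = mf.snowmelt_anomalies(snowmelt)
    return records, snowmelt, clim, weekly, monthly, melt


@pytest.fixture(scope="session")
def default_config():
    return mf.GeneratorConfig()


@pytest.fixture(scope="session")
def balanced_config():
    """11 sites x 16 years, full 2004-2019 coverage."""
    return mf.GeneratorConfig(n_sites=11, years_per_site=[16] * 11)


@pytest.fixture(scope="session")
def default_world(default_config):
    return make_tables(default_config)


@pytest.fixture(scope="session")
def balanced_world(balanced_config):
    return make_tables(balanced_config)


@pytest.fixture(scope="session")
def complete_world():
    """No missingness: for exactness properties (identities, dense oracles)."""
    cfg = mf.GeneratorConfig(n_sites=11, years_per_site=[16] * 11,
                             missing_rate=0.0)
    return make_tables(cfg)
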