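"""Synthetic multi-site eddy-covariance world generator.

Generates weekly gap-filled flux and meteorology records for a network of
Arctic tundra towers with a *known*, month-dependent statistical coupling
between snowmelt timing and the summer carbon/water fluxes.  Because every
coupling coefficient is a configuration knob, the generator doubles as the
oracle for the downstream anomaly, partial-correlation, MCA and mixed-model
stages: the population value of each association is available in closed form
(:func:`population_partial_correlation`).

Generative model
----------------
For site *s*, year *y*, week *w* (midpoint month *m*):

* snowmelt anomaly  ``z_sy = sqrt(rho) * g_y + sqrt(1-rho) * e_sy`` with
  ``g_y`` a regional year effect shared by all sites and ``e_sy``
  site-specific, both standard normal; ``rho`` is the spatial correlation of
  snowmelt timing (regionally synchronised melt).  The melt date is
  ``melt_doy = mean_s + sd * z_sy``.
* weather anomalies ``r_swy`` (shortwave) and ``t_swy`` (air temperature),
  independent standard normals entering both the met columns and the fluxes.
* each flux variable *v* gets a standardized weekly anomaly

  ``a = beta[m][v] * z_sy + c_rg[v] * r + c_ta[v] * t + eps``,
  ``eps ~ N(0, noise_sd[v])``,

  where ``beta[m][v]`` is nonzero only in June-August (the coupling applies
  to the same summer only; no carry-over between years).
* raw values are ``climatology(s, w) + scale[v] * a`` with physically
  motivated seasonal climatologies, clipped to physical bounds
  (GPP, ER, ET, VPD, precipitation nonnegative; soil moisture in (0, 1)).
* NEE is derived exactly as ``NEE = ER - GPP`` (negative = uptake); its
  noise is whatever propagates from the GPP and ER noise draws.

All randomness flows from the single ``seed`` in :class:`GeneratorConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .weeks import SUMMER_MONTHS, WEEKS_PER_YEAR, month_of_week, normalize_month

__all__ = [
    "GeneratorConfig",
    "generate_world",
    "apply_missingness",
    "population_partial_correlation",
    "write_weekly_csv",
    "write_snowmelt_csv",
]

#: variables that receive a generated standardized anomaly
ANOMALY_VARS = ("gpp", "er", "et", "soil_moisture", "vpd")

#: canonical weekly record columns, in output order
RECORD_COLUMNS = [
    "site_id", "year", "week",
    "nee", "gpp", "er", "et", "h", "le",
    "air_t", "rg", "vpd", "soil_moisture", "precip",
]

#: header names of the flux CSV dialect (canonical -> file column)
CSV_HEADER = {
    "site_id": "site_id", "year": "year", "week": "week",
    "nee": "NEE", "gpp": "GPP", "er": "ER", "et": "ET", "h": "H", "le": "LE",
    "air_t": "TA", "rg": "SW_IN", "vpd": "VPD", "soil_moisture": "SWC",
    "precip": "P",
}

# raw-unit scale of one standardized anomaly unit, per variable.  GPP is the
# more variable flux; its noise is strongly shared with ER (same warm,
# productive weeks drive both), which keeps NEE = ER - GPP from being
# swamped by propagated noise.
DEFAULT_ANOMALY_SCALE = {
    "gpp": 2.5,            # g C m-2 wk-1
    "er": 1.0,             # g C m-2 wk-1
    "et": 2.5,             # mm wk-1
    "soil_moisture": 0.06,  # volumetric fraction
    "vpd": 0.08,           # kPa
}

#: correlation between the GPP and ER weekly noise draws
DEFAULT_GPP_ER_NOISE_CORR = 0.8

# Month-specific snowmelt->flux couplings (standardized units per melt SD).
# Positive melt anomaly = later snowmelt.  Early/peak season: later melt
# suppresses productivity and respiration (earlier melt -> more uptake, and
# higher ET / soil moisture right after melt); late season the productivity
# response reverses and respiration and water fluxes decouple from melt
# timing.  July and August magnitudes are calibrated by simulation so the
# implied monthly-median partial correlations sit near the observed tundra
# values (GPP about -0.33 in July, +0.27 in August; ER -0.34 and n.s.);
# the June magnitudes are set by a power analysis so that the early-season
# coupling dominates the late season strongly enough for the June > August
# first-mode SCF ordering to be recoverable in ~98% of realizations at the
# default cohort size (11 sites x 16 years).
DEFAULT_COUPLING = {
    6: {"gpp": -0.55, "er": -0.35, "et": -0.141, "soil_moisture": -0.141,
        "vpd": 0.0},
    7: {"gpp": -0.157, "er": -0.162, "et": 0.0, "soil_moisture": 0.0, "vpd": 0.0},
    8: {"gpp": 0.126, "er": 0.0, "et": 0.0, "soil_moisture": 0.0, "vpd": 0.0},
}

# couplings of the standardized weather anomalies onto each flux anomaly
DEFAULT_CONTROL_COUPLING = {
    "gpp": {"rg": 0.30, "air_t": 0.20},
    "er": {"rg": 0.05, "air_t": 0.35},
    "et": {"rg": 0.30, "air_t": 0.15},
    "soil_moisture": {"rg": -0.05, "air_t": -0.10},
    "vpd": {"rg": 0.15, "air_t": 0.45},
}

DEFAULT_NOISE_SD = {v: 0.8 for v in ANOMALY_VARS}

# record spans (years per site): 11 sites, 6-19 years each, 119 site-years
DEFAULT_SPANS = (19, 16, 14, 12, 11, 10, 9, 8, 7, 7, 6)


def _default_melt_means(n_sites: int) -> list[float]:
    # spread of climatological melt dates across the network (late May-mid June)
    return list(np.linspace(140.0, 170.0, n_sites))


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world.

    Parameters
    ----------
    n_sites
        Number of tower sites (>= 2).
    years_per_site
        Record span (years) for each site; every span must be >= 3 so the
        site-week climatology SD is defined downstream.
    snowmelt_mean_doy
        Climatological melt day of year per site.
    snowmelt_sd_doy
        Interannual SD of the melt date, days.
    melt_spatial_corr
        Correlation of melt-date anomalies between any two sites in the same
        year (a shared regional spring-climate signal), in [0, 1).
    coupling
        ``{month: {variable: coefficient}}``; months restricted to
        June/July/August.  Coefficients are standardized-anomaly units per
        standardized melt-date anomaly.
    control_coupling
        ``{variable: {"rg": c, "air_t": c}}`` couplings of the weather
        anomalies onto each flux anomaly.
    noise_sd
        Residual SD of each variable's standardized weekly anomaly (> 0).
    missing_rate
        Probability in [0, 1) that any one value is removed (MCAR).
    """

    n_sites: int = 11
    years_per_site: Sequence[int] = DEFAULT_SPANS
    weeks_per_year: int = WEEKS_PER_YEAR
    end_year: int = 2019
    snowmelt_mean_doy: Sequence[float] | None = None
    snowmelt_sd_doy: float = 10.0
    melt_spatial_corr: float = 0.6
    coupling: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(d) for m, d in DEFAULT_COUPLING.items()})
    control_coupling: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {v: dict(d) for v, d in DEFAULT_CONTROL_COUPLING.items()})
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    gpp_er_noise_corr: float = DEFAULT_GPP_ER_NOISE_CORR
    anomaly_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANOMALY_SCALE))
    missing_rate: float = 0.05
    seed: int = 42

    def __post_init__(self):
        self.coupling = {normalize_month(m): dict(d) for m, d in self.coupling.items()}
        if self.snowmelt_mean_doy is None:
            self.snowmelt_mean_doy = _default_melt_means(self.n_sites)
        self.validate()

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ConfigError(f"n_sites must be >= 2, got {self.n_sites}")
        spans = list(self.years_per_site)
        if len(spans) != self.n_sites:
            raise ConfigError(
                f"years_per_site must list one span per site "
                f"({self.n_sites}), got {len(spans)}")
        if any(s < 3 for s in spans):
            raise ConfigError(
                "years_per_site: every span must be >= 3 "
                "(climatology SD undefined otherwise)")
        if len(list(self.snowmelt_mean_doy)) != self.n_sites:
            raise ConfigError("snowmelt_mean_doy must have one entry per site")
        if not all(60 <= d <= 220 for d in self.snowmelt_mean_doy):
            raise ConfigError("snowmelt_mean_doy entries must lie in [60, 220]")
        if self.snowmelt_sd_doy <= 0:
            raise ConfigError(f"snowmelt_sd_doy must be > 0, got {self.snowmelt_sd_doy}")
        if not 0 <= self.melt_spatial_corr < 1:
            raise ConfigError(
                f"melt_spatial_corr must be in [0, 1), got {self.melt_spatial_corr}")
        bad = set(self.coupling) - set(SUMMER_MONTHS)
        if bad:
            raise ConfigError(
                f"coupling: months restricted to June-August, got {sorted(bad)}")
        for m, d in self.coupling.items():
            unknown = set(d) - set(ANOMALY_VARS)
            if unknown:
                raise ConfigError(
                    f"coupling[{m}]: unknown variables {sorted(unknown)}")
        for v in ANOMALY_VARS:
            if self.noise_sd.get(v, 0.0) <= 0:
                raise ConfigError(f"noise_sd[{v!r}] must be > 0")
            if self.anomaly_scale.get(v, 0.0) <= 0:
                raise ConfigError(f"anomaly_scale[{v!r}] must be > 0")
        if not 0 <= self.gpp_er_noise_corr < 1:
            raise ConfigError(
                f"gpp_er_noise_corr must be in [0, 1), got {self.gpp_er_noise_corr}")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def site_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_sites)]

    def site_years(self) -> list[tuple[str, list[int]]]:
        out = []
        for sid, span in zip(self.site_ids, self.years_per_site):
            out.append((sid, list(range(self.end_year - span + 1, self.end_year + 1))))
        return out


# --- seasonal climatologies -------------------------------------------------

def _seasonal_cycles(doy: np.ndarray, site_index: int, rng: np.random.Generator):
    """Deterministic per-site seasonal mean cycles (site traits drawn from rng)."""
    t_mean = -11.0 + 3.0 * rng.uniform(-1, 1)
    t_amp = 17.0 + 2.0 * rng.uniform(-1, 1)
    rg_amp = 220.0 + 30.0 * rng.uniform(-1, 1)
    gpp_max = 14.0 + 3.0 * rng.uniform(-1, 1)
    er_max = 9.0 + 2.0 * rng.uniform(-1, 1)
    et_max = 14.0 + 3.0 * rng.uniform(-1, 1)

    air_t = t_mean + t_amp * np.cos(2 * np.pi * (doy - 203) / 365.0)
    rg = np.maximum(0.0, rg_amp * np.cos(2 * np.pi * (doy - 172) / 365.0))
    gpp = gpp_max * np.exp(-(((doy - 198) / 40.0) ** 2))
    er = er_max * np.exp(-(((doy - 205) / 50.0) ** 2))
    et = et_max * np.exp(-(((doy - 192) / 48.0) ** 2))
    sm = 0.55 + 0.05 * np.cos(2 * np.pi * (doy - 160) / 365.0)
    vpd = np.maximum(0.02, 0.28 + 0.22 * np.cos(2 * np.pi * (doy - 200) / 365.0))
    return dict(air_t=air_t, rg=rg, gpp=gpp, er=er, et=et,
                soil_moisture=sm, vpd=vpd)


def generate_world(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the weekly record table and the snowmelt table.

    Returns
    -------
    records : DataFrame
        One row per site-week with columns :data:`RECORD_COLUMNS`.  Before
        missingness is applied (see ``config.missing_rate``) the identity
        ``NEE = ER - GPP`` holds exactly on every row.
    snowmelt : DataFrame
        Columns ``site_id, year, melt_doy``, one row per site-year.

    Fully deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    weeks = np.arange(1, config.weeks_per_year + 1)
    doy_mid = (weeks - 1) * 7 + 4
    months = month_of_week(weeks)

    site_years = config.site_years()
    all_years = sorted({y for _, ys in site_years for y in ys})
    year_pos = {y: i for i, y in enumerate(all_years)}
    # regional spring-climate year effect shared by all sites
    g_year = rng.standard_normal(len(all_years))
    rho = config.melt_spatial_corr

    frames = []
    melt_rows = []
    for si, (sid, years) in enumerate(site_years):
        cyc = _seasonal_cycles(doy_mid, si, rng)
        ny, nw = len(years), len(weeks)

        e_site = rng.standard_normal(ny)
        z = np.sqrt(rho) * g_year[[year_pos[y] for y in years]] + np.sqrt(1 - rho) * e_site
        melt_doy = config.snowmelt_mean_doy[si] + config.snowmelt_sd_doy * z
        melt_doy = np.clip(melt_doy, 60, 220)
        for y, d in zip(years, melt_doy):
            melt_rows.append((sid, y, float(d)))

        # standardized weather anomalies (enter met columns and fluxes)
        r_anom = rng.standard_normal((ny, nw))
        t_anom = rng.standard_normal((ny, nw))

        # month-dependent melt coupling, broadcast over weeks
        beta = {v: np.zeros(nw) for v in ANOMALY_VARS}
        for m, coefs in config.coupling.items():
            in_m = months == m
            for v, b in coefs.items():
                beta[v][in_m] = b

        # GPP/ER noise shares a component so their correlation is
        # gpp_er_noise_corr; other variables draw independent noise
        rho_ge = config.gpp_er_noise_corr
        shared = rng.standard_normal((ny, nw))
        cols = {}
        anoms = {}
        for v in ANOMALY_VARS:
            cc = config.control_coupling.get(v, {})
            if v in ("gpp", "er"):
                own = rng.standard_normal((ny, nw))
                eps = config.noise_sd[v] * (np.sqrt(rho_ge) * shared
                                            + np.sqrt(1 - rho_ge) * own)
            else:
                eps = rng.normal(0.0, config.noise_sd[v], size=(ny, nw))
            a = (beta[v][None, :] * z[:, None]
                 + cc.get("rg", 0.0) * r_anom
                 + cc.get("air_t", 0.0) * t_anom
                 + eps)
            anoms[v] = a

        scale = config.anomaly_scale
        cols["gpp"] = np.clip(cyc["gpp"][None, :] + scale["gpp"] * anoms["gpp"], 0.0, None)
        cols["er"] = np.clip(cyc["er"][None, :] + scale["er"] * anoms["er"], 0.0, None)
        cols["nee"] = cols["er"] - cols["gpp"]
        cols["et"] = np.clip(cyc["et"][None, :] + scale["et"] * anoms["et"], 0.0, None)
        cols["soil_moisture"] = np.clip(
            cyc["soil_moisture"][None, :] + scale["soil_moisture"] * anoms["soil_moisture"],
            0.02, 0.98)
        cols["vpd"] = np.clip(cyc["vpd"][None, :] + scale["vpd"] * anoms["vpd"], 0.0, None)
        cols["air_t"] = cyc["air_t"][None, :] + 2.0 * t_anom
        cols["rg"] = np.maximum(0.0, cyc["rg"][None, :] + 25.0 * r_anom)
        # latent heat from ET (1 mm d-1 ~ 28.4 W m-2); sensible from a noisy
        # seasonal Bowen ratio around 1
        cols["le"] = cols["et"] / 7.0 * 28.4
        bowen = 1.0 + 0.25 * rng.standard_normal((ny, nw))
        cols["h"] = np.maximum(0.0, bowen * cols["le"])
        cols["precip"] = rng.gamma(shape=0.9, scale=12.0, size=(ny, nw))

        frame = pd.DataFrame({
            "site_id": np.repeat(sid, ny * nw),
            "year": np.repeat(years, nw),
            "week": np.tile(weeks, ny),
        })
        for v in RECORD_COLUMNS[3:]:
            frame[v] = cols[v].ravel()
        frames.append(frame)

    records = pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]
    snowmelt = pd.DataFrame(melt_rows, columns=["site_id", "year", "melt_doy"])
    if config.missing_rate > 0:
        # sub-seed derived from the main seed keeps the one-seed contract
        records = apply_missingness(
            records, config.missing_rate,
            seed=int(np.random.default_rng(config.seed + 1).integers(2 ** 31)))
    return records, snowmelt


def apply_missingness(records: pd.DataFrame, rate: float, seed: int,
                      block_length: int = 1) -> pd.DataFrame:
    """Set values missing with probability ``rate`` per value (MCAR).

    With ``block_length`` > 1, missingness instead strikes in runs of that
    many consecutive records (all variables at once) within the row order —
    an instrument-failure pattern; the marginal missing probability per
    value stays ``rate``.  Key columns (site_id, year, week) are never
    touched and no row is ever removed.  Deterministic for a fixed seed.
    """
    if not 0 <= rate < 1:
        raise ConfigError(f"missing_rate must be in [0, 1), got {rate}")
    if block_length < 1:
        raise ConfigError(f"block_length must be >= 1, got {block_length}")
    out = records.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    value_cols = [c for c in out.columns if c not in ("site_id", "year", "week")]
    if block_length == 1:
        mask = rng.random((len(out), len(value_cols))) < rate
    else:
        starts = rng.random(len(out)) < rate / block_length
        rows = np.zeros(len(out), dtype=bool)
        for i in np.flatnonzero(starts):
            rows[i:i + block_length] = True
        mask = np.broadcast_to(rows[:, None], (len(out), len(value_cols)))
    vals = out[value_cols].to_numpy(dtype=float)
    vals[mask] = np.nan
    out[value_cols] = vals
    return out


def population_partial_correlation(config: GeneratorConfig, month, variable: str) -> float:
    """Closed-form partial correlation implied by the generative model.

    For a variable with weekly anomaly ``a = beta*z + controls + eps`` the
    partial correlation between ``a`` and the melt anomaly ``z`` given the
    (independent) controls is ``beta*sd(z) / sqrt(beta^2*sd(z)^2 + noise^2)``
    with ``sd(z) = 1``.  NEE is handled by propagating the GPP and ER
    couplings and noises through ``NEE = ER - GPP`` in raw units.

    This is the week-level population value; monthly medianing of the weekly
    anomalies shrinks the noise, so pipeline estimates on monthly medians are
    larger in magnitude but share the sign.
    """
    m = normalize_month(month)
    if m not in config.coupling:
        raise ConfigError(f"month {m} has no coupling entry")
    coefs = config.coupling[m]
    if variable == "nee":
        s_g, s_e = config.anomaly_scale["gpp"], config.anomaly_scale["er"]
        sd_g, sd_e = config.noise_sd["gpp"], config.noise_sd["er"]
        beta = s_e * coefs.get("er", 0.0) - s_g * coefs.get("gpp", 0.0)
        noise = np.sqrt((s_e * sd_e) ** 2 + (s_g * sd_g) ** 2
                        - 2 * config.gpp_er_noise_corr * s_e * s_g * sd_e * sd_g)
    else:
        if variable not in ANOMALY_VARS:
            raise ConfigError(f"unknown variable {variable!r}")
        beta = coefs.get(variable, 0.0)
        noise = config.noise_sd[variable]
    if beta == 0.0:
        return 0.0
    return float(beta / np.hypot(beta, noise))


# --- CSV writers ------------------------------------------------------------

def write_weekly_csv(records: pd.DataFrame, path) -> None:
    """Write records in the standard flux CSV dialect read by ``ingest``."""
    # full repr precision so reading the file back reproduces the records
    out = records[RECORD_COLUMNS].rename(columns=CSV_HEADER)
    out.to_csv(path, index=False)


def write_snowmelt_csv(snowmelt: pd.DataFrame, path) -> None:
    snowmelt[["site_id", "year", "melt_doy"]].to_csv(path, index=False)
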