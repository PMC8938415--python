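"""Water-limitation diagnostics: Priestley-Taylor PET, PET-ET, PPT-ET, Bowen.

Potential evapotranspiration follows the Priestley-Taylor formula

    PET = alpha * Delta / (Delta + gamma) * (Rn - G) / lambda    [mm d-1]

with Delta the slope of the Tetens saturation-vapour-pressure curve at air
temperature (kPa degC-1), gamma the psychrometric constant (0.066 kPa
degC-1 by default), lambda the latent heat of vaporisation (2.45 MJ kg-1)
and alpha the Priestley-Taylor coefficient (1.26).  Negative PET (available
energy below zero) is clipped to 0.

Monthly balances subtract eddy-covariance ET from monthly PET totals and
from precipitation; the Bowen ratio H/LE is computed on weekly means and
medianed within each month.  Cross-site seasonal summaries use medians, as
robust against the outliers typical of flux records.
"""

from __future__ import annotations

import calendar
import logging

import numpy as np
import pandas as pd

from .errors import ConfigError
from .weeks import SUMMER_MONTHS, month_of_week

log = logging.getLogger(__name__)

__all__ = [
    "tetens_slope",
    "priestley_taylor_pet",
    "weekly_pet_from_records",
    "monthly_balance",
    "bowen_ratio",
    "add_weekly_bowen",
    "monthly_bowen",
    "seasonal_median_summary",
]

GAMMA_DEFAULT = 0.066   # psychrometric constant, kPa degC-1
LAMBDA_DEFAULT = 2.45   # latent heat of vaporisation, MJ kg-1
ALPHA_DEFAULT = 1.26    # Priestley-Taylor coefficient

#: W m-2 sustained over a day, in MJ m-2 d-1
WM2_TO_MJ_DAY = 0.0864


def tetens_slope(air_t):
    """Slope of the Tetens saturation-vapour-pressure curve, kPa degC-1."""
    t = np.asarray(air_t, dtype=float)
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return 4098.0 * es / (t + 237.3) ** 2


def priestley_taylor_pet(air_t, net_radiation, ground_heat_flux=0.0,
                         alpha: float = ALPHA_DEFAULT,
                         gamma: float = GAMMA_DEFAULT,
                         lam: float = LAMBDA_DEFAULT):
    """Daily Priestley-Taylor PET in mm d-1.

    Parameters
    ----------
    air_t
        Air temperature, degC.
    net_radiation, ground_heat_flux
        Energy terms in MJ m-2 d-1 (G defaults to 0).
    alpha, gamma, lam
        Priestley-Taylor coefficient, psychrometric constant (kPa degC-1)
        and latent heat of vaporisation (MJ kg-1).

    Missing inputs give missing output; negative values are clipped to 0
    with a logged count.
    """
    if alpha <= 0:
        raise ConfigError(f"alpha must be > 0, got {alpha}")
    t = np.asarray(air_t, dtype=float)
    rn = np.asarray(net_radiation, dtype=float)
    g = np.asarray(ground_heat_flux, dtype=float)
    delta = tetens_slope(t)
    pet = alpha * delta / (delta + gamma) * (rn - g) / lam
    neg = np.sum(pet < 0)
    if neg:
        log.info("%d negative PET values clipped to 0", int(neg))
    out = np.where(np.isnan(pet), np.nan, np.clip(pet, 0.0, None))
    if np.isscalar(air_t) and np.isscalar(net_radiation):
        return float(out)
    return out


def weekly_pet_from_records(records: pd.DataFrame, rn_fraction: float = 0.6,
                            alpha: float = ALPHA_DEFAULT,
                            gamma: float = GAMMA_DEFAULT,
                            lam: float = LAMBDA_DEFAULT) -> pd.DataFrame:
    """Weekly PET totals (mm wk-1) from weekly mean air T and shortwave-in.

    Net radiation is approximated as ``rn_fraction`` of incoming shortwave
    (an all-wave surrogate for sites without measured Rn), converted from
    W m-2 to MJ m-2 d-1.  Returns site_id, year, week, pet.
    """
    rn = records["rg"].to_numpy(float) * rn_fraction * WM2_TO_MJ_DAY
    pet_daily = priestley_taylor_pet(records["air_t"].to_numpy(float), rn,
                                     alpha=alpha, gamma=gamma, lam=lam)
    out = records[["site_id", "year", "week"]].copy()
    out["pet"] = np.asarray(pet_daily, dtype=float) * 7.0
    return out


def monthly_balance(pet: pd.DataFrame, weekly_records: pd.DataFrame,
                    completeness: float = 0.8,
                    months=SUMMER_MONTHS) -> pd.DataFrame:
    """Monthly PET, ET, PPT totals and their differences per site-month.

    Parameters
    ----------
    pet
        Either daily PET (columns site_id, date, pet in mm d-1) or weekly
        PET (columns site_id, year, week, pet in mm wk-1).
    weekly_records
        Canonical weekly table supplying ``et`` and ``precip`` (mm wk-1).
    completeness
        Rows where fewer than this fraction of the month's expected
        days/weeks are present are flagged ``incomplete``.

    The identities ``pet_minus_et = pet - et`` and ``ppt_minus_et =
    ppt - et`` hold exactly on every emitted row.
    """
    if "date" in pet.columns:
        pp = pet.copy()
        d = pd.to_datetime(pp["date"])
        pp["year"] = d.dt.year
        pp["month"] = d.dt.month
        pet_m = pp.groupby(["site_id", "year", "month"])["pet"].agg(
            pet="sum", n="count").reset_index()
        pet_m["expected"] = [calendar.monthrange(y, m)[1]
                             for y, m in zip(pet_m["year"], pet_m["month"])]
    elif "week" in pet.columns:
        pp = pet.copy()
        pp["month"] = month_of_week(pp["week"].to_numpy())
        pet_m = pp.dropna(subset=["pet"]).groupby(
            ["site_id", "year", "month"])["pet"].agg(pet="sum", n="count").reset_index()
        pet_m["expected"] = [_weeks_in(m) for m in pet_m["month"]]
    else:
        raise ConfigError("pet table needs a 'date' or 'week' column")
    pet_m["pet_ok"] = pet_m["n"] >= completeness * pet_m["expected"]

    wk = weekly_records.copy()
    wk["month"] = month_of_week(wk["week"].to_numpy())
    wk = wk[wk["month"].isin(list(months))]

    def _tot(col):
        g = wk.dropna(subset=[col]).groupby(["site_id", "year", "month"])[col]
        t = g.agg(total="sum", n="count").reset_index()
        t["ok"] = t["n"] >= completeness * t["month"].map(_weeks_in)
        return t

    et_m = _tot("et").rename(columns={"total": "et", "ok": "et_ok"})
    ppt_m = _tot("precip").rename(columns={"total": "ppt", "ok": "ppt_ok"})

    out = pet_m[["site_id", "year", "month", "pet", "pet_ok"]]
    out = out[out["month"].isin(list(months))]
    out = out.merge(et_m[["site_id", "year", "month", "et", "et_ok"]],
                    on=["site_id", "year", "month"], how="outer")
    out = out.merge(ppt_m[["site_id", "year", "month", "ppt", "ppt_ok"]],
                    on=["site_id", "year", "month"], how="outer")
    out["pet_minus_et"] = out["pet"] - out["et"]
    out["ppt_minus_et"] = out["ppt"] - out["et"]
    flags = out[["pet_ok", "et_ok", "ppt_ok"]].astype("boolean").fillna(False)
    out["incomplete"] = ~flags.all(axis=1)
    return out.drop(columns=["pet_ok", "et_ok", "ppt_ok"]).sort_values(
        ["site_id", "year", "month"]).reset_index(drop=True)


def _weeks_in(month: int) -> int:
    from .weeks import weeks_in_month
    return len(weeks_in_month(int(month)))


def bowen_ratio(h, le, min_le: float = 5.0):
    """Bowen ratio H / LE; missing where |LE| is below ``min_le`` W m-2."""
    scalar = np.isscalar(h) and np.isscalar(le)
    h = np.asarray(h, dtype=float)
    le = np.asarray(le, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(np.abs(le) >= min_le, h / le, np.nan)
    n_small = int(np.sum(np.isfinite(le) & (np.abs(le) < min_le)))
    if n_small:
        log.info("%d Bowen ratios dropped (|LE| < %g W m-2)", n_small, min_le)
    return float(ratio) if scalar else ratio


def add_weekly_bowen(weekly_records: pd.DataFrame,
                     min_le: float = 5.0) -> pd.DataFrame:
    """Records with a derived weekly ``bowen`` column (H/LE), for use as a
    response in the anomaly/partial-correlation pipeline."""
    out = weekly_records.copy()
    out["bowen"] = bowen_ratio(out["h"].to_numpy(), out["le"].to_numpy(),
                               min_le=min_le)
    return out


def monthly_bowen(weekly_records: pd.DataFrame, min_le: float = 5.0,
                  months=SUMMER_MONTHS) -> pd.DataFrame:
    """Median of the weekly Bowen ratios within each site-month."""
    wk = weekly_records.copy()
    wk["month"] = month_of_week(wk["week"].to_numpy())
    wk = wk[wk["month"].isin(list(months))]
    wk["bowen"] = bowen_ratio(wk["h"].to_numpy(), wk["le"].to_numpy(),
                              min_le=min_le)
    g = wk.dropna(subset=["bowen"]).groupby(["site_id", "year", "month"])["bowen"]
    return g.agg(bowen_median="median", n_weeks="count").reset_index()


def seasonal_median_summary(rows: pd.DataFrame,
                            include_incomplete: bool = False) -> pd.DataFrame:
    """Per-month medians of the balance columns pooled over sites and years."""
    df = rows
    if "incomplete" in df.columns and not include_incomplete:
        df = df[~df["incomplete"]]
    if df.empty:
        raise ValueError("no complete rows to summarise")
    cols = [c for c in ("pet", "et", "ppt", "pet_minus_et", "ppt_minus_et",
                        "bowen_median") if c in df.columns]
    return df.groupby("month")[cols].median().reset_index()
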