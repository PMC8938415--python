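"""Site-week climatologies and standardized anomalies.

The core statistic of the analysis: for each site, week of year and variable,
a climatological mean and SD are computed over all years available at that
site; the standardized weekly anomaly is (observation - mean) / SD, and the
monthly anomaly is the *median* of the standardized weekly anomalies of the
weeks whose midpoint falls in the month (the median being robust to the
outliers common in flux data).  Snowmelt dates are standardized per site the
same way, across years.

Everything is dimensionless after standardization, so anomalies from sites
with very different flux magnitudes can be pooled ("site as the unit of
variation").
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .weeks import SUMMER_MONTHS, month_of_week

log = logging.getLogger(__name__)

__all__ = [
    "build_climatology",
    "weekly_standardized_anomalies",
    "monthly_median_anomalies",
    "snowmelt_anomalies",
]


def _value_columns(records: pd.DataFrame) -> list:
    """Every non-key column is a variable (derived columns like a weekly
    Bowen ratio flow through the anomaly pipeline unchanged)."""
    return [c for c in records.columns if c not in ("site_id", "year", "week")]


def build_climatology(records: pd.DataFrame, min_years: int = 3) -> pd.DataFrame:
    """Per (site, week, variable) climatological mean, sample SD and year count.

    The climatology uses each site's full record ("the entire period
    available"), not a common window.  SD is the sample SD (denominator
    n - 1).  Cells with fewer than ``min_years`` contributing years or zero
    SD are kept but flagged ``usable = False``; all-missing site-weeks are
    absent from the table.
    """
    if min_years < 2:
        raise ValueError(f"min_years must be >= 2, got {min_years}")
    value_cols = _value_columns(records)
    long = records.melt(id_vars=["site_id", "year", "week"],
                        value_vars=value_cols,
                        var_name="variable", value_name="value")
    long = long.dropna(subset=["value"])
    g = long.groupby(["site_id", "week", "variable"], sort=True)["value"]
    clim = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n_years="count").reset_index()
    clim["sd"] = clim["sd"].fillna(0.0)
    clim["usable"] = (clim["n_years"] >= min_years) & (clim["sd"] > 0)
    return clim


def weekly_standardized_anomalies(records: pd.DataFrame,
                                  climatology: pd.DataFrame) -> pd.DataFrame:
    """Standardized weekly anomalies (obs - clim mean) / clim SD, long format.

    Anomalies are missing where the observation is missing, the climatology
    cell is unusable, or SD is zero.  A non-missing observation whose
    site-week is absent from the climatology is an integrity error (the two
    tables were built with different week conventions or datasets).
    """
    value_cols = _value_columns(records)
    long = records.melt(id_vars=["site_id", "year", "week"],
                        value_vars=value_cols,
                        var_name="variable", value_name="value")
    merged = long.merge(climatology, on=["site_id", "week", "variable"],
                        how="left")
    orphan = merged["value"].notna() & merged["mean"].isna()
    if orphan.any():
        row = merged.loc[orphan.idxmax()]
        raise IntegrityError(
            "record site-week absent from climatology: "
            f"({row['site_id']}, week {row['week']}, {row['variable']})")
    usable = merged["usable"].astype("boolean").fillna(False).astype(bool)
    ok = merged["value"].notna() & usable
    n_sd_zero = int((merged["value"].notna() & ~usable).sum())
    if n_sd_zero:
        log.info("%d weekly values dropped (unusable climatology cell)", n_sd_zero)
    merged["anomaly"] = np.where(
        ok, (merged["value"] - merged["mean"]) / merged["sd"].where(merged["sd"] > 0),
        np.nan)
    return merged[["site_id", "year", "week", "variable", "anomaly"]]


def monthly_median_anomalies(weekly: pd.DataFrame, min_weeks: int = 2,
                             months=SUMMER_MONTHS) -> pd.DataFrame:
    """Monthly median of the standardized weekly anomalies.

    A week belongs to the month containing its midpoint day.  Months with
    fewer than ``min_weeks`` non-missing contributing weeks are omitted
    (missing).  Returns a long table (site_id, year, month, variable,
    anomaly, n_weeks_used).
    """
    if min_weeks < 1:
        raise ValueError(f"min_weeks must be >= 1, got {min_weeks}")
    df = weekly.copy()
    df["month"] = month_of_week(df["week"].to_numpy())
    df = df[df["month"].isin(list(months))]
    df = df.dropna(subset=["anomaly"])
    g = df.groupby(["site_id", "year", "month", "variable"], sort=True)["anomaly"]
    out = g.agg(anomaly="median", n_weeks_used="count").reset_index()
    return out[out["n_weeks_used"] >= min_weeks].reset_index(drop=True)


def snowmelt_anomalies(snowmelt: pd.DataFrame, min_years: int = 3) -> pd.DataFrame:
    """Standardized snowmelt-date anomalies, per site across its years.

    Sites with fewer than ``min_years`` melt dates or zero interannual SD are
    dropped with a warning — a standardized anomaly is undefined for them.
    """
    df = snowmelt.dropna(subset=["melt_doy"]).copy()
    out = []
    for sid, g in df.groupby("site_id", sort=True):
        if len(g) < min_years:
            log.warning("site %s dropped: only %d melt dates (< %d)",
                        sid, len(g), min_years)
            continue
        sd = g["melt_doy"].std(ddof=1)
        if not sd > 0:
            log.warning("site %s dropped: constant melt date (sd = 0)", sid)
            continue
        anom = (g["melt_doy"] - g["melt_doy"].mean()) / sd
        out.append(pd.DataFrame({"site_id": sid, "year": g["year"].to_numpy(),
                                 "melt_anomaly": anom.to_numpy()}))
    if not out:
        return pd.DataFrame(columns=["site_id", "year", "melt_anomaly"])
    return pd.concat(out, ignore_index=True)
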