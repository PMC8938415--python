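"""Reading and harmonizing site flux files into the canonical weekly table.

The canonical table has one row per (site, year, week) and the value columns
``nee, gpp, er, et, h, le, air_t, rg, vpd, soil_moisture, precip`` in fixed
units (g C m-2 wk-1, mm wk-1, W m-2, degC, kPa, volumetric fraction).
A ``column_map`` translates provider headers (the package's own CSV dialect
or FLUXNET-style names) onto the canonical fields; ingest never invents
values — unparseable cells become missing with a logged warning, and
duplicate keys are a hard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, IntegrityError
from .synth import CSV_HEADER, RECORD_COLUMNS
from .weeks import week_of_doy

log = logging.getLogger(__name__)

KEY_COLUMNS = ("site_id", "year", "week")
VALUE_COLUMNS = tuple(c for c in RECORD_COLUMNS if c not in KEY_COLUMNS)

#: file header -> canonical name, for the package's own CSV dialect
DEFAULT_COLUMN_MAP = {v: k for k, v in CSV_HEADER.items()}

#: FLUXNET-style export headers -> canonical names
FLUXNET_COLUMN_MAP = {
    "site_id": "site_id", "year": "year", "week": "week",
    "NEE_VUT_REF": "nee", "GPP_NT_VUT_REF": "gpp", "RECO_NT_VUT_REF": "er",
    "ET": "et", "H_F": "h", "LE_F": "le", "TA_F": "air_t", "SW_IN_F": "rg",
    "VPD_F": "vpd", "SWC_F_MDS_1": "soil_moisture", "P_F": "precip",
}

#: weekly aggregation rule per canonical variable: totals are summed,
#: states/intensities averaged
AGGREGATION_RULES = {
    "nee": "sum", "gpp": "sum", "er": "sum", "et": "sum", "precip": "sum",
    "h": "mean", "le": "mean", "air_t": "mean", "rg": "mean",
    "vpd": "mean", "soil_moisture": "mean",
}


@dataclass
class SiteMeta:
    """Descriptive metadata for one tower site."""

    site_id: str
    latitude: float
    longitude: float
    vegetation_class: str = ""
    first_year: int | None = None
    last_year: int | None = None

    def __post_init__(self):
        if abs(self.latitude) > 90:
            raise ConfigError(f"latitude out of range: {self.latitude}")
        if (self.first_year is not None and self.last_year is not None
                and self.first_year > self.last_year):
            raise ConfigError(
                f"first_year {self.first_year} > last_year {self.last_year}")


def read_weekly_csv(path, column_map: dict | None = None,
                    flip_nee: bool = False) -> pd.DataFrame:
    """Read a weekly flux CSV into the canonical record table.

    Parameters
    ----------
    path
        CSV file (comma separated, UTF-8, header row).
    column_map
        Mapping of file header -> canonical field.  Defaults to the
        package's own dialect; pass :data:`FLUXNET_COLUMN_MAP` for
        FLUXNET-style exports.
    flip_nee
        Negate NEE on read, for providers using positive = uptake.

    Unparseable numeric cells become missing (one warning with a count);
    duplicate (site, year, week) keys raise :class:`IntegrityError`.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw = raw.rename(columns=column_map)

    missing_keys = [k for k in KEY_COLUMNS if k not in raw.columns]
    if missing_keys:
        raise FormatError(
            f"{path}: mandatory key columns missing: {missing_keys}")

    out = pd.DataFrame({"site_id": raw["site_id"].astype(str)})
    n_bad = 0
    for key in ("year", "week"):
        vals = pd.to_numeric(raw[key], errors="coerce")
        if vals.isna().any():
            raise FormatError(f"{path}: unparseable {key} values")
        out[key] = vals.astype(int)

    dups = out.duplicated(subset=list(KEY_COLUMNS))
    if dups.any():
        first = out.loc[dups.idxmax(), list(KEY_COLUMNS)].tolist()
        raise IntegrityError(
            f"{path}: duplicate (site, year, week) keys, e.g. {first}")

    for v in VALUE_COLUMNS:
        if v in raw.columns:
            col = pd.to_numeric(raw[v], errors="coerce")
            n_bad += int((col.isna() & raw[v].notna()
                          & (raw[v].str.strip() != "")).sum())
            out[v] = col.astype(float)
        else:
            out[v] = np.nan
    if n_bad:
        log.warning("%s: %d unparseable numeric cells set to missing", path, n_bad)
    if flip_nee:
        out["nee"] = -out["nee"]

    bad_week = ~out["week"].between(1, 52)
    if bad_week.any():
        raise FormatError(f"{path}: week values outside 1-52")
    return out[list(RECORD_COLUMNS)]


def read_snowmelt_csv(path) -> pd.DataFrame:
    """Read a snowmelt CSV (site_id, year, melt_doy), one row per site-year."""
    df = pd.read_csv(path)
    for col in ("site_id", "year", "melt_doy"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df = df[["site_id", "year", "melt_doy"]].copy()
    df["site_id"] = df["site_id"].astype(str)
    df["year"] = df["year"].astype(int)
    df["melt_doy"] = pd.to_numeric(df["melt_doy"], errors="coerce")
    if df.duplicated(subset=["site_id", "year"]).any():
        raise IntegrityError(f"{path}: duplicate (site, year) snowmelt keys")
    bad = df["melt_doy"].notna() & ~df["melt_doy"].between(60, 220)
    if bad.any():
        log.warning("%s: %d melt dates outside [60, 220] set to missing",
                    path, int(bad.sum()))
        df.loc[bad, "melt_doy"] = np.nan
    return df


def aggregate_to_weekly(finer: pd.DataFrame, rules: dict | None = None,
                        completeness: float = 0.5) -> pd.DataFrame:
    """Aggregate sub-weekly (e.g. daily) records to the canonical weekly table.

    Parameters
    ----------
    finer
        DataFrame with ``site_id``, a parseable ``date`` column, and any
        subset of the canonical value columns at a sub-weekly (daily or
        coarser) cadence.
    rules
        Per-variable aggregation rule (``"sum"`` or ``"mean"``); defaults to
        :data:`AGGREGATION_RULES` (fluxes and precipitation summed, states
        averaged).
    completeness
        A week is emitted only when at least this fraction of its expected
        finer records is present for the variable; otherwise missing.
        Summed variables are rescaled by expected/present so a nearly
        complete week is not biased low.
    """
    rules = dict(AGGREGATION_RULES, **(rules or {}))
    unknown = set(rules) - set(VALUE_COLUMNS)
    if unknown:
        raise ConfigError(f"aggregation rules for unknown variables: {sorted(unknown)}")
    if not 0 < completeness <= 1:
        raise ConfigError(f"completeness must be in (0, 1], got {completeness}")

    df = finer.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year.astype(int)
    doy = dates.dt.dayofyear.to_numpy()
    df["week"] = week_of_doy(doy)

    value_cols = [c for c in VALUE_COLUMNS if c in df.columns]
    grouped = df.groupby(["site_id", "year", "week"], sort=True)
    # expected finer records per week: days in the block (7, or 8-9 for the
    # folded week 52) divided by the inferred sampling step in days
    step = _infer_step_days(dates)

    rows = []
    for (sid, year, week), g in grouped:
        if week < 52:
            block_days = 7
        else:
            block_days = (366 if _is_leap(year) else 365) - 357
        expected = max(1, int(round(block_days / step)))
        row = {"site_id": sid, "year": int(year), "week": int(week)}
        for v in value_cols:
            vals = g[v].to_numpy(dtype=float)
            present = int(np.isfinite(vals).sum())
            if present < completeness * expected:
                row[v] = np.nan
            elif rules.get(v, "mean") == "sum":
                row[v] = np.nansum(vals) * expected / present
            else:
                row[v] = np.nanmean(vals)
        rows.append(row)
    out = pd.DataFrame(rows)
    for v in VALUE_COLUMNS:
        if v not in out.columns:
            out[v] = np.nan
    return out[list(RECORD_COLUMNS)]


def _infer_step_days(dates: pd.Series) -> float:
    diffs = dates.sort_values().diff().dt.total_seconds().dropna()
    diffs = diffs[diffs > 0]
    if diffs.empty:
        return 1.0
    return float(diffs.median() / 86400.0)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
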