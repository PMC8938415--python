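"""One-command orchestration: generate/ingest -> anomalies -> analyses.

A :class:`RunConfig` (usually loaded from YAML via :func:`validate_config`)
describes the whole run: either a synthetic-world generator configuration or
paths to weekly flux and snowmelt CSVs, the months analysed, the control
variables, the MCA year window and all thresholds.  :func:`run_pipeline`
executes every stage, writes tidy CSV artifacts plus a JSON manifest with
the software version, seed, thresholds and input hashes, and returns the
in-memory results.  All outputs are reproduced byte-identically from the
same (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DegenerateInputError, InsufficientDataError
from .weeks import SUMMER_MONTHS, normalize_month
from . import anomalies as anom_mod
from . import association as assoc_mod
from . import ingest as ingest_mod
from . import lmm as lmm_mod
from . import mca as mca_mod
from . import synth as synth_mod
from . import waterbalance as water_mod

log = logging.getLogger(__name__)

DEFAULT_RESPONSES = ("nee", "gpp", "er", "et", "soil_moisture", "vpd")


@dataclass
class RunConfig:
    """Normalized configuration of one pipeline run."""

    outdir: str = "meltflux_out"
    seed: int = 42
    records_csv: str | None = None
    snowmelt_csv: str | None = None
    generator: synth_mod.GeneratorConfig = None
    months: tuple = SUMMER_MONTHS
    responses: tuple = DEFAULT_RESPONSES
    controls: tuple = ("rg", "air_t")
    year_range: tuple = (2004, 2019)
    min_years: int = 3
    min_weeks: int = 2
    min_overlap: int = 3
    alpha_report: float = 0.1
    flip_nee: bool = False

    def __post_init__(self):
        self.months = tuple(normalize_month(m) for m in self.months)
        if not self.months:
            raise ConfigError("months must be non-empty")
        bad = set(self.months) - set(SUMMER_MONTHS)
        if bad:
            raise ConfigError(f"months restricted to June-August, got {sorted(bad)}")
        if not 0 < self.alpha_report <= 1:
            raise ConfigError(
                f"alpha_report must be in (0, 1], got {self.alpha_report}")
        for name in ("min_years", "min_weeks", "min_overlap"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.min_years < 2:
            raise ConfigError("min_years must be >= 2")
        if len(self.year_range) != 2 or self.year_range[0] > self.year_range[1]:
            raise ConfigError(f"year_range must be (first, last), got {self.year_range}")
        if self.generator is None and self.records_csv is None:
            self.generator = synth_mod.GeneratorConfig(seed=self.seed)


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(path) -> RunConfig:
    """Load and normalize a YAML run configuration.

    Unknown keys are rejected (not ignored) so typos surface immediately;
    defaults are filled for everything omitted.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown configuration keys: {sorted(unknown)}")
    gen = raw.pop("generator", None)
    if gen is not None:
        if not isinstance(gen, dict):
            raise ConfigError(f"{path}: generator must be a mapping")
        gen.setdefault("seed", raw.get("seed", 42))
        try:
            gen = synth_mod.GeneratorConfig(**gen)
        except TypeError as err:
            raise ConfigError(f"{path}: generator: {err}") from None
    try:
        return RunConfig(generator=gen, **raw)
    except TypeError as err:
        raise ConfigError(f"{path}: {err}") from None


# --- stages -----------------------------------------------------------------

def load_world(cfg: RunConfig):
    """Generate the synthetic world or read the configured input CSVs."""
    if cfg.records_csv is not None:
        records = ingest_mod.read_weekly_csv(cfg.records_csv,
                                             flip_nee=cfg.flip_nee)
        if cfg.snowmelt_csv is None:
            raise ConfigError("snowmelt_csv required when records_csv is given")
        snowmelt = ingest_mod.read_snowmelt_csv(cfg.snowmelt_csv)
    else:
        records, snowmelt = synth_mod.generate_world(cfg.generator)
    return records, snowmelt


def stage_anomalies(records, snowmelt, cfg: RunConfig):
    clim = anom_mod.build_climatology(records, min_years=cfg.min_years)
    weekly = anom_mod.weekly_standardized_anomalies(records, clim)
    monthly = anom_mod.monthly_median_anomalies(weekly, min_weeks=cfg.min_weeks,
                                                months=cfg.months)
    melt = anom_mod.snowmelt_anomalies(snowmelt, min_years=cfg.min_years)
    return clim, monthly, melt


def stage_association(monthly, melt, cfg: RunConfig):
    results = []
    for m in cfg.months:
        res = assoc_mod.monthly_partial_correlations(
            monthly, melt, cfg.responses, m, controls=cfg.controls)
        results.extend(assoc_mod.reporting_filter(res, alpha=cfg.alpha_report))
    table = assoc_mod.results_table(results)

    inter_rows = []
    if len(cfg.months) >= 2:
        for resp in cfg.responses:
            try:
                it = assoc_mod.interaction_test(monthly, melt, resp,
                                                controls=cfg.controls,
                                                months=cfg.months)
            except (InsufficientDataError, DegenerateInputError) as err:
                log.warning("interaction test skipped for %s: %s", resp, err)
                continue
            inter_rows.append({"response": it.response, "f_stat": it.f_stat,
                               "df_num": it.df_num, "df_den": it.df_den,
                               "p": it.p, "n": it.n})
    return table, pd.DataFrame(inter_rows)


def stage_mca(monthly, melt, cfg: RunConfig):
    years = range(cfg.year_range[0], cfg.year_range[1] + 1)
    results = {}
    for m in cfg.months:
        try:
            melt_field = mca_mod.build_snowmelt_field(
                melt, years, month=m, min_site_years=cfg.min_overlap)
        except DegenerateInputError as err:
            log.warning("MCA skipped for month %s: %s", m, err)
            continue
        for resp in cfg.responses:
            try:
                f = mca_mod.build_field(monthly, resp, m, years,
                                        min_site_years=cfg.min_overlap)
                res = mca_mod.run_mca(f, melt_field, min_overlap=cfg.min_overlap)
            except DegenerateInputError as err:
                log.warning("MCA skipped for %s/%s: %s", resp, m, err)
                continue
            results[(f"{resp}-melt", m)] = res
    return mca_mod.scf_table(results) if results else pd.DataFrame(
        columns=["pair", "month", "scf1", "sigma1", "undefined"]), results


def stage_lmm(monthly, melt, cfg: RunConfig):
    rows = []
    for m in cfg.months:
        for resp in cfg.responses:
            try:
                reml = lmm_mod.fit_lmm(monthly, melt, resp, m, reml=True)
                ml = lmm_mod.fit_lmm(monthly, melt, resp, m, reml=False)
            except (InsufficientDataError, DegenerateInputError) as err:
                log.warning("LMM skipped for %s/%s: %s", resp, m, err)
                continue
            rows.append({
                "response": resp, "month": m,
                "beta_melt": reml.beta.get("melt_anomaly"),
                "se_melt": reml.se.get("melt_anomaly"),
                "p_melt": reml.p_fixed.get("melt_anomaly"),
                "r2_marginal": reml.r2_marginal,
                "aic_ml": ml.aic, "n": reml.n, "singular": reml.singular,
            })
    return pd.DataFrame(rows)


def stage_water(records, cfg: RunConfig):
    pet = water_mod.weekly_pet_from_records(records)
    balance = water_mod.monthly_balance(pet, records, months=cfg.months)
    bowen = water_mod.monthly_bowen(records, months=cfg.months)
    balance = balance.merge(bowen[["site_id", "year", "month", "bowen_median"]],
                            on=["site_id", "year", "month"], how="left")
    summary = water_mod.seasonal_median_summary(balance)
    return balance, summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write all artifacts under ``cfg.outdir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, snowmelt = load_world(cfg)
    synth_mod.write_weekly_csv(records, outdir / "records.csv")
    synth_mod.write_snowmelt_csv(snowmelt, outdir / "snowmelt.csv")

    clim, monthly, melt = stage_anomalies(records, snowmelt, cfg)
    _write(clim, outdir / "climatology.csv")
    _write(monthly, outdir / "anomalies_monthly.csv")
    _write(melt, outdir / "snowmelt_anomalies.csv")

    pcorr, inter = stage_association(monthly, melt, cfg)
    _write(pcorr, outdir / "partial_correlations.csv")
    _write(inter, outdir / "interaction_tests.csv")

    scf, _ = stage_mca(monthly, melt, cfg)
    _write(scf, outdir / "scf_table.csv")

    lmm_table = stage_lmm(monthly, melt, cfg)
    _write(lmm_table, outdir / "lmm_table.csv")

    balance, summary = stage_water(records, cfg)
    _write(balance, outdir / "water_balance.csv")
    _write(summary, outdir / "water_summary.csv")

    artifacts = ["records.csv", "snowmelt.csv", "climatology.csv",
                 "anomalies_monthly.csv", "snowmelt_anomalies.csv",
                 "partial_correlations.csv", "interaction_tests.csv",
                 "scf_table.csv", "lmm_table.csv", "water_balance.csv",
                 "water_summary.csv"]
    manifest = {
        "package": "meltflux",
        "version": __version__,
        "seed": cfg.seed,
        "months": list(cfg.months),
        "responses": list(cfg.responses),
        "controls": list(cfg.controls),
        "year_range": list(cfg.year_range),
        "thresholds": {"min_years": cfg.min_years, "min_weeks": cfg.min_weeks,
                       "min_overlap": cfg.min_overlap,
                       "alpha_report": cfg.alpha_report},
        "inputs": {"records_csv": cfg.records_csv,
                   "snowmelt_csv": cfg.snowmelt_csv,
                   "synthetic": cfg.records_csv is None,
                   "input_sha256": {
                       p: _sha256(p) for p in (cfg.records_csv,
                                               cfg.snowmelt_csv)
                       if p is not None}},
        "counts": {"site_weeks": int(len(records)),
                   "site_years_melt": int(len(snowmelt)),
                   "monthly_anomalies": int(len(monthly))},
        "artifact_sha256": {name: _sha256(outdir / name) for name in artifacts},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
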