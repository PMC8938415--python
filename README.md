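# meltflux

Statistical analysis of how **snowmelt timing** relates to month-specific
anomalies of tundra **CO₂ fluxes** (NEE, GPP, ER) and **water fluxes** (ET,
Bowen ratio, PET−ET, PPT−ET) across a multi-site eddy-covariance tower
network — plus a synthetic multi-site generator with known couplings, so
every stage of the pipeline can be validated without downloading tower data.

Intended users: ecosystem carbon-cycle scientists working with weekly
gap-filled flux-tower exports (FLUXNET/AmeriFlux-style CSVs) and per-site
snowmelt dates, who want a reproducible, testable implementation of the
anomaly/partial-correlation/MCA/mixed-model workflow.

## The statistics

For each site *s*, week-of-year *w* and variable, a climatology
(mean *μ*<sub>s,w</sub>, SD *σ*<sub>s,w</sub>) is computed over all years
available at the site, and each observation becomes a **standardized weekly
anomaly** (x − μ)/σ. The **monthly anomaly** is the median of the weekly
anomalies of the weeks whose midpoint falls in the month (the median is
robust to flux outliers). Snowmelt day-of-year is standardized per site the
same way. On these dimensionless anomalies the package computes, per summer
month (June / July / August):

- **Partial correlations** r(flux, melt | Rg, airT): the Pearson correlation
  of the OLS residuals of each variable on the controls, with two-sided
  p-values from t = r·√((n−2−k)/(1−r²)), and the reporting convention that
  r and P are shown only when P < 0.1;
- an **interaction F-test** comparing `flux ~ melt × month + controls`
  against the no-interaction model (is the melt slope month-dependent?);
- **Maximum covariance analysis (MCA)**: SVD of the cross-covariance matrix
  between two years × sites anomaly fields, with gap-tolerant
  pairwise-complete covariances; mode k's **squared covariance fraction**
  SCF<sub>k</sub> = σ<sub>k</sub>²/Σσ<sub>i</sub>² measures how strongly the
  two variables co-vary across the network over time;
- **Linear mixed models** `flux ~ melt + (1 | site)` with REML estimates,
  ML-based AIC comparison, and the Nakagawa–Schielzeth **marginal R²** =
  var(fixed)/(var(fixed)+var(random)+var(residual));
- the **water balance**: Priestley–Taylor potential evapotranspiration
  PET = α·Δ/(Δ+γ)·(Rn−G)/λ (Tetens slope Δ, γ = 0.066 kPa °C⁻¹,
  λ = 2.45 MJ kg⁻¹, α = 1.26), monthly PET−ET and PPT−ET totals, and
  monthly medians of the weekly Bowen ratio H/LE.

## Worked example

```bash
meltflux all --seed 7 -o out7
```

generates the default synthetic network (11 sites, 6–19 years each, 119
site-years), runs every stage and prints

```
run complete: 11 artifacts in out7
```

`out7/partial_correlations.csv` then holds the Table-style results; for GPP
this seed gives exactly:

```
response  month         r            p   n  reported
     gpp      6 -0.740226 1.487080e-21 119      True
     gpp      7 -0.461403 1.643300e-07 119      True
     gpp      8  0.364604 5.311322e-05 119      True
```

Reading: later snowmelt (positive melt anomaly) is associated with *lower*
early/peak-season GPP (earlier melt → more productivity in June/July), but
the sign reverses in August — the month-specific coupling the generator
embeds, recovered by the pipeline. `scf_table.csv` shows the same story in
the MCA (first-mode SCF of the GPP–snowmelt pair, same run):

```
    pair  month     scf1
gpp-melt      6 0.903521
gpp-melt      7 0.769176
gpp-melt      8 0.660299
```

`water_balance.csv` and `water_summary.csv` hold the monthly PET−ET /
PPT−ET medians and Bowen ratios.

The same pipeline runs on real tower exports:

```bash
meltflux ingest weekly_fluxes.csv snowmelt.csv -o myrun   # FLUXNET names: --fluxnet-names
meltflux all -c run.yml
```

with a YAML config selecting months, controls, thresholds and the MCA year
window (see `meltflux.pipeline.RunConfig`).

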