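# Methods

This note documents the statistical procedures implemented in `meltflux`,
the model behind the synthetic data generator, the defaults and why they
were chosen, and the known limits of what the test suite demonstrates.

## Anomaly construction

The unit of analysis is the dimensionless **standardized anomaly**. For
each (site, week-of-year, variable) a climatology — mean and *sample* SD
(denominator n−1) — is computed over **all years available at that site**
(not a common window: sites contribute 6–19 years, and truncating to a
common window would discard most of the data). The weekly anomaly is
(obs − mean)/SD; the monthly value is the **median** of the weekly
anomalies of the weeks whose midpoint day falls in the month. Weeks are
fixed 7-day day-of-year blocks (days 1–7 = week 1, …, day 365/366 folded
into week 52) so climatologies align exactly across years; ISO weeks drift
by up to three days and would not.

Defaults and their rationale:

- `min_years = 3` for a usable climatology cell. An SD from two points
  makes ±1/√2 the only attainable anomaly magnitudes; three is the minimum
  that produces a non-degenerate distribution. Cells below the floor, or
  with zero SD, are flagged unusable and their anomalies set missing.
- `min_weeks = 2` weekly values per monthly median. One week is a
  "median" in name only.
- Month membership by the week's **midpoint** day on a non-leap calendar.
  June then contains 4 candidate weeks and August 5; the boundary-week
  convention is exposed as configuration because any choice is defensible.
- Snowmelt dates are standardized per site across its years; sites with
  fewer than `min_years` dates or zero interannual variance are dropped
  (their standardized anomaly is undefined), with a warning.

Exact identities used as tests: with complete data, each site-week's
anomalies have sample mean 0 and SD 1 to 1e-12, and the whole pipeline is
invariant to affine transforms of any one site's raw series.

## Partial correlations and the interaction test

The association between the melt anomaly and each monthly flux anomaly is
the Pearson partial correlation controlling for the solar-radiation and
air-temperature anomalies — the two dominant meteorological drivers of the
summer fluxes, which covary with melt timing. All site-years of a month are
pooled: the anomalies are already standardized within site, so pooling
"retains site as the unit of variation" without letting high-flux sites
dominate.

Implementation is the residual method (correlate the OLS residuals of x and
y on the controls, intercept included); an independent precision-matrix
route (r = −P₁₂/√(P₁₁P₂₂) from the inverse correlation matrix) is kept in
the package and asserted equal to 1e-10. Complete-case deletion is joint
across x, y and all controls. p-values are two-sided from
t = r·√((n−2−k)/(1−r²)) on n−2−k df. Fewer than k+3 complete cases yields
an explicit flagged "insufficient-n" result, never a number. No
multiple-testing correction is applied; results are masked (key kept,
value hidden) when P ≥ 0.1, strictly — P = 0.1 is masked. This mirrors a
reporting convention, not an inference procedure, and is documented as a
caveat.

Month-dependence of the melt slope is tested by the F-statistic comparing
`y ~ melt×month + controls` to `y ~ melt + month + controls` (month
categorical) on pooled complete cases of the requested months.

Calibration caveat: because climatologies are *estimated* from short
records, anomalies within a site are weakly dependent across years, and
the nominal t/F reference distributions are slightly anti-conservative.
Measured on the null synthetic world (no couplings, 11 sites × 16 years),
the empirical rejection rate at α = 0.05 is ≈ 0.058 for the partial
correlation and ≈ 0.067 for the interaction F — inflation that shrinks
with record length (≈ 0.042 at 40-year records). Users of real (short)
tower records should treat p-values near the threshold accordingly.

## Maximum covariance analysis

Two fields with years as rows and sites as columns (monthly anomalies of a
flux, and the melt anomalies) are related through their cross-covariance
matrix C; the SVD of C gives site-loading pairs ordered by explained
squared covariance, summarized by SCF_k = σ_k²/Σσ_i². Gaps and unequal
record lengths are handled by **pairwise-complete covariance**: entry
(i, j) uses the years where both sites are present (denominator n_ij−1),
and is zeroed (and flagged) when the overlap is below `min_overlap = 3`.
On complete data this is exactly the textbook (AᵀB)/(n−1) computation — a
bit-level test asserts it. A pairwise-complete C need not be positive
semidefinite, which is why the SVD (defined for any matrix) is used rather
than an eigendecomposition. A zero-imputation alternative (missing
standardized anomalies set to 0, the climatological mean, before a dense
computation) is available via `gap_method="zero_fill"` for sensitivity
analysis.

SVD sign indeterminacy is removed by flipping each mode so its
largest-magnitude left loading is positive. Expansion series project the
zero-filled fields onto the loadings. An all-zero C produces a result
flagged `undefined` — never NaN propagation and never SCF = 0, which would
be a valid-looking number. Default year window 2004–2019, the period when
most sites overlap; sites with fewer than 3 non-missing years in the
window are dropped from the field. No significance test is attached to
SCF modes (deliberately out of scope).

## Mixed models

`flux ~ melt + (1 | site)` with a Gaussian random intercept per site
accounts for pseudo-replication of repeated years within sites. Fitting is
delegated to `statsmodels.MixedLM`; the package recomputes the
log-likelihood from the compound-symmetry closed form (per-group
log det V and quadratic form via Woodbury), because optimizer-reported
likelihoods can overflow on the exact τ² = 0 boundary — a boundary the
anomaly data *systematically* approach, since per-site standardization
removes most site-level variance. Such fits are flagged `singular`, not
failed; their slope collapses to the OLS slope (asserted to 1e-6).

Conventions: REML for reported estimates, ML enforced for AIC comparison
(`compare_models` refuses REML fits and fits on differing case sets);
AIC = −2ℓ + 2p with p counting fixed effects plus both variance
components; fixed-effect p-values by Wald t on n − k df — an approximation,
as no exact small-sample df exists for mixed models. The marginal R² is
Nakagawa–Schielzeth: var(Xβ̂)/(var(Xβ̂) + τ̂² + σ̂²), with var(Xβ̂) the
sample variance (n−1) of the fixed-effect predictor.

## Water balance

Priestley–Taylor PET = α·Δ/(Δ+γ)·(Rn−G)/λ with FAO-56-style constants:
Tetens coefficients (0.6108 kPa, 17.27, 237.3 °C) for the saturation
curve slope Δ, psychrometric constant γ = 0.066 kPa °C⁻¹ (a
γ-from-pressure option would be straightforward but the sites are near sea
level), λ = 2.45 MJ kg⁻¹, α = 1.26. Negative PET (energy deficit) is
clipped to zero with a logged count. A hand-derived reference pins the
implementation: T = 15 °C, Rn = 10 MJ m⁻² d⁻¹, G = 0 gives
Δ ≈ 0.1098 kPa °C⁻¹, Δ/(Δ+γ) ≈ 0.6246, PET ≈ 3.2119 mm d⁻¹.

When no measured net radiation is available (as in the synthetic world),
weekly PET uses Rn ≈ 0.6 × incoming shortwave as an all-wave surrogate.
Monthly balances sum PET, ET and precipitation per site-month; rows with
under 80% of expected days/weeks are flagged incomplete and excluded from
summaries by default. The identities pet_minus_et = pet − et and
ppt_minus_et = ppt − et hold exactly on every row. The Bowen ratio is
computed per week as the ratio of weekly mean H to LE (masked when
|LE| < 5 W m⁻², where the ratio explodes), then medianed within each
month; cross-site seasonal summaries are medians throughout. Runoff is not
modelled.

## The synthetic world

The generator emulates a circumpolar tundra tower network: 11 sites with
6–19 years each (119 site-years, ending 2019), weekly resolution — the
smallest unit the analysis touches. Each site has sinusoidal air-T and
shortwave annual cycles, bell-shaped GPP/ER/ET seasonal baselines with
site-specific amplitudes, and standard-normal weekly weather anomalies.
Snowmelt anomalies are √ρ·g_y + √(1−ρ)·e_sy with a regional year effect
g_y shared across sites (ρ = 0.6): melt timing is regionally synchronized,
and without cross-site correlation the melt–flux cross-covariance would be
diagonal and the MCA's first mode meaningless. Each flux variable's weekly
anomaly is β_m·z + c_rg·r + c_ta·t + ε, with the melt coupling β_m active
only in June–August of the same year (same-summer associations only, no
carry-over). Raw values are climatology + scale × anomaly, clipped to
physical ranges; NEE = ER − GPP holds exactly pre-missingness, with the
GPP and ER noise draws correlated at 0.8 (the same warm productive weeks
drive both fluxes; without that correlation the NEE channel would carry
implausibly little signal relative to its components). Missingness is
completely at random (default 5%), applied after generation without
touching keys.

Default couplings (standardized units per melt-anomaly SD): July and
August magnitudes were calibrated by simulation so the population
monthly-median partial correlations sit near observed tundra values
(GPP ≈ −0.33 in July and +0.27 in August; ER ≈ −0.34 and ≈ 0); the June
magnitudes (GPP −0.55, ER −0.35) were then set by a power analysis so that
the early-season coupling dominates the late season strongly enough for
the June > August SCF ordering to be recoverable in ≈ 98% of realizations
at 11 sites × 16 years — the criterion the validation suite demands. ET
and soil moisture couple to melt in June only (post-melt surface wetness),
negatively; VPD not at all. The closed-form implied partial correlation
β/√(β² + σ_noise²) (with NEE by propagation through ER − GPP, including
the noise correlation) serves as the oracle for recovery tests; note it is
the *week-level* value — monthly medianing shrinks noise, so pipeline
estimates are larger in magnitude but share the sign.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: temporal autocorrelation of weather and
flux anomalies within a season; non-Gaussian flux error distributions;
instrument-failure (block) missingness — available via
``apply_missingness(..., block_length=...)`` but off by default;
energy-balance closure error;
spatially correlated *weather* anomalies; any causal structure beyond the
linear couplings. Recovery of the sign pattern here shows the pipeline is
correct, not that the field data satisfy its assumptions.

## Reproducibility and problem sizes

Every random draw flows from one seed (sub-seeds derived
deterministically), and a full pipeline run writes a manifest with content
hashes; two runs from the same (config, seed) are byte-identical. The
validation suite uses 100 generator seeds for the coupling-recovery rates
and 500 for the null calibration, sizes at which the Monte-Carlo error of
a rejection-rate estimate (≈ 0.01 at 500 draws, smaller after pooling the
independent-noise responses and months) is well below the width of the
calibration band being checked; `scripts/acceptance.py` defaults to
100/200 seeds for the same rates.
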