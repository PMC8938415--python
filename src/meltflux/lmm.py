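"""Linear mixed-effects fits of monthly anomalies on snowmelt anomalies.

Each model regresses a monthly-median flux anomaly on the standardized
snowmelt-date anomaly (plus optional extra fixed terms) with a random
intercept per site, accounting for the pseudo-replication of repeated years
within a site.  Fits use REML by default for reported estimates; model
comparison by AIC requires maximum-likelihood fits on the identical
complete-case dataset, which :func:`compare_models` enforces.

The explanatory power of the fixed effects is summarised by the marginal
R-squared in the Nakagawa-Schielzeth sense: the variance of the fixed-effect
linear predictor over the total of fixed, random-intercept and residual
variances.

AIC is computed as ``-2*loglik + 2*p`` with ``p`` counting fixed-effect
coefficients plus variance components (random-intercept variance and
residual variance), matching the parameter count used by nlme-style mixed
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .errors import DegenerateInputError, InsufficientDataError
from .association import _month_wide
from .weeks import normalize_month

__all__ = ["MixedModelResult", "fit_lmm", "marginal_r2", "compare_models",
           "mixed_loglik"]


@dataclass
class MixedModelResult:
    """One mixed-model fit: response ~ fixed terms + (1 | site)."""

    response: str
    month: int
    fixed_terms: tuple
    beta: dict                 # term -> estimate
    se: dict                   # term -> standard error
    p_fixed: dict              # term -> two-sided Wald-t p-value
    var_fixed: float
    var_random: float
    var_resid: float
    llf: float
    aic: float
    reml: bool
    n: int
    n_sites: int
    singular: bool = False
    case_keys: tuple = field(default_factory=tuple, repr=False)

    @property
    def r2_marginal(self) -> float:
        return marginal_r2(self.var_fixed, self.var_random, self.var_resid)


def fit_lmm(anomalies: pd.DataFrame, melt: pd.DataFrame, response: str,
            month, reml: bool = True, extra_fixed=(),
            min_cases: int = 10) -> MixedModelResult:
    """Fit ``response ~ melt_anomaly [+ extra] + (1 | site)`` for one month.

    A boundary fit with (near-)zero random-intercept variance is flagged
    ``singular`` rather than treated as an error; its slope collapses to the
    ordinary least squares slope.
    """
    m = normalize_month(month)
    wide = _month_wide(anomalies, melt, m)
    terms = ["melt_anomaly", *extra_fixed]
    cols = [response, *terms]
    missing = [c for c in cols if c not in wide.columns]
    if missing:
        raise InsufficientDataError(f"columns absent for month {m}: {missing}")
    df = wide.dropna(subset=cols).reset_index(drop=True)
    if len(df) < min_cases:
        raise InsufficientDataError(
            f"mixed model needs >= {min_cases} complete cases, got {len(df)}")
    if df[response].std() == 0:
        raise DegenerateInputError(f"response {response!r} is constant")

    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.mixedlm(formula, df, groups=df["site_id"])
    with warnings.catch_warnings():
        # boundary fits (zero random variance) are expected and flagged below
        warnings.simplefilter("ignore")
        fit = None
        last_err = None
        for method in (None, "lbfgs", "powell", "nm"):
            try:
                kwargs = {} if method is None else {"method": method}
                fit = model.fit(reml=reml, **kwargs)
                if np.isfinite(fit.fe_params).all():
                    break
            except Exception as err:   # optimizer hit a singular region
                last_err = err
                fit = None
        if fit is None:
            raise DegenerateInputError(
                f"mixed model failed to converge for {response!r} "
                f"month {m}: {last_err}")

    fe_names = [n for n in fit.fe_params.index]
    beta = {n: float(fit.fe_params[n]) for n in fe_names}
    se = {n: float(fit.bse_fe[n]) for n in fe_names}
    n = len(df)
    k = len(fe_names)
    # Wald t on residual-df approximation (n - k); the exact small-sample df
    # for mixed models is not uniquely defined
    dof = max(n - k, 1)
    p_fixed = {nm: float(2 * stats.t.sf(abs(beta[nm] / se[nm]), dof))
               if se[nm] > 0 else float("nan") for nm in fe_names}

    var_resid = float(fit.scale)
    var_random = max(0.0, float(np.asarray(fit.cov_re)[0, 0]))
    X = np.column_stack([np.ones(n)] + [df[t].to_numpy(float) for t in terms])
    b = np.array([beta["Intercept"], *(beta[t] for t in terms)])
    eta = X @ b
    var_fixed = float(np.var(eta, ddof=1))

    # log-likelihood from the compound-symmetry closed form (finite even on
    # the tau^2 = 0 boundary, where optimizer-reported values can overflow)
    y = df[response].to_numpy(float)
    groups = df["site_id"].to_numpy()
    llf = mixed_loglik(y, X, groups, b, var_random, var_resid, reml=reml)
    p_count = k + 2                       # variance components: tau^2, sigma^2
    aic = float(-2.0 * llf + 2.0 * p_count)
    singular = var_random < 1e-8 * max(var_resid + var_random, 1e-300)

    keys = tuple(sorted(zip(df["site_id"], df["year"])))
    return MixedModelResult(
        response=response, month=m, fixed_terms=tuple(terms), beta=beta,
        se=se, p_fixed=p_fixed, var_fixed=var_fixed, var_random=var_random,
        var_resid=var_resid, llf=llf, aic=aic, reml=reml, n=n,
        n_sites=df["site_id"].nunique(), singular=singular, case_keys=keys)


def mixed_loglik(y, X, groups, beta, tau2: float, sigma2: float,
                 reml: bool = False) -> float:
    """Log-likelihood of a random-intercept model, closed form.

    With per-group covariance ``V_i = sigma2 * I + tau2 * J`` the
    determinant and quadratic form reduce (Woodbury) to

        logdet V_i = (n_i - 1) log sigma2 + log(sigma2 + n_i tau2)
        r' V_i^-1 r = (r'r - tau2 * (sum r)^2 / (sigma2 + n_i tau2)) / sigma2

    For ``reml=True`` the restricted likelihood subtracts the fixed-effect
    information term ``0.5 * logdet(X' V^-1 X)`` and uses n - p in the
    2*pi constant.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    if sigma2 <= 0:
        return float("-inf")
    n, p = X.shape
    resid = y - X @ beta
    logdet = 0.0
    quad = 0.0
    XtVinvX = np.zeros((p, p))
    for g in pd.unique(groups):
        idx = groups == g
        r = resid[idx]
        Xg = X[idx]
        ni = len(r)
        w = sigma2 + ni * tau2
        logdet += (ni - 1) * np.log(sigma2) + np.log(w)
        quad += (r @ r - tau2 * r.sum() ** 2 / w) / sigma2
        XtVg = (Xg.T @ Xg - tau2 * np.outer(Xg.sum(0), Xg.sum(0)) / w) / sigma2
        XtVinvX += XtVg
    ll = -0.5 * ((n - p if reml else n) * np.log(2 * np.pi) + logdet + quad)
    if reml:
        ll -= 0.5 * np.linalg.slogdet(XtVinvX)[1]
    return float(ll)


def marginal_r2(var_fixed: float, var_random: float, var_resid: float) -> float:
    """Marginal R-squared: var_fixed / (var_fixed + var_random + var_resid).

    The fraction of total variance attributable to the fixed effects
    (Nakagawa-Schielzeth definition for a Gaussian mixed model).  Undefined
    (NaN) when all three components are zero.
    """
    for name, v in (("var_fixed", var_fixed), ("var_random", var_random),
                    ("var_resid", var_resid)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    total = var_fixed + var_random + var_resid
    if total == 0:
        return float("nan")
    return float(var_fixed / total)


def compare_models(results) -> pd.DataFrame:
    """Rank ML fits by AIC (delta AIC relative to the best).

    Refuses REML fits (their likelihoods are not comparable across fixed
    structures) and fits whose complete-case datasets differ.
    """
    results = list(results)
    if not results:
        raise ValueError("no models to compare")
    if any(r.reml for r in results):
        raise ValueError(
            "AIC comparison requires maximum-likelihood fits; got REML "
            f"fits for: {[r.response for r in results if r.reml]}")
    ref = results[0].case_keys
    for r in results[1:]:
        if r.case_keys != ref:
            raise ValueError(
                "models were fit on different complete-case datasets "
                f"({results[0].response} vs {r.response}); refit on the "
                "common cases before comparing AIC")
    rows = [{"response": r.response, "month": r.month,
             "fixed": "+".join(r.fixed_terms), "aic": r.aic,
             "r2_marginal": r.r2_marginal, "n": r.n} for r in results]
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return table.sort_values("delta_aic", kind="stable").reset_index(drop=True)
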