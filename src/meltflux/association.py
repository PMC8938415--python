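"""Partial correlations between snowmelt timing and monthly flux anomalies.

The association between the standardized snowmelt-date anomaly and each
monthly-median flux/hydrology anomaly is measured by the Pearson partial
correlation controlling for the main meteorological forcings (solar
radiation and air temperature anomalies), separately per summer month,
pooling all site-years (anomalies are already standardized within site, so
pooling retains site as the unit of variation).

Two routes to the same number are implemented — the residual method
(correlate the OLS residuals of x and y on the controls) and the precision
route (from the inverse of the joint correlation matrix).  They agree to
numerical precision and serve as mutual cross-checks.

Month-dependence of the slope is tested with an F-test comparing the linear
model ``response ~ melt * month + controls`` against the no-interaction
model, and reported results follow the convention that r and P are shown
only when P < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError
from .weeks import SUMMER_MONTHS, normalize_month

__all__ = [
    "PartialCorrResult",
    "InteractionTestResult",
    "partial_correlation",
    "partial_correlation_precision",
    "monthly_partial_correlations",
    "interaction_test",
    "reporting_filter",
]

DEFAULT_CONTROLS = ("rg", "air_t")


@dataclass
class PartialCorrResult:
    """One partial-correlation row (Table-1-style)."""

    response: str
    predictor: str
    controls: tuple
    month: int
    r: float | None
    p: float | None
    n: int
    reported: bool = True
    note: str = ""

    def as_row(self) -> dict:
        return {"response": self.response, "predictor": self.predictor,
                "controls": "+".join(self.controls), "month": self.month,
                "r": self.r, "p": self.p, "n": self.n,
                "reported": self.reported, "note": self.note}


@dataclass
class InteractionTestResult:
    """F-test of the month x snowmelt interaction."""

    response: str
    f_stat: float
    df_num: int
    df_den: int
    p: float
    n: int
    months: tuple = SUMMER_MONTHS


def _complete_cases(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        mask &= np.isfinite(a if a.ndim == 1 else a.sum(axis=1))
    return mask


def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), controls])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ coef


def partial_correlation(x, y, controls=None) -> tuple[float, float, int]:
    """Pearson partial correlation of x and y given control columns.

    Residual method: x and y are each regressed (OLS with intercept) on the
    controls and the residuals correlated.  The two-sided p-value uses
    ``t = r * sqrt((n - 2 - k) / (1 - r^2))`` on n - 2 - k degrees of
    freedom, with k the number of controls.

    Rows with any missing value across x, y and the controls are removed
    jointly.  Raises :class:`InsufficientDataError` when fewer than k + 3
    complete cases remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or (np.size(controls) == 0):
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(controls, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    mask = _complete_cases(x, y) & np.isfinite(C).all(axis=1)
    x, y, C = x[mask], y[mask], C[mask]
    n, k = len(x), C.shape[1]
    if n < k + 3:
        raise InsufficientDataError(
            f"partial correlation needs >= {k + 3} complete cases, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("x or y is constant after case deletion")

    rx = _residualize(x, C)
    ry = _residualize(y, C)
    # residuals that are numerically zero relative to the centred variable
    # mean x or y is (exactly) linear in the controls: partial r is 0
    ss_x = np.sum((x - x.mean()) ** 2)
    ss_y = np.sum((y - y.mean()) ** 2)
    if (rx @ rx) <= 1e-24 * max(ss_x, 1e-300) or \
            (ry @ ry) <= 1e-24 * max(ss_y, 1e-300):
        return 0.0, 1.0, n
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, n


def partial_correlation_precision(x, y, controls=None) -> float:
    """Partial correlation via the inverse of the joint correlation matrix.

    Independent algebraic route used to cross-check the residual method:
    with P the inverse of the correlation matrix of (x, y, controls),
    ``r = -P_xy / sqrt(P_xx * P_yy)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or np.size(controls) == 0:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(controls, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    mask = _complete_cases(x, y) & np.isfinite(C).all(axis=1)
    M = np.column_stack([x[mask], y[mask], C[mask]])
    P = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


def monthly_partial_correlations(anomalies: pd.DataFrame, melt: pd.DataFrame,
                                 responses, month,
                                 controls=DEFAULT_CONTROLS) -> list[PartialCorrResult]:
    """Partial correlation of each response anomaly with the melt anomaly.

    One result per response for the given month, pooling all site-years.
    Responses with too few complete cases yield a flagged insufficient-n
    result rather than a number.
    """
    m = normalize_month(month)
    if m not in SUMMER_MONTHS:
        raise ValueError(f"month must be June-August (6-8), got {m}")
    wide = _month_wide(anomalies, melt, m)
    results = []
    for resp in responses:
        cols = [resp, "melt_anomaly", *controls]
        missing_cols = [c for c in cols if c not in wide.columns]
        if missing_cols or wide.empty:
            results.append(PartialCorrResult(
                resp, "melt_anomaly", tuple(controls), m, None, None, 0,
                reported=False, note="insufficient_n"))
            continue
        try:
            r, p, n = partial_correlation(
                wide["melt_anomaly"], wide[resp],
                wide[list(controls)].to_numpy() if controls else None)
        except (InsufficientDataError, DegenerateInputError) as err:
            results.append(PartialCorrResult(
                resp, "melt_anomaly", tuple(controls), m, None, None, 0,
                reported=False, note=f"insufficient_n: {err}"))
            continue
        results.append(PartialCorrResult(
            resp, "melt_anomaly", tuple(controls), m, r, p, n))
    return results


def _month_wide(anomalies: pd.DataFrame, melt: pd.DataFrame,
                month: int) -> pd.DataFrame:
    """Site-year wide table of anomalies for one month, joined with melt."""
    sub = anomalies[anomalies["month"] == month]
    wide = sub.pivot_table(index=["site_id", "year"], columns="variable",
                           values="anomaly", aggfunc="first").reset_index()
    return wide.merge(melt, on=["site_id", "year"], how="inner")


def interaction_test(anomalies: pd.DataFrame, melt: pd.DataFrame,
                     response: str, controls=DEFAULT_CONTROLS,
                     months=SUMMER_MONTHS) -> InteractionTestResult:
    """F-test for a month-dependent snowmelt slope.

    Compares ``response ~ melt * month + controls`` against
    ``response ~ melt + month + controls`` (month categorical) on the pooled
    complete cases of the requested months.
    """
    months = tuple(normalize_month(m) for m in months)
    frames = []
    for m in months:
        w = _month_wide(anomalies, melt, m)
        if not w.empty:
            w = w.assign(month=m)
            frames.append(w)
    if not frames:
        raise InsufficientDataError("no data in the requested months")
    df = pd.concat(frames, ignore_index=True)
    cols = [response, "melt_anomaly", *controls]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise InsufficientDataError(f"columns absent: {missing_cols}")
    df = df.dropna(subset=cols)
    present = sorted(df["month"].unique())
    if len(present) < 2:
        raise DegenerateInputError(
            f"interaction test needs >= 2 months with data, got {present}")
    y = df[response].to_numpy()
    if np.std(y) == 0:
        raise DegenerateInputError(f"response {response!r} is constant")

    n = len(df)
    x = df["melt_anomaly"].to_numpy()
    C = df[list(controls)].to_numpy() if controls else np.empty((n, 0))
    # month dummies (first month as reference)
    dummies = np.column_stack([(df["month"] == m).to_numpy(float)
                               for m in present[1:]])
    X0 = np.column_stack([np.ones(n), x, dummies, C])
    X1 = np.column_stack([X0] + [x[:, None] * dummies])
    rss0 = _rss(X0, y)
    rss1 = _rss(X1, y)
    df_num = X1.shape[1] - X0.shape[1]
    df_den = n - X1.shape[1]
    if df_den < 1:
        raise InsufficientDataError("not enough cases for the interaction F-test")
    f = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return InteractionTestResult(response, float(f), df_num, df_den, p, n,
                                 tuple(present))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def reporting_filter(results, alpha: float = 0.1) -> list[PartialCorrResult]:
    """Mask r and P where P >= alpha (strict inequality: P = alpha is masked).

    Keys are retained; masked results carry ``reported=False`` with the
    original n, mirroring the convention of showing r and P only when
    P < 0.1.
    """
    out = []
    for res in results:
        if res.p is not None and res.p < alpha:
            out.append(replace(res, reported=True))
        else:
            out.append(replace(res, r=None, p=None, reported=False,
                               note=res.note or "p>=alpha"))
    return out


def results_table(results) -> pd.DataFrame:
    """Tidy DataFrame of partial-correlation results (Table-1-style layout)."""
    return pd.DataFrame([r.as_row() for r in results])
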