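"""Maximum covariance analysis (MCA) of paired site x year anomaly fields.

MCA takes two space-time fields — here, years as rows and tower sites as
columns, values being monthly-median standardized anomalies — forms their
cross-covariance matrix, and decomposes it by SVD.  The leading pair of
singular vectors are the site-weight patterns whose projected time series
have the largest possible cross-covariance, and the squared covariance
fraction (SCF) of mode k, ``scf_k = sigma_k^2 / sum_i sigma_i^2``, measures
how strongly the two variables co-vary over time across the network.

Records with gaps and unequal lengths are handled by a pairwise-complete
cross-covariance: entry (i, j) is computed over the years where both site i
of field A and site j of field B are present (denominator n_ij - 1), falling
back to 0 (and flagged) when the overlap is below ``min_overlap``.  A
pairwise-complete matrix is not guaranteed positive semidefinite, which is
why SVD (defined for any matrix) is used rather than an eigendecomposition.
An alternative zero-fill strategy (missing standardized anomalies treated as
0, i.e. climatological mean, before a dense computation) is available for
sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .weeks import normalize_month

__all__ = [
    "AnomalyField",
    "McaResult",
    "build_field",
    "build_snowmelt_field",
    "cross_covariance",
    "run_mca",
    "scf_table",
]


@dataclass
class AnomalyField:
    """A years x sites matrix of standardized anomalies (NaN = missing)."""

    variable: str
    month: int | None
    years: np.ndarray          # row labels
    site_ids: list[str]        # column labels
    values: np.ndarray         # shape (n_years, n_sites), float with NaN

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.years), len(self.site_ids)):
            raise ValueError("field shape does not match labels")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids in field")
        if len(set(self.years.tolist())) != len(self.years):
            raise ValueError("duplicate years in field")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.years, columns=self.site_ids)


@dataclass
class McaResult:
    """SVD modes of one cross-covariance matrix (one variable pair x month)."""

    pair: tuple[str, str]
    month: int | None
    singular_values: np.ndarray        # descending, >= 0
    scf: np.ndarray | None             # fractions summing to 1, or None if undefined
    left_loadings: np.ndarray          # (n_sites_a, n_modes), unit columns
    right_loadings: np.ndarray         # (n_sites_b, n_modes), unit columns
    left_series: pd.DataFrame          # year x mode expansion series
    right_series: pd.DataFrame
    n_overlap: np.ndarray              # pairwise sample counts
    undefined: bool = False

    @property
    def scf1(self) -> float | None:
        return None if self.undefined else float(self.scf[0])


def build_field(anomalies: pd.DataFrame, variable: str, month,
                year_range, min_site_years: int = 3) -> AnomalyField:
    """Pivot the monthly anomaly table into a years x sites field.

    Sites with fewer than ``min_site_years`` non-missing years in the range
    are dropped; fewer than 2 surviving sites (or an empty year range) is a
    degenerate-field error.
    """
    years = np.asarray(sorted(year_range), dtype=int)
    if years.size == 0:
        raise DegenerateInputError("empty year range")
    m = normalize_month(month)
    sub = anomalies[(anomalies["variable"] == variable)
                    & (anomalies["month"] == m)
                    & (anomalies["year"].isin(years))]
    wide = sub.pivot_table(index="year", columns="site_id", values="anomaly",
                           aggfunc="first")
    wide = wide.reindex(index=years)
    keep = wide.notna().sum(axis=0) >= min_site_years
    dropped = [c for c, k in keep.items() if not k]
    if dropped:
        logging.getLogger(__name__).info(
            "field %s/%s: dropped sites with < %d years: %s",
            variable, m, min_site_years, dropped)
    wide = wide.loc[:, keep]
    if wide.shape[1] < 2:
        raise DegenerateInputError(
            f"field {variable}/{m}: fewer than 2 sites survive pruning")
    return AnomalyField(variable, m, wide.index.to_numpy(),
                        list(wide.columns), wide.to_numpy())


def build_snowmelt_field(melt: pd.DataFrame, year_range, month=None,
                         min_site_years: int = 3) -> AnomalyField:
    """Field of standardized snowmelt anomalies (the same for every month)."""
    years = np.asarray(sorted(year_range), dtype=int)
    if years.size == 0:
        raise DegenerateInputError("empty year range")
    sub = melt[melt["year"].isin(years)]
    wide = sub.pivot_table(index="year", columns="site_id",
                           values="melt_anomaly", aggfunc="first")
    wide = wide.reindex(index=years)
    keep = wide.notna().sum(axis=0) >= min_site_years
    wide = wide.loc[:, keep]
    if wide.shape[1] < 2:
        raise DegenerateInputError("snowmelt field: fewer than 2 sites survive")
    return AnomalyField("melt", month, wide.index.to_numpy(),
                        list(wide.columns), wide.to_numpy())


def cross_covariance(a: AnomalyField, b: AnomalyField,
                     min_overlap: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete cross-covariance matrix between two fields.

    Entry (i, j) is the sample covariance (denominator n_ij - 1) of site i
    of ``a`` with site j of ``b`` over the years where both are present;
    entries with overlap below ``min_overlap`` are set to 0.  On complete
    data this equals the textbook ``A_c.T @ B_c / (n - 1)``.

    Returns ``(C, n_overlap)``.
    """
    shared, ia, ib = np.intersect1d(a.years, b.years, return_indices=True)
    if shared.size == 0:
        raise DegenerateInputError("fields share no years")
    A = a.values[ia]
    B = b.values[ib]
    ma = np.isfinite(A)
    mb = np.isfinite(B)
    A0 = np.where(ma, A, 0.0)
    B0 = np.where(mb, B, 0.0)
    n_ov = ma.astype(float).T @ mb.astype(float)          # (sites_a, sites_b)
    s_ab = A0.T @ B0
    s_a = A0.T @ mb.astype(float)
    s_b = ma.astype(float).T @ B0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = s_a / n_ov
        mean_b = s_b / n_ov
        cov = (s_ab - n_ov * mean_a * mean_b) / (n_ov - 1.0)
    bad = (n_ov < min_overlap) | ~np.isfinite(cov)
    cov = np.where(bad, 0.0, cov)
    return cov, n_ov.astype(int)


def run_mca(a: AnomalyField, b: AnomalyField, min_overlap: int = 3,
            gap_method: str = "pairwise") -> McaResult:
    """MCA of two anomaly fields: SVD of their cross-covariance.

    ``gap_method`` selects the gap treatment: ``"pairwise"`` (default,
    pairwise-complete covariance) or ``"zero_fill"`` (missing standardized
    anomalies set to 0 before a dense covariance).  Mode signs are fixed so
    that each mode's largest-magnitude left loading is positive.  Expansion
    series project the (zero-filled) fields on the loadings.
    """
    if gap_method == "pairwise":
        C, n_ov = cross_covariance(a, b, min_overlap=min_overlap)
    elif gap_method == "zero_fill":
        shared, ia, ib = np.intersect1d(a.years, b.years, return_indices=True)
        if shared.size == 0:
            raise DegenerateInputError("fields share no years")
        A = np.nan_to_num(a.values[ia])
        B = np.nan_to_num(b.values[ib])
        n = len(shared)
        C = (A - A.mean(0)).T @ (B - B.mean(0)) / (n - 1.0)
        ma = np.isfinite(a.values[ia])
        n_ov = (ma.astype(float).T @ np.isfinite(b.values[ib]).astype(float)).astype(int)
    else:
        raise ValueError(f"unknown gap_method {gap_method!r}")

    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    V = Vt.T
    # sign convention: largest-|left-loading| element positive, per mode
    for k in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, k])))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]

    total = float(np.sum(s ** 2))
    undefined = not total > 0
    scf = None if undefined else (s ** 2) / total

    A_fill = np.nan_to_num(a.values)
    B_fill = np.nan_to_num(b.values)
    modes = [f"mode{k + 1}" for k in range(len(s))]
    left_series = pd.DataFrame(A_fill @ U, index=a.years, columns=modes)
    right_series = pd.DataFrame(B_fill @ V, index=b.years, columns=modes)
    return McaResult(pair=(a.variable, b.variable), month=a.month,
                     singular_values=s, scf=scf,
                     left_loadings=U, right_loadings=V,
                     left_series=left_series, right_series=right_series,
                     n_overlap=n_ov, undefined=undefined)


def scf_table(results: dict) -> pd.DataFrame:
    """First-mode SCF per (variable pair, month), Fig.-3-style.

    ``results`` maps keys (pair label, month) -> McaResult; input ordering is
    preserved.  Undefined results appear with a missing SCF and an
    ``undefined`` flag, never as 0.
    """
    rows = []
    for key, res in results.items():
        pair, month = key if isinstance(key, tuple) else (key, res.month)
        rows.append({
            "pair": pair if isinstance(pair, str) else "-".join(res.pair),
            "month": month,
            "scf1": np.nan if res.undefined else float(res.scf[0]),
            "sigma1": float(res.singular_values[0]) if len(res.singular_values) else np.nan,
            "undefined": res.undefined,
        })
    return pd.DataFrame(rows)
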