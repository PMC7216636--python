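"""Descriptive summaries: ICCs and hybrid between/within correlation tables.

The intraclass correlation of a repeated measure comes from a null
two-level model (random subject intercept only) estimated by maximum
likelihood; ICC = between-variance / (between + within).  The correlation
table reports Pearson correlations of person means (between-subject,
upper triangle), pooled correlations of within-person deviations (lower
triangle), and ICCs on the diagonal -- the layout conventionally used for
EMA descriptive tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "IccResult",
    "variance_components_icc",
    "BwCorrMatrix",
    "between_within_correlations",
    "summary_table",
]


@dataclass(frozen=True)
class IccResult:
    between_variance: float
    within_variance: float
    loglik: float

    def __post_init__(self):
        if self.between_variance < 0 or self.within_variance < 0:
            raise ValueError("variances must be non-negative")

    @property
    def icc(self) -> float:
        tot = self.between_variance + self.within_variance
        return self.between_variance / tot if tot > 0 else 0.0


def _null_model_nll(logvars, ybar, yss, ns):
    """-2 loglik (up to constant) of the one-way random-intercept model.

    Uses the compound-symmetry closed form per subject with the grand mean
    profiled out by GLS.  ``ybar``/``yss``/``ns`` are per-subject means,
    within sums of squares, and counts.
    """
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        vb, vw = np.exp(logvars)
        denom = vw + ns * vb
        w = ns / denom
        mu = float(np.sum(w * ybar) / np.sum(w))
        logdet = np.sum((ns - 1) * np.log(vw) + np.log(denom))
        quad = np.sum(yss) / vw + np.sum(ns * (ybar - mu) ** 2 / denom)
        val = logdet + quad
    return val if np.isfinite(val) else 1e12


def variance_components_icc(values, subjects) -> IccResult:
    """ML variance components of a repeated measure grouped by subject."""
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    keep = ~np.isnan(values)
    values, subjects = values[keep], subjects[keep]
    uniq, inv, ns = np.unique(subjects, return_inverse=True, return_counts=True)
    if len(uniq) < 2 or (ns >= 2).sum() < 2:
        raise ValueError("ICC needs >= 2 subjects with >= 2 observations each")
    if np.var(values) == 0:
        raise ValueError("ICC undefined for a constant variable")
    ybar = np.bincount(inv, weights=values) / ns
    yss = np.bincount(inv, weights=(values - ybar[inv]) ** 2)
    ns = ns.astype(float)

    # ANOVA moment start
    vw0 = float(np.sum(yss) / max(np.sum(ns - 1), 1))
    vt = float(np.var(values, ddof=1))
    vb0 = max(vt - vw0, 1e-3 * vt)
    res = optimize.minimize(_null_model_nll, np.log([vb0, max(vw0, 1e-3 * vt)]),
                            args=(ybar, yss, ns), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 2000})
    vb, vw = np.exp(res.x)
    n_tot = len(values)
    ll = -0.5 * (res.fun + n_tot * np.log(2 * np.pi))
    return IccResult(float(vb), float(vw), float(ll))


@dataclass(frozen=True)
class BwCorrMatrix:
    variables: tuple
    between: pd.DataFrame   # correlations of person means
    within: pd.DataFrame    # pooled correlations of deviations
    iccs: pd.Series

    def to_frame(self) -> pd.DataFrame:
        """Hybrid table: between above the diagonal, within below, ICC on it."""
        k = len(self.variables)
        out = pd.DataFrame(np.full((k, k), np.nan), index=self.variables,
                           columns=self.variables)
        for i, vi in enumerate(self.variables):
            for j, vj in enumerate(self.variables):
                if i < j:
                    out.iloc[i, j] = self.between.loc[vi, vj]
                elif i > j:
                    out.iloc[i, j] = self.within.loc[vi, vj]
                else:
                    out.iloc[i, j] = self.iccs[vi]
        return out


def _corr_with_missing_guard(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    corr = df.corr()
    for v in df.columns[sd == 0]:
        corr.loc[v, :] = np.nan
        corr.loc[:, v] = np.nan
    return corr


def between_within_correlations(df: pd.DataFrame, variables,
                                subject_col: str = "dyad_id") -> BwCorrMatrix:
    """Between-subject and pooled within-subject correlation matrices.

    Between entries correlate subjects' person means; within entries
    correlate the stacked within-person deviations.  Constant variables
    yield missing entries rather than errors.
    """
    variables = tuple(variables)
    g = df.groupby(subject_col)[list(variables)]
    means = g.mean()
    devs = df[list(variables)] - g.transform("mean")
    between = _corr_with_missing_guard(means)
    within = _corr_with_missing_guard(devs)
    def _icc(v):
        try:
            return variance_components_icc(df[v], df[subject_col]).icc
        except ValueError:
            return np.nan

    iccs = pd.Series({v: _icc(v) for v in variables})
    return BwCorrMatrix(variables, between, within, iccs)


def summary_table(df: pd.DataFrame, variables,
                  subject_col: str = "dyad_id") -> pd.DataFrame:
    """Mean, SD, median (linear interpolation), observed min-max per variable."""
    rows = []
    for v in variables:
        x = df[v].dropna()
        rows.append({
            "variable": v,
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "median": float(np.percentile(x, 50)),
            "min": float(x.min()),
            "max": float(x.max()),
        })
    return pd.DataFrame(rows)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided t-test p-value for a Pearson correlation."""
    if not np.isfinite(r) or n < 3 or abs(r) >= 1:
        return np.nan
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))
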