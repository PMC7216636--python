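"""Affect composites, reliability, person-mean centering and Box-Cox.

Momentary positive/negative affect is measured with 2-3 items on a 1-4
scale; composites are plain item means (listwise within prompt).  Repeated
composites are split into a between-person component (the person mean over
all of that subject's included prompts) and a within-person deviation,
which become separate predictors in the dyadic model.  MVPA minutes are
strongly right-skewed and go through a Box-Cox power transform before
modeling; sedentary minutes stay in raw minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "score_composite",
    "ReliabilityResult",
    "omega_reliability",
    "sample_skewness",
    "BoxCoxResult",
    "boxcox_transform",
    "apply_boxcox",
    "inverse_boxcox",
    "CenteredPredictor",
    "person_center",
    "add_person_centered",
]


def score_composite(items: pd.DataFrame) -> pd.Series:
    """Row-wise mean of affect items; missing any item -> missing composite."""
    vals = items.to_numpy(dtype=float)
    out = vals.mean(axis=1)
    out[np.isnan(vals).any(axis=1)] = np.nan
    return pd.Series(out, index=items.index)


# --------------------------------------------------------------------------
# Reliability (McDonald's omega from a one-factor model)


@dataclass(frozen=True)
class ReliabilityResult:
    omega: float
    method: str
    loadings: np.ndarray
    uniquenesses: np.ndarray

    def __post_init__(self):
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError("omega must lie in [0, 1]")


def _one_factor_ml(S: np.ndarray, max_iter: int = 500):
    """ML one-factor model on a covariance matrix: S ~ ll' + diag(psi)."""
    p = S.shape[0]
    # principal-factor start
    w, V = np.linalg.eigh(S)
    lam0 = V[:, -1] * np.sqrt(max(w[-1], 1e-8))
    if lam0.sum() < 0:
        lam0 = -lam0
    psi0 = np.clip(np.diag(S) - lam0 ** 2, 1e-4 * np.diag(S), None)
    x0 = np.concatenate([lam0, np.log(psi0)])

    def nll(x):
        lam, psi = x[:p], np.exp(x[p:])
        Sigma = np.outer(lam, lam) + np.diag(psi)
        try:
            cho = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2 * np.sum(np.log(np.diag(cho)))
        inv_S = np.linalg.solve(cho.T, np.linalg.solve(cho, S))
        val = logdet + np.trace(inv_S)
        return val if np.isfinite(val) else 1e10

    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": 1e-12})
    lam, psi = res.x[:p], np.exp(res.x[p:])
    if lam.sum() < 0:
        lam = -lam
    return lam, psi


def omega_reliability(items: pd.DataFrame) -> ReliabilityResult:
    """McDonald's omega of an item set from a one-factor model.

    For >= 3 items, omega = (sum lambda)^2 / ((sum lambda)^2 + sum theta)
    from a maximum-likelihood one-factor solution on the item covariance.
    For 2 items the factor model is under-identified, so equal standardized
    loadings are imposed, making omega the Spearman-Brown value 2r/(1+r).
    """
    X = items.dropna().to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("omega needs at least 2 items")
    if X.shape[0] < 30:
        raise ValueError("omega needs at least 30 complete rows")
    S = np.cov(X, rowvar=False)
    if (np.diag(S) <= 0).any():
        raise ValueError("every item needs positive variance")
    if X.shape[1] == 2:
        # perfectly correlated items are allowed here (omega = 1)
        r = float(S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]))
        r = min(r, 1.0)
        if r <= 0:
            raise ValueError("2-item omega undefined for non-positive correlation")
        lam = np.sqrt(r) * np.ones(2)           # standardized equal loadings
        psi = (1 - r) * np.ones(2)
        omega = (lam.sum() ** 2) / (lam.sum() ** 2 + psi.sum())
        return ReliabilityResult(float(omega), "spearman-brown-2item", lam, psi)
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("item covariance matrix is not positive definite")
    lam, psi = _one_factor_ml(S)
    omega = (lam.sum() ** 2) / (lam.sum() ** 2 + psi.sum())
    return ReliabilityResult(float(np.clip(omega, 0.0, 1.0)),
                             "ml-one-factor", lam, psi)


# --------------------------------------------------------------------------
# Skewness and Box-Cox


def sample_skewness(values) -> float:
    """Adjusted Fisher-Pearson G1 = [n^2/((n-1)(n-2))] m3 / s^3."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("skewness needs at least 3 values")
    if np.var(x) == 0:
        raise ValueError("skewness undefined for zero variance")
    return float(stats.skew(x, bias=False))


@dataclass(frozen=True)
class BoxCoxResult:
    lmbda: float
    offset: float
    skewness_before: float
    skewness_after: float
    transformed: np.ndarray

    def inverse(self, y):
        return inverse_boxcox(y, self.lmbda, self.offset)


def _boxcox_apply(x: np.ndarray, lmbda: float) -> np.ndarray:
    if abs(lmbda) < 1e-12:
        return np.log(x)
    return (np.power(x, lmbda) - 1.0) / lmbda


def apply_boxcox(values, lmbda: float, offset: float = 0.0) -> np.ndarray:
    """Forward transform y* = ((y+offset)^lambda - 1)/lambda (log at lambda 0)."""
    x = np.asarray(values, dtype=float) + offset
    if (x <= 0).any():
        raise ValueError("values plus offset must be positive")
    return _boxcox_apply(x, lmbda)


def inverse_boxcox(y, lmbda: float, offset: float = 0.0):
    """Invert y* = ((y+offset)^lambda - 1)/lambda (log when lambda = 0)."""
    y = np.asarray(y, dtype=float)
    if abs(lmbda) < 1e-12:
        raw = np.exp(y)
    else:
        base = lmbda * y + 1.0
        base = np.clip(base, 1e-12, None)
        raw = np.power(base, 1.0 / lmbda)
    return raw - offset


def boxcox_transform(values, lmbda: float | None = None) -> BoxCoxResult:
    """Box-Cox transform with automatic +1 offset when zeros are present.

    When ``lmbda`` is omitted it maximizes the profile log-likelihood over a
    grid on [-2, 2] (step 0.01) and then refines by bounded golden-section
    search around the best grid point.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("Box-Cox input contains missing values")
    if (x < 0).any():
        raise ValueError("Box-Cox input must be non-negative")
    offset = 1.0 if (x == 0).any() else 0.0
    shifted = x + offset
    if (shifted <= 0).any():
        raise ValueError("values plus offset must be positive")
    if lmbda is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
        llf = np.array([stats.boxcox_llf(l, shifted) for l in grid])
        k = int(np.argmax(llf))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(lambda l: -stats.boxcox_llf(l, shifted),
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-6})
        lmbda = float(res.x)
    transformed = _boxcox_apply(shifted, float(lmbda))

    def _skew(v):
        try:
            return sample_skewness(v)
        except ValueError:
            return float("nan")

    return BoxCoxResult(lmbda=float(lmbda), offset=offset,
                        skewness_before=_skew(x),
                        skewness_after=_skew(transformed),
                        transformed=transformed)


# --------------------------------------------------------------------------
# Person-mean (group-mean) centering


@dataclass(frozen=True)
class CenteredPredictor:
    person_mean: pd.Series   # indexed like the input, constant within subject
    deviation: pd.Series

    def reconstruct(self) -> pd.Series:
        return self.person_mean + self.deviation


def person_center(values: pd.Series, subjects: pd.Series) -> CenteredPredictor:
    """Split a repeated measure into person means and within-person deviations.

    Person means pool every included observation of a subject (across all
    waves); per subject the deviations sum to zero by construction.
    """
    if len(values) != len(subjects):
        raise ValueError("values and subjects must align")
    pm = values.groupby(subjects.to_numpy()).transform("mean")
    return CenteredPredictor(person_mean=pm, deviation=values - pm)


def add_person_centered(df: pd.DataFrame, columns, subject_col: str = "dyad_id",
                        member_prefixes=("m_", "c_")) -> pd.DataFrame:
    """Add ``<col>_pm`` and ``<col>_dev`` columns for each listed column.

    The grouping subject for a member-prefixed column is that member within
    the dyad (the dyad id is shared; mother and child are distinct subjects).
    """
    out = df.copy()
    for col in columns:
        cp = person_center(out[col], out[subject_col])
        out[f"{col}_pm"] = cp.person_mean
        out[f"{col}_dev"] = cp.deviation
    return out
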