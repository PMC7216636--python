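"""Two-intercept dyadic multilevel model (actor-partner interdependence model).

The analysis table has one row per prompt-matched dyad window; the stacked
design has two rows per window (mother, child).  There is no global
intercept: every fixed-effect column is a member dummy times that member's
predictor, so mother and child get separate parameter sets in one model
(the "two-intercept" approach for distinguishable dyads).

Random structure: a 2x2 covariance ``G`` of (mother, child) dyad-level
random intercepts, plus heteroscedastic member residuals with a
within-window cross-member correlation ``rho``:

    y_d ~ N(X_d beta, Z_d G Z_d' + R_d),
    R_d = I_{n_d} (x) S,   S = [[s_m^2, rho s_m s_c], [rho s_m s_c, s_c^2]].

Because every window contributes a complete (mother, child) pair,
``V_d = I (x) S + J (x) G`` decomposes exactly as
``(I - P) (x) S + P (x) (S + n_d G)`` with ``P = J/n_d``, so the marginal
log-likelihood needs only 2x2 factorizations.  ``beta`` is profiled out by
GLS; the six variance parameters are optimized on an unconstrained scale
(log-Cholesky for G, log for the sigmas, atanh for rho) by quasi-Newton
from three deterministic starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ApimParams",
    "ApimDesign",
    "ApimFit",
    "MOTHER_TERMS",
    "CHILD_TERMS",
    "design_terms",
    "build_design",
    "apim_loglik",
    "fit_apim",
    "wald_tests",
    "p_stars",
]


# --------------------------------------------------------------------------
# Term tables: (design column name, source column in the analysis table).
# Mother rows carry the "m:" columns, child rows the "c:" columns; on the
# other member's rows the columns are structurally zero.  Actor terms pair a
# member's outcome with their own affect components, partner terms with the
# other member's.

def _affect_terms(member: str, own: str, other: str, pm: str, dev: str):
    return [
        (f"{member}:pa_dev", f"{own}_pa{dev}"),
        (f"{member}:pa_pm", f"{own}_pa{pm}"),
        (f"{member}:na_dev", f"{own}_na{dev}"),
        (f"{member}:na_pm", f"{own}_na{pm}"),
        (f"{member}:partner_pa_dev", f"{other}_pa{dev}"),
        (f"{member}:partner_pa_pm", f"{other}_pa{pm}"),
        (f"{member}:partner_na_dev", f"{other}_na{dev}"),
        (f"{member}:partner_na_pm", f"{other}_na{pm}"),
    ]


def design_terms(use_true_affect: bool = False):
    """Return (mother_terms, child_terms) lists of (column, source) pairs.

    With ``use_true_affect`` the affect columns read the generator's
    ground-truth person means / deviations (``*_pm_true`` / ``*_dev_true``)
    instead of the sample-centered ones; used by the data-generating process.
    """
    pm = "_pm_true" if use_true_affect else "_pm"
    dev = "_dev_true" if use_true_affect else "_dev"
    mother = [
        ("m:intercept", "_one"),
        ("m:resp_time", "m_resp_hour"),
        ("m:age_wave", "m_age_wave"),
        ("m:age_base", "m_age_base"),
        ("m:hispanic", "m_hispanic"),
        ("m:prompt_diff", "prompt_diff"),
        ("m:weekend", "weekend"),
    ] + _affect_terms("m", "m", "c", pm, dev)
    child = [
        ("c:intercept", "_one"),
        ("c:resp_time", "c_resp_hour"),
        ("c:male", "c_male"),
        ("c:age_wave", "c_age_wave"),
        ("c:age_base", "c_age_base"),
        ("c:hispanic", "c_hispanic"),
        ("c:bmiz", "c_bmiz"),
        ("c:prompt_diff", "prompt_diff"),
        ("c:weekend", "weekend"),
    ] + _affect_terms("c", "c", "m", pm, dev)
    return mother, child


MOTHER_TERMS, CHILD_TERMS = design_terms()


# --------------------------------------------------------------------------
# Parameter containers


def _validate_G(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.shape != (2, 2):
        raise ValueError("G must be 2x2")
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("G must be symmetric")
    if np.linalg.eigvalsh(G).min() < -1e-10:
        raise ValueError("G must be positive semi-definite")
    return G


@dataclass(frozen=True)
class ApimParams:
    """Fixed effects plus random-effect parameters of the dyadic model.

    ``fixed`` maps design column names (see :func:`design_terms`) to
    coefficients; missing terms are treated as zero.
    """

    fixed: dict
    G: np.ndarray
    sigma_m: float
    sigma_c: float
    rho: float

    def __post_init__(self):
        object.__setattr__(self, "G", _validate_G(self.G))
        if not (self.sigma_m > 0 and self.sigma_c > 0):
            raise ValueError("residual SDs must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        known = {c for c, _ in MOTHER_TERMS + CHILD_TERMS}
        unknown = set(self.fixed) - known
        if unknown:
            raise ValueError(f"unknown fixed-effect terms: {sorted(unknown)}")

    def beta_vector(self, columns) -> np.ndarray:
        return np.array([float(self.fixed.get(c, 0.0)) for c in columns])

    @property
    def intercept_sds(self):
        return float(np.sqrt(self.G[0, 0])), float(np.sqrt(self.G[1, 1]))

    @property
    def intercept_corr(self) -> float:
        d = math.sqrt(self.G[0, 0] * self.G[1, 1])
        return float(self.G[0, 1] / d) if d > 0 else 0.0


@dataclass
class ApimDesign:
    """Stacked two-intercept design: rows interleave (mother, child) per window."""

    y: np.ndarray          # (2n,)
    X: np.ndarray          # (2n, p)
    columns: list          # p design column names
    dyads: np.ndarray      # (n,) dyad id per window
    window_ids: np.ndarray  # (n,) identifier per window

    def __post_init__(self):
        n = len(self.dyads)
        if self.y.shape != (2 * n,) or self.X.shape[0] != 2 * n:
            raise ValueError("design rows must be two per window")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column names do not match design width")

    @property
    def n_windows(self) -> int:
        return len(self.dyads)

    @property
    def n_dyads(self) -> int:
        return len(np.unique(self.dyads))

    @property
    def member(self) -> np.ndarray:
        """0 = mother row, 1 = child row."""
        out = np.zeros(2 * self.n_windows, dtype=int)
        out[1::2] = 1
        return out


def build_design(df: pd.DataFrame, outcome=("m_out", "c_out"),
                 use_true_affect: bool = False) -> ApimDesign:
    """Build the stacked design from one-row-per-window analysis data.

    Windows are sorted by (dyad, window id) so each dyad's rows are
    contiguous; fit results are invariant to the input row order.
    """
    mother_terms, child_terms = design_terms(use_true_affect)
    required = ({src for _, src in mother_terms + child_terms} - {"_one"}) | set(outcome)
    for col in sorted(required):
        if col not in df.columns:
            raise KeyError(f"analysis table is missing required column {col!r}")
    if "window_id" in df.columns:
        df = df.sort_values(["dyad_id", "window_id"], kind="stable")
    else:
        df = df.sort_values("dyad_id", kind="stable")
    n = len(df)
    work = df.assign(_one=1.0)
    cols = [c for c, _ in mother_terms] + [c for c, _ in child_terms]
    X = np.zeros((2 * n, len(cols)), dtype=float)
    for j, (_, src) in enumerate(mother_terms):
        X[0::2, j] = work[src].to_numpy(dtype=float)
    off = len(mother_terms)
    for j, (_, src) in enumerate(child_terms):
        X[1::2, off + j] = work[src].to_numpy(dtype=float)
    y = np.empty(2 * n)
    y[0::2] = work[outcome[0]].to_numpy(dtype=float)
    y[1::2] = work[outcome[1]].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        bad = [c for c in sorted(required) if work[c].isna().any()]
        raise ValueError(f"analysis table contains missing values in {bad}")
    wid = (work["window_id"].to_numpy() if "window_id" in work.columns
           else np.arange(n))
    return ApimDesign(y=y, X=X, columns=cols,
                      dyads=work["dyad_id"].to_numpy(), window_ids=wid)


# --------------------------------------------------------------------------
# Marginal likelihood via the paired compound-symmetry structure


class _Suffstats:
    """Per-design sufficient statistics so each likelihood evaluation is O(D p^2)."""

    def __init__(self, design: ApimDesign):
        X, y, dyads = design.X, design.y, design.dyads
        Xm, Xc = X[0::2], X[1::2]
        ym, yc = y[0::2], y[1::2]
        # global cross-products
        self.P_mm = Xm.T @ Xm
        self.P_sym = Xm.T @ Xc
        self.P_sym = self.P_sym + self.P_sym.T
        self.P_cc = Xc.T @ Xc
        self.q_a = Xm.T @ ym
        self.q_b = Xm.T @ yc + Xc.T @ ym
        self.q_c = Xc.T @ yc
        self.s_mm = float(ym @ ym)
        self.s_mc = float(ym @ yc)
        self.s_cc = float(yc @ yc)
        # per-dyad means
        uniq, inv, counts = np.unique(dyads, return_inverse=True, return_counts=True)
        D, p = len(uniq), X.shape[1]
        self.ns = counts.astype(float)
        self.Xbar_m = np.zeros((D, p))
        self.Xbar_c = np.zeros((D, p))
        np.add.at(self.Xbar_m, inv, Xm)
        np.add.at(self.Xbar_c, inv, Xc)
        self.Xbar_m /= counts[:, None]
        self.Xbar_c /= counts[:, None]
        self.ybar_m = np.bincount(inv, weights=ym) / counts
        self.ybar_c = np.bincount(inv, weights=yc) / counts
        self.N = 2 * len(dyads)
        self.p = p

    def quadratics(self, G, sigma_m, sigma_c, rho):
        """Return (A, b, yy, logdet) for the full marginal covariance.

        A = X'V^-1 X, b = X'V^-1 y, yy = y'V^-1 y, logdet = log|V|.
        """
        sm2, sc2 = sigma_m ** 2, sigma_c ** 2
        cov = rho * sigma_m * sigma_c
        detS = sm2 * sc2 - cov ** 2
        if detS <= 0:
            raise ValueError("residual 2x2 covariance is not positive definite")
        a, b_, c = sc2 / detS, -cov / detS, sm2 / detS
        n = self.ns
        T11 = sm2 + n * G[0, 0]
        T12 = cov + n * G[0, 1]
        T22 = sc2 + n * G[1, 1]
        detT = T11 * T22 - T12 ** 2
        if np.any(detT <= 0):
            raise ValueError("marginal covariance is not positive definite")
        d, e, f = T22 / detT, -T12 / detT, T11 / detT

        w1 = n * (d - a)
        w2 = n * (e - b_)
        w3 = n * (f - c)
        A = a * self.P_mm + b_ * self.P_sym + c * self.P_cc
        A += np.einsum("d,di,dj->ij", w1, self.Xbar_m, self.Xbar_m)
        cross = np.einsum("d,di,dj->ij", w2, self.Xbar_m, self.Xbar_c)
        A += cross + cross.T
        A += np.einsum("d,di,dj->ij", w3, self.Xbar_c, self.Xbar_c)

        b_vec = a * self.q_a + b_ * self.q_b + c * self.q_c
        b_vec += (w1 * self.ybar_m) @ self.Xbar_m
        b_vec += (w2 * self.ybar_c) @ self.Xbar_m + (w2 * self.ybar_m) @ self.Xbar_c
        b_vec += (w3 * self.ybar_c) @ self.Xbar_c

        yy = a * self.s_mm + 2 * b_ * self.s_mc + c * self.s_cc
        yy += float(w1 @ self.ybar_m ** 2 + 2 * (w2 * self.ybar_m) @ self.ybar_c
                    + w3 @ self.ybar_c ** 2)

        logdet = float(np.sum((n - 1) * math.log(detS)) + np.sum(np.log(detT)))
        return A, b_vec, yy, logdet


def apim_loglik(design: ApimDesign, beta, G, sigma_m: float, sigma_c: float,
                rho: float) -> float:
    """Marginal Gaussian log-likelihood at the given parameters."""
    G = _validate_G(G)
    if not (sigma_m > 0 and sigma_c > 0):
        raise ValueError("residual SDs must be positive")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (design.X.shape[1],):
        raise ValueError("beta length does not match design")
    ss = _Suffstats(design)
    A, b_vec, yy, logdet = ss.quadratics(G, sigma_m, sigma_c, rho)
    q = yy - 2 * beta @ b_vec + beta @ A @ beta
    return -0.5 * (logdet + q + ss.N * math.log(2 * math.pi))


# --------------------------------------------------------------------------
# Fitting


def _theta_to_params(theta):
    L = np.array([[math.exp(theta[0]), 0.0], [theta[1], math.exp(theta[2])]])
    G = L @ L.T
    return G, math.exp(theta[3]), math.exp(theta[4]), math.tanh(theta[5])


def _params_to_theta(G, sigma_m, sigma_c, rho):
    G = np.asarray(G, float) + 1e-10 * np.eye(2)
    L = np.linalg.cholesky(G)
    return np.array([math.log(L[0, 0]), L[1, 0], math.log(L[1, 1]),
                     math.log(sigma_m), math.log(sigma_c), math.atanh(rho)])


def _neg_profiled(theta, ss: _Suffstats, reml: bool):
    try:
        G, sm, sc, rho = _theta_to_params(theta)
        A, b_vec, yy, logdet = ss.quadratics(G, sm, sc, rho)
        cho = np.linalg.cholesky(A)
        beta = np.linalg.solve(cho.T, np.linalg.solve(cho, b_vec))
    except (np.linalg.LinAlgError, ValueError, OverflowError):
        return 1e12
    q = yy - beta @ b_vec
    nll = 0.5 * (logdet + q + ss.N * math.log(2 * math.pi))
    if reml:
        nll += float(np.sum(np.log(np.diag(cho)))) \
            - 0.25 * ss.p * math.log(2 * math.pi) * 2
    if not np.isfinite(nll):
        return 1e12
    return nll


def _moment_start(design: ApimDesign):
    """Variance-component moment start from OLS residuals."""
    X, y, dyads = design.X, design.y, design.dyads
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta0
    em, ec = e[0::2], e[1::2]
    uniq, inv, counts = np.unique(dyads, return_inverse=True, return_counts=True)
    out = []
    dyad_means = []
    for r in (em, ec):
        mbar = np.bincount(inv, weights=r) / counts
        within = r - mbar[inv]
        vw = float(within @ within) / max(len(r) - len(uniq), 1)
        vb = float(np.var(mbar, ddof=1) - vw * np.mean(1.0 / counts))
        vtot = float(np.var(r, ddof=1))
        vb = min(max(vb, 1e-4 * vtot), 0.9 * vtot)
        vw = max(vw, 1e-4 * vtot)
        out.append((vb, vw))
        dyad_means.append(mbar)
    (vb_m, vw_m), (vb_c, vw_c) = out
    g12 = float(np.cov(dyad_means[0], dyad_means[1])[0, 1])
    lim = 0.9 * math.sqrt(vb_m * vb_c)
    g12 = float(np.clip(g12, -lim, lim))
    rho0 = float(np.corrcoef(em, ec)[0, 1])
    rho0 = float(np.clip(rho0, -0.9, 0.9))
    G0 = np.array([[vb_m, g12], [g12, vb_c]])
    return G0, math.sqrt(vw_m), math.sqrt(vw_c), rho0


@dataclass
class ApimFit:
    """Fitted two-intercept dyadic model with Wald inference."""

    method: str
    columns: list
    beta: np.ndarray
    se: np.ndarray
    G: np.ndarray
    sigma_m: float
    sigma_c: float
    rho: float
    rho_ci: tuple
    r_intercepts: float
    r_ci: tuple
    loglik: float
    n_windows: int
    n_dyads: int
    converged: bool
    boundary: bool
    start_used: int
    theta: np.ndarray = field(repr=False, default=None)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.z))

    @property
    def intercept_sds(self):
        return float(np.sqrt(self.G[0, 0])), float(np.sqrt(self.G[1, 1]))

    def coef(self, term: str) -> float:
        return float(self.beta[self.columns.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.columns.index(term)])

    def fixed_effects(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.columns,
            "estimate": self.beta,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "stars": [p_stars(v) for v in self.p],
        })

    def random_effects(self) -> pd.DataFrame:
        sd_m, sd_c = self.intercept_sds
        rows = [
            ("mother_intercept_sd", sd_m),
            ("child_intercept_sd", sd_c),
            ("intercept_correlation", self.r_intercepts),
            ("mother_residual_sd", self.sigma_m),
            ("child_residual_sd", self.sigma_c),
            ("residual_correlation", self.rho),
        ]
        return pd.DataFrame(rows, columns=["component", "value"])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "fixed_effects": {c: {"estimate": float(b), "se": float(s)}
                              for c, b, s in zip(self.columns, self.beta, self.se)},
            "G": [[float(v) for v in row] for row in self.G],
            "intercept_sds": list(self.intercept_sds),
            "intercept_correlation": self.r_intercepts,
            "intercept_correlation_ci": list(self.r_ci),
            "sigma_mother": self.sigma_m,
            "sigma_child": self.sigma_c,
            "residual_correlation": self.rho,
            "residual_correlation_ci": list(self.rho_ci),
            "loglik": self.loglik,
            "n_windows": self.n_windows,
            "n_dyads": self.n_dyads,
            "converged": self.converged,
            "boundary": self.boundary,
        }


def p_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _numeric_hessian(fun, x, step=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = step
            ej = np.zeros(k); ej[j] = step
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step * step)
    return H


def _transformed_ci(fun_z, theta, cov_theta, step=1e-5):
    """Wald CI on an atanh-transformed scalar function of theta."""
    k = len(theta)
    g = np.zeros(k)
    for i in range(k):
        e = np.zeros(k); e[i] = step
        g[i] = (fun_z(theta + e) - fun_z(theta - e)) / (2 * step)
    var = float(g @ cov_theta @ g)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    z0 = fun_z(theta)
    return math.tanh(z0 - half), math.tanh(z0 + half)


def fit_apim(design: ApimDesign, method: str = "ML", start=None, tol: float = 1e-9,
             max_iter: int = 300, seed=None) -> ApimFit:
    """Fit the dyadic model by (RE)ML.

    Three deterministic starts are tried (moment, generic, shrunken moment)
    and the best profiled likelihood wins; ``start`` may prepend a user
    start as ``(G, sigma_m, sigma_c, rho)``.  ``seed`` is accepted for
    interface symmetry; the optimizer is deterministic.
    """
    method = method.upper()
    if method not in {"ML", "REML"}:
        raise ValueError("method must be 'ML' or 'REML'")
    reml = method == "REML"
    if np.linalg.matrix_rank(design.X) < design.X.shape[1]:
        raise ValueError("design is rank deficient on member rows")
    ss = _Suffstats(design)

    G0, sm0, sc0, rho0 = _moment_start(design)
    vt_m = float(np.var(design.y[0::2], ddof=1))
    vt_c = float(np.var(design.y[1::2], ddof=1))
    starts = []
    if start is not None:
        starts.append(_params_to_theta(*start))
    starts.append(_params_to_theta(G0, sm0, sc0, rho0))
    starts.append(_params_to_theta(np.diag([0.1 * vt_m, 0.1 * vt_c]),
                                   math.sqrt(0.9 * vt_m), math.sqrt(0.9 * vt_c), 0.0))
    starts.append(_params_to_theta(0.5 * G0, sm0, sc0, 0.5 * rho0))

    best = None
    best_idx = -1
    for idx, th0 in enumerate(starts):
        res = optimize.minimize(_neg_profiled, th0, args=(ss, reml),
                                method="L-BFGS-B",
                                options={"maxiter": max_iter, "ftol": tol,
                                         "gtol": 1e-6})
        if best is None or res.fun < best.fun - 1e-9:
            best, best_idx = res, idx
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("APIM optimization failed from all starts")
    if not best.success and best.fun >= 1e11:
        raise RuntimeError(f"APIM optimization did not converge: {best.message}")

    theta = best.x
    G, sm, sc, rho = _theta_to_params(theta)
    A, b_vec, yy, logdet = ss.quadratics(G, sm, sc, rho)
    cho = np.linalg.cholesky(A)
    beta = np.linalg.solve(cho.T, np.linalg.solve(cho, b_vec))
    cov_beta = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    q = yy - beta @ b_vec
    loglik = -0.5 * (logdet + q + ss.N * math.log(2 * math.pi))

    boundary = bool(min(G[0, 0], G[1, 1]) < 1e-8 * max(sm, sc) ** 2
                    or abs(rho) > 0.999
                    or abs(theta[0]) > 12 or abs(theta[2]) > 12)

    H = _numeric_hessian(lambda t: _neg_profiled(t, ss, reml), theta)
    try:
        cov_theta = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov_theta = np.full((6, 6), np.nan)

    def z_r(t):
        Gt, *_ = _theta_to_params(t)
        r = Gt[0, 1] / math.sqrt(Gt[0, 0] * Gt[1, 1])
        return math.atanh(max(min(r, 1 - 1e-12), -1 + 1e-12))

    r_hat = float(G[0, 1] / math.sqrt(G[0, 0] * G[1, 1]))
    r_ci = _transformed_ci(z_r, theta, cov_theta)
    rho_half = 1.959963984540054 * math.sqrt(max(cov_theta[5, 5], 0.0))
    rho_ci = (math.tanh(theta[5] - rho_half), math.tanh(theta[5] + rho_half))

    return ApimFit(method=method, columns=list(design.columns), beta=beta, se=se,
                   G=G, sigma_m=sm, sigma_c=sc, rho=rho, rho_ci=rho_ci,
                   r_intercepts=r_hat, r_ci=r_ci, loglik=float(loglik),
                   n_windows=design.n_windows, n_dyads=design.n_dyads,
                   converged=bool(best.success), boundary=boundary,
                   start_used=best_idx, theta=theta)


def wald_tests(fit: ApimFit) -> pd.DataFrame:
    """Wald z inference table for the fixed effects (normal reference)."""
    return fit.fixed_effects()
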