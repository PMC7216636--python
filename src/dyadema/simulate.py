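"""Synthetic mother-child EMA + accelerometer data with known ground truth.

Emulates a longitudinal EMA study of working mothers and their 8-12
year-old children: up to six 7-day waves of signal-contingent prompts
(mothers 8 on weekend days / 4 on weekdays, children 7 / 3), with the
mother prompted in the first half-hour of a shared hour window and the
child in the second half, a minimum one-hour gap between a member's
prompts, ~80%/77% compliance, 1-4 bounded affect with realistic ICCs, and
prompt-matched 45-min MVPA / sedentary outcomes generated from the
two-intercept actor-partner model equations.

Two affect tiers: tier-1 continuous composites (clipped to [1, 4]) drive
outcome generation and parameter-recovery tests; tier-2 ordinal 1-4 item
responses (latent + item noise, rounded) exercise scoring and reliability.
Outcome modes: ``model_scale`` is the exact linear-model data-generating
process used for recovery; ``bounded`` maps MVPA back through the inverse
Box-Cox and truncates both outcomes to the 0-45 min window (realistic but
documented as biased for recovery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accelerometry import EPOCH_SECONDS, EpochSeries, Thresholds, mvpa_threshold_cpm
from .apim import ApimParams, build_design
from .scoring import inverse_boxcox
from .windows import WINDOW_MINUTES, SchedulingError, pair_prompts

__all__ = [
    "AffectParams",
    "CovariateParams",
    "GeneratorConfig",
    "MVPA_TRUTH",
    "SEDENTARY_TRUTH",
    "affect_params_from_totals",
    "generate_schedule",
    "apply_missingness",
    "generate_affect",
    "generate_covariates",
    "attach_covariates",
    "generate_window_outcomes",
    "generate_bounded_outcomes",
    "render_epoch_counts",
    "simulate_icc_panel",
    "simulate_recovery_dataset",
    "simulate_study",
]

_STUDY_START = pd.Timestamp("2015-01-05")   # a Monday; day index 0 = Monday
_WAVE_SPACING_DAYS = 182                     # semi-annual, keeps weekday alignment


# --------------------------------------------------------------------------
# Parameter containers and study-condition defaults


@dataclass(frozen=True)
class AffectParams:
    """Variance components of one member's affect scale (1-4 composite)."""

    mean: float
    between_sd: float
    within_sd: float
    n_items: int
    item_noise_sd: float

    def __post_init__(self):
        if self.between_sd < 0 or self.within_sd < 0 or self.item_noise_sd < 0:
            raise ValueError("SDs must be non-negative")
        if self.n_items < 1:
            raise ValueError("need at least one item")
        if self.between_sd > 0 and self.within_sd > 0:
            if not 0 < self.icc < 1:
                raise ValueError("implied ICC must lie in (0, 1)")

    @property
    def icc(self) -> float:
        tot = self.between_sd ** 2 + self.within_sd ** 2
        return self.between_sd ** 2 / tot if tot > 0 else 0.0


def affect_params_from_totals(mean: float, total_sd: float, icc: float,
                              n_items: int, omega: float) -> AffectParams:
    """Build AffectParams from a total SD, an ICC and a target omega.

    For tau-equivalent items x_j = latent + e_j, omega =
    (k sd_L)^2 / ((k sd_L)^2 + k sd_e^2), so the item noise needed for a
    target omega is sd_e^2 = sd_L^2 k (1 - omega) / omega.
    """
    between = total_sd * math.sqrt(icc)
    within = total_sd * math.sqrt(1 - icc)
    noise = total_sd * math.sqrt(n_items * (1 - omega) / omega)
    return AffectParams(mean, between, within, n_items, noise)


# composites calibrated to the study's descriptives: (mean, SD, ICC, items, omega)
DEFAULT_AFFECT = {
    ("mother", "pa"): affect_params_from_totals(2.636, 0.745, 0.134, 2, 0.71),
    ("mother", "na"): affect_params_from_totals(1.381, 0.532, 0.214, 3, 0.83),
    ("child", "pa"): affect_params_from_totals(3.032, 0.944, 0.111, 2, 0.90),
    ("child", "na"): affect_params_from_totals(1.260, 0.515, 0.293, 3, 0.85),
}


@dataclass(frozen=True)
class CovariateParams:
    """Baseline covariate distributions for the simulated cohort."""

    mother_age: tuple = (41.03, 5.86)
    child_age: tuple = (9.51, 0.90)
    child_female_prob: float = 0.53
    mother_hispanic_prob: float = 0.51
    child_hispanic_prob: float = 0.59
    child_bmiz: tuple = (0.49, 1.10)


def _G(sd_m: float, sd_c: float, r: float) -> np.ndarray:
    return np.array([[sd_m ** 2, r * sd_m * sd_c],
                     [r * sd_m * sd_c, sd_c ** 2]])


# Generating truth for the transformed-MVPA outcome model
MVPA_TRUTH = ApimParams(
    fixed={
        "m:intercept": 0.850, "m:resp_time": -0.050, "m:age_wave": 0.015,
        "m:age_base": -0.011, "m:hispanic": -0.012, "m:prompt_diff": -0.001,
        "m:weekend": -0.064,
        "m:pa_dev": -0.026, "m:pa_pm": 0.026, "m:na_dev": 0.010, "m:na_pm": -0.011,
        "m:partner_pa_dev": 0.030, "m:partner_pa_pm": -0.058,
        "m:partner_na_dev": 0.009, "m:partner_na_pm": -0.084,
        "c:intercept": 3.139, "c:resp_time": -0.039, "c:male": 0.095,
        "c:age_wave": -0.127, "c:age_base": -0.012, "c:hispanic": -0.054,
        "c:bmiz": -0.012, "c:prompt_diff": 0.001, "c:weekend": -0.082,
        "c:pa_dev": 0.071, "c:pa_pm": -0.026, "c:na_dev": 0.029, "c:na_pm": 0.016,
        "c:partner_pa_dev": 0.014, "c:partner_pa_pm": -0.038,
        "c:partner_na_dev": -0.004, "c:partner_na_pm": -0.201,
    },
    G=_G(0.181, 0.206, 0.546), sigma_m=0.612, sigma_c=0.758, rho=0.060)

# Generating truth for the sedentary-minutes outcome model
SEDENTARY_TRUTH = ApimParams(
    fixed={
        "m:intercept": 28.327, "m:resp_time": 0.546, "m:age_wave": 0.242,
        "m:age_base": 0.278, "m:hispanic": -0.423, "m:prompt_diff": 0.008,
        "m:weekend": -0.068,
        "m:pa_dev": 1.122, "m:pa_pm": 0.122, "m:na_dev": 0.316, "m:na_pm": 0.326,
        "m:partner_pa_dev": -0.188, "m:partner_pa_pm": 0.776,
        "m:partner_na_dev": -0.360, "m:partner_na_pm": 0.067,
        "c:intercept": 5.780, "c:resp_time": 0.392, "c:male": -0.631,
        "c:age_wave": 1.089, "c:age_base": -0.349, "c:hispanic": 0.087,
        "c:bmiz": 0.009, "c:prompt_diff": -0.002, "c:weekend": 0.018,
        "c:pa_dev": -0.640, "c:pa_pm": 0.083, "c:na_dev": 0.214, "c:na_pm": -0.537,
        "c:partner_pa_dev": 0.012, "c:partner_pa_pm": 0.762,
        "c:partner_na_dev": 0.280, "c:partner_na_pm": 2.153,
    },
    G=_G(2.976, 2.485, 0.441), sigma_m=8.418, sigma_c=8.761, rho=0.046)


@dataclass(frozen=True)
class GeneratorConfig:
    """Every generating parameter of the synthetic study."""

    n_dyads: int = 185
    n_waves: int = 6
    n_days: int = 7
    weekend_days: tuple = (5, 6)            # Saturday, Sunday (day 0 = Monday)
    prompts_mother_weekend: int = 8
    prompts_mother_weekday: int = 4
    prompts_child_weekend: int = 7
    prompts_child_weekday: int = 3
    day_start_hour: int = 7                 # first eligible hour-window start
    day_end_hour: int = 21                  # last eligible hour-window start
    compliance_mother: float = 0.803
    compliance_child: float = 0.769
    with_mother_prob: float = 0.774
    target_windows_per_dyad: int = 50
    affect_params: dict = field(default_factory=lambda: dict(DEFAULT_AFFECT))
    apim_mvpa: ApimParams = MVPA_TRUTH
    apim_sedentary: ApimParams = SEDENTARY_TRUTH
    boxcox_lambda: float = 0.06
    boxcox_offset: float = 1.0
    covariates: CovariateParams = CovariateParams()
    wear_start_hour: float = 7.0
    wear_end_hour: float = 22.5
    nonwear_runs_per_day: float = 0.4
    nonwear_duration_min: tuple = (70.0, 120.0)
    long_nonwear_prob: float = 0.05          # chance of a 400-min run (invalid day)
    seed: int = 0

    def __post_init__(self):
        for p in (self.compliance_mother, self.compliance_child,
                  self.with_mother_prob, self.long_nonwear_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for n in (self.prompts_mother_weekend, self.prompts_mother_weekday,
                  self.prompts_child_weekend, self.prompts_child_weekday):
            if n < 1:
                raise ValueError("prompt counts must be >= 1")
        if self.n_days < 1 or self.n_waves < 1 or self.n_dyads < 1:
            raise ValueError("counts must be >= 1")
        if (self.prompts_child_weekend > self.prompts_mother_weekend
                or self.prompts_child_weekday > self.prompts_mother_weekday):
            raise SchedulingError(
                "child prompts must not exceed mother prompts (children pair "
                "into mother windows)")

    def prompts_for(self, member: str, weekend: bool) -> int:
        if member == "mother":
            return self.prompts_mother_weekend if weekend else self.prompts_mother_weekday
        return self.prompts_child_weekend if weekend else self.prompts_child_weekday


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# --------------------------------------------------------------------------
# Schedule


def _pick_spaced(rng, n_positions: int, k: int) -> np.ndarray:
    """Uniform k-subset of range(n_positions) with pairwise gaps >= 2.

    Bijection with unrestricted subsets: choose q_1 < ... < q_k from
    range(n_positions - k + 1) and set p_i = q_i + i.
    """
    m = n_positions - k + 1
    if m < k:
        raise SchedulingError(
            f"cannot place {k} hour windows with one-hour spacing in "
            f"{n_positions} eligible hours")
    q = np.sort(rng.choice(m, size=k, replace=False))
    return q + np.arange(k)


def generate_schedule(config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Scheduled (unanswered) prompts for every dyad, wave and day.

    Hour windows are drawn with at least one empty hour between them, which
    guarantees >= 60 min between consecutive prompts of the same member;
    the mother's minute is uniform in [0, 30) of the window and the child's
    in [30, 60).  Child windows are a random subset of the mother's, so
    surplus mother windows carry no child prompt.
    """
    rng = _rng(config.seed if seed is None else seed)
    n_positions = config.day_end_hour - config.day_start_hour + 1
    rows = []
    for dyad in range(config.n_dyads):
        for wave in range(config.n_waves):
            wave_start = _STUDY_START + pd.Timedelta(days=wave * _WAVE_SPACING_DAYS)
            for day in range(config.n_days):
                weekend = (day % 7) in config.weekend_days
                n_m = config.prompts_for("mother", weekend)
                n_c = config.prompts_for("child", weekend)
                hours = config.day_start_hour + _pick_spaced(rng, n_positions, n_m)
                child_hours = set(rng.choice(hours, size=n_c, replace=False))
                day_ts = wave_start + pd.Timedelta(days=day)
                for h in hours:
                    base = day_ts + pd.Timedelta(hours=int(h))
                    m_sec = int(rng.integers(0, 30 * 60))
                    rows.append((dyad, wave, day, weekend, "mother",
                                 base + pd.Timedelta(seconds=m_sec)))
                    if h in child_hours:
                        c_sec = int(rng.integers(30 * 60, 60 * 60))
                        rows.append((dyad, wave, day, weekend, "child",
                                     base + pd.Timedelta(seconds=c_sec)))
    df = pd.DataFrame(rows, columns=["dyad_id", "wave", "day", "weekend",
                                     "member", "scheduled_ts"])
    df.insert(0, "prompt_id", np.arange(len(df)))
    return df


def apply_missingness(prompts: pd.DataFrame, config: GeneratorConfig,
                      seed=None) -> pd.DataFrame:
    """Independent Bernoulli answering; answered prompts get a response time
    (uniform within the 10-min accessibility span) and children a
    with-mother context flag."""
    rng = _rng(config.seed + 1 if seed is None else seed)
    out = prompts.copy()
    is_mother = (out["member"] == "mother").to_numpy()
    p = np.where(is_mother, config.compliance_mother, config.compliance_child)
    out["answered"] = rng.random(len(out)) < p
    delay = rng.uniform(0.5, 9.5, size=len(out))
    resp = pd.DatetimeIndex(out["scheduled_ts"]) + pd.to_timedelta(
        np.round(delay * 60), unit="s")
    out["response_ts"] = pd.Series(resp, index=out.index).where(out["answered"])
    with_mother = rng.random(len(out)) < config.with_mother_prob
    out["with_mother"] = np.where(~is_mother & out["answered"].to_numpy(),
                                  with_mother.astype(float), np.nan)
    return out


# --------------------------------------------------------------------------
# Affect


def _clipped_normal_mean(mu, sigma: float, lo: float = 1.0,
                         hi: float = 4.0) -> np.ndarray:
    """E[clip(X, lo, hi)] for X ~ Normal(mu, sigma), elementwise in mu."""
    from scipy.stats import norm
    mu = np.asarray(mu, dtype=float)
    if sigma == 0:
        return np.clip(mu, lo, hi)
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    return (lo * norm.cdf(a) + hi * norm.sf(b)
            + mu * (norm.cdf(b) - norm.cdf(a))
            - sigma * (norm.pdf(b) - norm.pdf(a)))


def generate_affect(prompts: pd.DataFrame, config: GeneratorConfig,
                    seed=None) -> pd.DataFrame:
    """Add tier-1 composites (and their ground-truth decomposition) and
    tier-2 ordinal items to every answered prompt.

    Tier 1: composite = clip(person mean + within deviation, 1, 4).  The
    stored ground-truth person mean is the person's long-run mean of the
    *clipped* composite (analytic truncated-normal expectation), so that
    the decomposition refers to the observable scale: a person's sample
    mean of composites is a consistent estimate of it, and person mean +
    deviation reconstructs the composite exactly.
    Tier 2: item j = round(person mean + deviation + noise), clipped to
    {1, 2, 3, 4}.
    """
    rng = _rng(config.seed + 2 if seed is None else seed)
    out = prompts.copy()
    n = len(out)
    dyad = out["dyad_id"].to_numpy()
    member = out["member"].to_numpy()
    max_items = max(ap.n_items for ap in config.affect_params.values())
    for scale in ("pa", "na"):
        comp = np.full(n, np.nan)
        pm_true = np.full(n, np.nan)
        items = np.full((n, max_items), np.nan)
        for mem in ("mother", "child"):
            ap = config.affect_params[(mem, scale)]
            person_means = ap.mean + ap.between_sd * rng.standard_normal(config.n_dyads)
            clipped_pm = _clipped_normal_mean(person_means, ap.within_sd)
            mask = (member == mem) & out["answered"].to_numpy()
            idx = np.flatnonzero(mask)
            pm = person_means[dyad[idx]]
            dev = ap.within_sd * rng.standard_normal(len(idx))
            latent = pm + dev
            comp[idx] = np.clip(latent, 1.0, 4.0)
            pm_true[idx] = clipped_pm[dyad[idx]]
            noise = ap.item_noise_sd * rng.standard_normal((len(idx), ap.n_items))
            iv = np.clip(np.rint(latent[:, None] + noise), 1, 4)
            items[idx, :ap.n_items] = iv
        out[scale] = comp
        out[f"{scale}_pm_true"] = pm_true
        out[f"{scale}_dev_true"] = comp - pm_true
        for j in range(max_items):
            out[f"{scale}_item{j + 1}"] = items[:, j]
    return out


# --------------------------------------------------------------------------
# Covariates


def simulate_icc_panel(between_sd: float, within_sd: float, n_subjects: int,
                       n_obs: int, mean: float = 0.0, seed=None):
    """Balanced one-way random-effects panel with a known variance ratio.

    Returns (values, subjects).  Composites here are NOT clipped to the 1-4
    response scale: this is the exact variance-components mechanism, used
    to study ICC recovery.  (Clipping, as applied to the tier-1 EMA
    composites, induces floor/ceiling effects that shift the raw-scale ICC
    for scales whose mean sits near a bound.)
    """
    rng = _rng(seed)
    subjects = np.repeat(np.arange(n_subjects), n_obs)
    person = mean + between_sd * rng.standard_normal(n_subjects)
    values = person[subjects] + within_sd * rng.standard_normal(len(subjects))
    return values, subjects


def generate_covariates(config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Dyad-level baseline covariates."""
    rng = _rng(config.seed + 3 if seed is None else seed)
    cp = config.covariates
    n = config.n_dyads
    return pd.DataFrame({
        "dyad_id": np.arange(n),
        "m_age_base": rng.normal(*cp.mother_age, size=n).round(2),
        "c_age_base": rng.normal(*cp.child_age, size=n).clip(8, 12).round(2),
        "c_male": (rng.random(n) >= cp.child_female_prob).astype(int),
        "m_hispanic": (rng.random(n) < cp.mother_hispanic_prob).astype(int),
        "c_hispanic": (rng.random(n) < cp.child_hispanic_prob).astype(int),
        "c_bmiz": rng.normal(*cp.child_bmiz, size=n).round(2),
    })


def attach_covariates(pairs: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Merge dyad covariates onto paired windows and derive per-window terms.

    Idempotent: covariate columns already present are left untouched.
    """
    fresh = [c for c in covariates.columns if c == "dyad_id" or c not in pairs.columns]
    out = pairs.merge(covariates[fresh], on="dyad_id", how="left")
    out["m_age_wave"] = out["m_age_base"] + 0.5 * out["wave"]
    out["c_age_wave"] = out["c_age_base"] + 0.5 * out["wave"]
    for mem in ("m", "c"):
        col = f"{mem}_response_ts"
        if col in out.columns and f"{mem}_resp_hour" not in out.columns:
            rt = pd.DatetimeIndex(out[col])
            out[f"{mem}_resp_hour"] = rt.hour + rt.minute / 60.0 + rt.second / 3600.0
    out["weekend"] = out["weekend"].astype(int)
    return out


# --------------------------------------------------------------------------
# Window outcomes from the APIM equations


def generate_window_outcomes(windows: pd.DataFrame, apim: ApimParams, seed=None,
                             mode: str = "model_scale", transform=None,
                             target_means=None,
                             out_cols=("m_out", "c_out")) -> pd.DataFrame:
    """Draw (mother, child) outcomes for paired windows from the dyadic model.

    Uses the generator's ground-truth affect decomposition (``*_pm_true`` /
    ``*_dev_true``), dyad random intercepts from ``G`` and window residuals
    from the correlated 2x2 residual covariance.

    ``model_scale`` returns the unbounded linear-model outcome (exact DGP,
    for recovery).  ``bounded`` centers the non-affect covariates at their
    sample means, shifts to ``target_means``, optionally applies an inverse
    Box-Cox ``transform=(lambda, offset)``, and truncates to [0, 45] --
    realistic magnitudes, biased for recovery.
    """
    if mode not in {"model_scale", "bounded"}:
        raise ValueError("mode must be 'model_scale' or 'bounded'")
    rng = _rng(seed)
    design = build_design(windows.assign(m_out=0.0, c_out=0.0),
                          use_true_affect=True)
    order = windows.sort_values(["dyad_id", "window_id"], kind="stable").index \
        if "window_id" in windows.columns else windows.sort_values(
            "dyad_id", kind="stable").index
    X = design.X
    if mode == "bounded":
        # interpret coefficients at covariate means so levels are realistic
        affect = {j for j, c in enumerate(design.columns)
                  if any(t in c for t in ("pa_", "na_", "intercept"))}
        Xc = X.copy()
        for j in range(X.shape[1]):
            if j in affect:
                continue
            rows = slice(0, None, 2) if design.columns[j].startswith("m:") else \
                slice(1, None, 2)
            col = Xc[rows, j]
            Xc[rows, j] = col - col.mean()
        X = Xc
    beta = apim.beta_vector(design.columns)
    lp = X @ beta
    if mode == "bounded" and target_means is not None:
        icols = [design.columns.index("m:intercept"), design.columns.index("c:intercept")]
        lp[0::2] += target_means[0] - apim.fixed.get("m:intercept", 0.0)
        lp[1::2] += target_means[1] - apim.fixed.get("c:intercept", 0.0)
        del icols

    dyads = design.dyads
    uniq, inv = np.unique(dyads, return_inverse=True)
    L_G = np.linalg.cholesky(apim.G + 1e-12 * np.eye(2))
    b = (L_G @ rng.standard_normal((2, len(uniq)))).T  # (D, 2)
    cov = apim.rho * apim.sigma_m * apim.sigma_c
    S = np.array([[apim.sigma_m ** 2, cov], [cov, apim.sigma_c ** 2]])
    L_S = np.linalg.cholesky(S)
    eps = (L_S @ rng.standard_normal((2, len(dyads)))).T  # (n, 2)

    y_m = lp[0::2] + b[inv, 0] + eps[:, 0]
    y_c = lp[1::2] + b[inv, 1] + eps[:, 1]
    if mode == "bounded":
        if transform is not None:
            lam, off = transform
            y_m = inverse_boxcox(y_m, lam, off)
            y_c = inverse_boxcox(y_c, lam, off)
        y_m = np.clip(y_m, 0.0, WINDOW_MINUTES)
        y_c = np.clip(y_c, 0.0, WINDOW_MINUTES)
    out = windows.copy()
    out.loc[order, out_cols[0]] = y_m
    out.loc[order, out_cols[1]] = y_c
    return out


def generate_bounded_outcomes(windows: pd.DataFrame, config: GeneratorConfig,
                              seed=None) -> pd.DataFrame:
    """Realistic per-window MVPA and sedentary minutes for both members.

    MVPA comes from the transformed-scale model through the inverse
    Box-Cox; sedentary from the minute-scale model; the pair is then
    jointly constrained so MVPA + sedentary <= 45 within each member.
    Target window means follow the study descriptives.
    """
    rng = _rng(config.seed + 4 if seed is None else seed)
    lam, off = config.boxcox_lambda, config.boxcox_offset

    def t(x):  # forward Box-Cox of a target raw mean
        return (math.pow(x + off, lam) - 1.0) / lam

    out = generate_window_outcomes(
        windows, config.apim_mvpa, seed=rng, mode="bounded",
        transform=(lam, off), target_means=(t(1.177), t(2.345)),
        out_cols=("m_mvpa_true", "c_mvpa_true"))
    out = generate_window_outcomes(
        out, config.apim_sedentary, seed=rng, mode="bounded",
        transform=None, target_means=(29.855, 26.847),
        out_cols=("m_sed_true", "c_sed_true"))
    for mem in ("m", "c"):
        mv, sd = out[f"{mem}_mvpa_true"], out[f"{mem}_sed_true"]
        out[f"{mem}_sed_true"] = np.minimum(sd, WINDOW_MINUTES - mv)
    # epoch-resolution targets (multiples of half a minute)
    for col in ("m_mvpa_true", "c_mvpa_true", "m_sed_true", "c_sed_true"):
        out[col] = (out[col] * 2).round() / 2.0
    return out


# --------------------------------------------------------------------------
# Epoch rendering


def render_epoch_counts(windows: pd.DataFrame, wave_start, n_days: int,
                        subject_id: str, member: str, config: GeneratorConfig,
                        seed=None, age: float | None = None,
                        thresholds: Thresholds = Thresholds()):
    """Render one subject-wave 30-s count series realizing planted windows.

    ``windows`` carries ``anchor_ts``, ``mvpa_min`` and ``sed_min`` for this
    subject's prompt-matched windows in the wave.  Within each 45-min
    window exactly round(2 x minutes) epochs land above the member's MVPA
    cut-point / below the sedentary cut-point, and the remainder strictly
    between.  Background wear is a sedentary/light mixture between the
    configured wear hours; the overnight gap and Poisson-planted daytime
    runs are all-zero (non-wear).  Returns (EpochSeries, truth frame) where
    the truth frame flags windows disturbed by planted non-wear.
    """
    rng = _rng(seed)
    wave_start = pd.Timestamp(wave_start)
    epd = 24 * 3600 // EPOCH_SECONDS
    n_epochs = n_days * epd
    index = wave_start + pd.to_timedelta(np.arange(n_epochs) * EPOCH_SECONDS, unit="s")

    thr = mvpa_threshold_cpm(member, age, thresholds)
    sed_hi = int(thresholds.sedentary_cpm * EPOCH_SECONDS / 60)     # exclusive cpm
    mv_lo = int(math.ceil(thr * EPOCH_SECONDS / 60))
    if mv_lo * 60 / EPOCH_SECONDS < thr:
        mv_lo += 1
    light_lo, light_hi = sed_hi, mv_lo - 1

    counts = np.zeros(n_epochs, dtype=np.int64)
    frac = np.arange(n_epochs) % epd / (epd / 24.0)   # hour of day per epoch
    wear_mask = (frac >= config.wear_start_hour) & (frac < config.wear_end_hour)
    n_wear = int(wear_mask.sum())
    sed_bg = rng.random(n_wear) < 0.6
    bg = np.where(sed_bg, rng.integers(1, sed_hi, size=n_wear),
                  rng.integers(light_lo, light_hi + 1, size=n_wear))
    counts[wear_mask] = bg

    # plant windows
    win_slices = []
    for rec in windows.itertuples(index=False):
        anchor = pd.Timestamp(rec.anchor_ts)
        if rec.mvpa_min + rec.sed_min > WINDOW_MINUTES:
            raise ValueError(
                f"window at {anchor} targets {rec.mvpa_min + rec.sed_min} min "
                f"> {WINDOW_MINUTES}")
        i0 = int(index.searchsorted(anchor, side="left"))
        i1 = int(index.searchsorted(anchor + pd.Timedelta(minutes=WINDOW_MINUTES),
                                    side="left"))
        n_win = i1 - i0
        n_mv = int(round(2 * rec.mvpa_min))
        n_sed = int(round(2 * rec.sed_min))
        n_light = n_win - n_mv - n_sed
        if n_light < 0:
            raise ValueError(f"window at {anchor} over-allocates its {n_win} epochs")
        vals = np.concatenate([
            rng.integers(mv_lo, 2 * mv_lo, size=n_mv),
            rng.integers(1, sed_hi, size=n_sed),
            rng.integers(light_lo, light_hi + 1, size=n_light),
        ])
        rng.shuffle(vals)
        counts[i0:i1] = vals
        win_slices.append((i0, i1))

    # plant non-wear runs inside wear hours (may disturb windows)
    planted = np.zeros(n_epochs, dtype=bool)
    for day in range(n_days):
        for _ in range(rng.poisson(config.nonwear_runs_per_day)):
            dur = rng.uniform(*config.nonwear_duration_min)
            if rng.random() < config.long_nonwear_prob:
                dur = 400.0
            n_run = int(round(dur * 60 / EPOCH_SECONDS))
            lo = day * epd + int(config.wear_start_hour * epd / 24)
            hi = day * epd + int(config.wear_end_hour * epd / 24) - n_run
            if hi <= lo:
                continue
            s = int(rng.integers(lo, hi))
            counts[s:s + n_run] = 0
            planted[s:s + n_run] = True

    truth = windows.copy().reset_index(drop=True)
    truth["full_wear"] = [not planted[i0:i1].any() for i0, i1 in win_slices]
    return EpochSeries(subject_id, index, counts), truth


# --------------------------------------------------------------------------
# High-level generators


def _complete_pairs(config: GeneratorConfig, seed: int):
    """Schedule -> missingness -> affect -> pairing -> covariates, keeping
    pairs where both members answered and the child was with the mother."""
    prompts = generate_schedule(config, seed)
    prompts = apply_missingness(prompts, config, seed + 1)
    prompts = generate_affect(prompts, config, seed + 2)
    pairs = pair_prompts(prompts)
    keep = (pairs["m_answered"].astype(bool) & pairs["c_answered"].astype(bool)
            & (pairs["with_mother"].fillna(0) == 1))
    pairs = pairs[keep].reset_index(drop=True)
    covs = generate_covariates(config, seed + 3)
    return prompts, attach_covariates(pairs, covs)


def simulate_recovery_dataset(config: GeneratorConfig, seed: int,
                              outcome: str = "mvpa",
                              mode: str = "model_scale") -> pd.DataFrame:
    """Analysis-ready paired windows with outcomes from known parameters.

    Subsamples complete pairs to ``target_windows_per_dyad`` per dyad (the
    study-scale analysis set), then draws outcomes from the requested
    model's generating truth.  Columns include both the raw composites
    (``m_pa`` ...) used by the estimation pipeline and the ground-truth
    decomposition (``*_pm_true`` / ``*_dev_true``).
    """
    if outcome not in {"mvpa", "sedentary"}:
        raise ValueError("outcome must be 'mvpa' or 'sedentary'")
    _, pairs = _complete_pairs(config, seed)
    k = config.target_windows_per_dyad
    rng = _rng(seed + 4)
    picks = []
    for _, grp in pairs.groupby("dyad_id"):
        if len(grp) > k:
            picks.append(grp.iloc[np.sort(rng.choice(len(grp), size=k, replace=False))])
        else:
            picks.append(grp)
    pairs = pd.concat(picks, ignore_index=True)
    apim = config.apim_mvpa if outcome == "mvpa" else config.apim_sedentary
    transform = ((config.boxcox_lambda, config.boxcox_offset)
                 if (mode == "bounded" and outcome == "mvpa") else None)
    return generate_window_outcomes(pairs, apim, seed=seed + 5, mode=mode,
                                    transform=transform)


@dataclass
class SimulatedStudy:
    """Full synthetic study: prompts, paired windows with planted outcomes,
    per-(dyad, member, wave) epoch series, and per-window ground truth."""

    config: GeneratorConfig
    prompts: pd.DataFrame
    pairs: pd.DataFrame
    covariates: pd.DataFrame
    series: dict           # (dyad_id, member, wave) -> EpochSeries
    window_truth: pd.DataFrame
    child_ages: dict       # dyad_id -> baseline age


def simulate_study(config: GeneratorConfig, seed=None) -> SimulatedStudy:
    """End-to-end synthetic study including rendered accelerometer streams."""
    seed = config.seed if seed is None else seed
    prompts = generate_schedule(config, seed)
    prompts = apply_missingness(prompts, config, seed + 1)
    prompts = generate_affect(prompts, config, seed + 2)
    covs = generate_covariates(config, seed + 3)
    all_pairs = attach_covariates(pair_prompts(prompts), covs)
    both = (all_pairs["m_answered"].astype(bool)
            & all_pairs["c_answered"].astype(bool))
    planted = generate_bounded_outcomes(all_pairs[both].reset_index(drop=True),
                                        config, seed + 4)

    series = {}
    truths = []
    rng = _rng(seed + 5)
    child_age = dict(zip(covs["dyad_id"], covs["c_age_base"]))
    for dyad in range(config.n_dyads):
        for wave in range(config.n_waves):
            wave_start = _STUDY_START + pd.Timedelta(days=wave * _WAVE_SPACING_DAYS)
            sub = planted[(planted["dyad_id"] == dyad) & (planted["wave"] == wave)]
            for mem, pfx in (("mother", "m"), ("child", "c")):
                w = sub[["anchor_ts", f"{pfx}_mvpa_true", f"{pfx}_sed_true"]].rename(
                    columns={f"{pfx}_mvpa_true": "mvpa_min",
                             f"{pfx}_sed_true": "sed_min"})
                sid = f"d{dyad:03d}_{mem}_w{wave}"
                es, tr = render_epoch_counts(
                    w, wave_start, config.n_days, sid, mem, config,
                    seed=rng, age=child_age[dyad] if mem == "child" else None)
                series[(dyad, mem, wave)] = es
                tr["dyad_id"], tr["member"], tr["wave"] = dyad, mem, wave
                truths.append(tr)
    window_truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    return SimulatedStudy(config=config, prompts=prompts, pairs=planted,
                          covariates=covs, series=series,
                          window_truth=window_truth, child_ages=child_age)
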