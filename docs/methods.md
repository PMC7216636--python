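# Methods

This note records the model, the synthetic-data generator's assumptions,
the numerical choices, and the limits of what the test suite can show.

## The dyadic model and its estimator

The analysis unit is a prompt-matched 45-min window with one MVPA (or
sedentary) outcome per dyad member. The two-intercept specification
stacks two rows per window and multiplies every predictor by a member
dummy, so mothers and children get separate intercepts, covariate
effects, actor effects (own affect) and partner effects (the other
member's affect), with no global intercept. Affect predictors enter
twice: as the person's mean over all their included prompts
(between-person) and as the prompt-level deviation from that mean
(within-person). Dependence is carried by (i) a 2×2 covariance `G` of
mother/child dyad-level random intercepts and (ii) a 2×2 within-window
residual covariance with member-specific SDs `σ_m ≠ σ_c` and cross-member
correlation `ρ`.

**Likelihood.** All windows in the analysis set are complete pairs, so a
dyad with `n` windows has marginal covariance `V = I_n ⊗ S + J_n ⊗ G`
(`S` the residual block, `J` the all-ones matrix). Writing `P = J/n`,
`V = (I−P) ⊗ S + P ⊗ (S + nG)` is an exact spectral split into orthogonal
idempotents, so `V⁻¹` and `log|V|` need only the 2×2 matrices `S` and
`S + nG`. Per-dyad cross-products are precomputed once; each likelihood
evaluation is then O(dyads × p²), and a full study-scale fit (9,250
windows, 32 fixed effects, 6 variance parameters) takes ~1 s. A dense
multivariate-normal evaluation is kept in the test suite as the
independent oracle (agreement to 1e-8 on ≤ 5-dyad instances).

**Optimization.** `β` is profiled out by GLS at each variance-parameter
value. The six variance parameters are optimized on an unconstrained
scale — log-Cholesky for `G`, log for the σs, atanh for `ρ` — by L-BFGS-B
from three deterministic starts (OLS-residual moment estimates; a generic
10 %-between split; the moment start shrunken toward independence); the
best profiled likelihood wins. ML is the default; REML adds the
log-determinant of the projected information to the profiled objective.
Estimates with `G` nearly singular or `|ρ| → 1` are flagged as boundary
but returned.

**Inference.** Fixed effects get Wald z tests from the GLS covariance at
the optimum (stars at .05/.01/.001). With ~9,000 window pairs,
denominator-degrees-of-freedom corrections (Satterthwaite/Kenward-Roger)
are immaterial, so the normal reference is used; this is a documented
divergence from lme-style t tests. CIs for the intercept correlation `r`
and residual correlation `ρ` are Wald intervals on the atanh scale
(delta method through a finite-difference Hessian of the profiled
objective), back-transformed.

## Accelerometry rules

Counts arrive on a uniform 30-s grid (10-s exports are re-integrated by
summation). Non-wear is any maximal zero-count run strictly longer than
60 min, judged over continuous time including across midnight, with no
artifact-spike tolerance. A day is valid with ≥ 600 wear minutes.
Intensity uses counts-per-minute = 2 × counts/30 s: sedentary is wear
below 100 cpm (exclusive), MVPA is wear at or above the member cut-point
(inclusive) — 2020 cpm for adults, and for children the cpm solving the
Freedson children's MET equation
`METs = 2.757 + 0.0015·cpm − 0.08957·age − 0.000038·cpm·age`
at 4 METs (≈ 1910 cpm at age 10, increasing with age). All three
cut-points and both wear rules are configuration keys, and the run log
records the values used. The boundary conventions (MVPA ≥, sedentary <)
are fixed and tested.

## Windows and the funnel

A mother prompt and a child prompt pair iff they fall in the same
scheduled hour window; the accelerometry window for the pair is
`[mother prompt + 15 min, +45 min)`, half-open, an epoch belonging iff
its start lies inside — both members' minutes are extracted at this
shared anchor. Partial wear is not rescaled (accumulated minutes). The
funnel keeps, in order: answered self-reports; reports with ≥ 30 valid
wear minutes in their prompt-matched window on a valid day (valid-day
status must hold for each member separately, hence for both members of a
surviving pair); paired occasions where the child reported being with
the mother; complete pairs (both members answered, both accelerometer-
valid, both composites present). EMA response time enters the model as
decimal hours since midnight; weekend is Saturday/Sunday of the anchor
date; person means pool all waves.

## Transforms, reliability, descriptives

MVPA minutes are strongly right-skewed and are Box-Cox transformed,
`((y+offset)^λ − 1)/λ`, with offset 1 because zero-MVPA windows exist;
λ = 0.06 by default (the value the original analysis reports), with
λ = 0 (log) and profile-ML options — the ML search uses a grid on
[−2, 2] at step 0.01 refined by bounded golden-section on the Box-Cox
profile likelihood. Sedentary minutes (skewness ≈ −0.4) stay in raw
minutes; the transform-when-|skew| > 1 rule reproduces that asymmetric
treatment. Skewness is adjusted Fisher–Pearson G1. Reliability is
McDonald's ω from a one-factor ML model for ≥ 3 items; with 2 items the
model is under-identified, so equal standardized loadings are imposed
(ω = 2r/(1+r), Spearman-Brown), and the method is tagged in the result.
ICCs come from a null two-level model (random subject intercept,
profiled grand mean) estimated by ML, consistent with the main
estimator; the descriptive correlation table reports person-mean
correlations above the diagonal, pooled deviation correlations below,
and ICCs on the diagonal.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Cohort**: 185 dyads, six 7-day waves 182 days apart. Baseline
  covariates: mother age N(41.03, 5.86); child age N(9.51, 0.90) clipped
  to the 8–12 recruitment band; child female 53 %; Hispanic 51 %
  (mothers) / 59 % (children); child BMI-z N(0.49, 1.10).
* **Schedule**: eligible hour windows 07:00–21:00; mothers get 8
  (weekend) / 4 (weekday) windows, children 7 / 3, children's windows a
  random subset of the mother's (surplus mother windows stay unpaired
  and are excluded by the pairing filter, mirroring the study's funnel).
  Hour windows are drawn uniformly among arrangements with at least one
  empty hour between them, which guarantees the ≥ 60-min within-member
  spacing; the mother's minute is uniform in [0, 30), the child's in
  [30, 60), making the mean mother→child gap 30 min (the study observed
  29.5). Compliance is Bernoulli 0.803 (mothers) / 0.769 (children);
  answered prompts get a response delay uniform in the 10-min
  accessibility span; the child-with-mother flag is Bernoulli 0.774,
  chosen so the with-mother share of valid occasions matches the
  study's funnel proportions.
* **Affect**: per member × valence, a person mean N(grand mean,
  between-SD) plus prompt deviations N(0, within-SD), calibrated to the
  study descriptives (e.g. child negative affect mean 1.26, total SD
  0.515, ICC 0.293). Tier-1 composites are clipped to the 1–4 response
  scale; tier-2 items add N(0, σ_item) noise and round to {1,…,4}, with
  σ_item set so the implied ω matches the reported reliabilities
  (.71/.90 for the 2-item positive scales, .83/.85 for the 3-item
  negative scales).
* **Clipping and ground truth.** Clipping creates floor effects for the
  negative-affect scales (a third of child-NA draws hit 1). Two
  consequences are deliberate design choices. First, the generator's
  ground-truth person mean is the analytic truncated-normal expectation
  `E[clip(μ_i + W, 1, 4)]` — the person's long-run mean on the
  *observable* scale — so the deviation is composite minus that, the
  decomposition reconstructs the composite exactly, and a refit's sample
  person means estimate the DGP regressors consistently; defining truth
  on the latent scale instead demonstrably rescales between-person
  coefficients on recovery. Second, the raw-scale ICC of clipped child
  NA sits near 0.24 rather than the latent ratio 0.293; ICC-recovery
  experiments therefore use `simulate_icc_panel`, the exact (unclipped)
  variance-components mechanism, and the floor effect itself is covered
  by a dedicated test.
* **Outcomes**: `model_scale` mode draws outcomes exactly from the APIM
  equations (fixed effects → linear predictor on the ground-truth
  decomposition; random intercepts from `G`; correlated residuals) — the
  clean DGP used for recovery. `bounded` mode centers the non-affect
  covariates at their sample means, shifts levels to the observed window
  means, maps MVPA through the inverse Box-Cox, and truncates to [0, 45]
  with MVPA + sedentary ≤ 45 — realistic magnitudes for end-to-end runs,
  and documented as biased for recovery (truncation is not part of the
  fitted model).
* **Epoch rendering**: within each planted window exactly
  `round(2 × minutes)` epochs carry counts above the member's MVPA
  cut-point / below the sedentary cut-point (the remainder strictly
  between), so classification and extraction reproduce the planted
  minutes exactly when no non-wear intrudes. Background wear (07:00–
  22:30) is a sedentary/light mixture with counts ≥ 1; the overnight gap
  is zeros; Poisson-planted daytime zero runs (70–120 min, occasionally
  400 min to invalidate a day) may overlap windows, and the ground truth
  flags those windows as disturbed.
* **What it does not emulate**: diurnal affect rhythms, autocorrelation,
  reactive (MNAR) missingness, multi-axis accelerometer physics, partial
  wave participation. Passing recovery tests therefore demonstrates
  estimator correctness under the stated model, not robustness to those
  real-data features.

## Recovery experiments and problem sizes

The parameter-recovery experiment simulates the analysis set directly
(no epoch rendering): complete pairs are subsampled to 50 windows per
dyad (~9,250 pairs across 185 dyads, the study's analysis-set scale),
outcomes are drawn in `model_scale` mode from the published estimates as
truth, affect is re-centered from the composites the way the estimation
pipeline does, and the model is refit by ML. One simulate+fit replicate
takes ~3 s; tests and the acceptance script average 20 replicates
(fixed-effect means within 0.5 × reported SE of truth; intercept
correlation within ±0.05; residual correlation within ±0.03), the
replicate-averaged form of the acceptance design, which is stricter on
bias and insensitive to the luck of a single draw. ICC recovery averages
10 panels of 185 × 50. The full epoch-rendering pipeline at study scale
(≈ 45 M epochs) runs in ~30 s within ~1.4 GB; tests exercise it at 6–25
dyads.

## Known limitations

* Wald-z inference only; no small-sample df corrections (irrelevant at
  this scale, wrong for very small studies).
* The two-member compound-symmetry factorization requires complete
  pairs; designs with singleton rows would need the dense path.
* `bounded`-mode recovery is intentionally biased (truncation); only
  `model_scale` mode is a fit-consistent DGP.
* The ω estimator assumes a single factor; with 2 items it reports the
  Spearman-Brown equivalent, which understates ω if loadings are
  unequal.
* Age-at-wave is baseline age plus 0.5 × wave, so single-wave designs
  make it collinear with baseline age; the fitter rejects such designs
  as rank-deficient rather than silently dropping a column.
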