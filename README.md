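# dyadema

Dyadic EMA + accelerometry analysis: from mother–child ecological momentary
assessment (EMA) prompts and epoch-level activity counts to the
two-intercept actor–partner interdependence multilevel model (APIM).

## The problem

In EMA studies of families, a mother and her child each report momentary
positive and negative affect several times a day while wearing
accelerometers. The scientific question is dyadic: does a person's
momentary affect predict not only their *own* moderate-to-vigorous
physical activity (MVPA) and sedentary time in the minutes around the
prompt (actor effects), but also their *partner's* (partner effects)?
Because the two members' outcomes within a dyad are interdependent,
member-wise regressions are biased; the field's answer is the APIM
embedded in a multilevel model.

`dyadema` implements the full analysis chain for this design and — since
such datasets are rarely deposited — a synthetic-data generator that
emulates the study conditions with known ground truth, so every stage is
testable end to end:

* **simulate** (`dyadema.simulate`): signal-contingent prompt schedules
  (mothers 8 weekend / 4 weekday prompts, children 7 / 3, mother in the
  first half-hour of a shared hour window, child in the second half,
  ≥ 60 min between a member's prompts), 1–4 bounded affect with realistic
  intraclass correlations, ~80 %/77 % compliance, covariates, and window
  outcomes drawn from the APIM equations; optional rendering of 30-s
  ActiGraph-style count streams realizing the planted minutes.
* **accelerometry** (`dyadema.accelerometry`): non-wear (> 60 continuous
  minutes of zero counts), valid days (≥ 10 h wear), cut-point
  classification (sedentary < 100 cpm; adult MVPA ≥ 2020 cpm; child MVPA
  from the age-specific 4-MET Freedson equation).
* **windows** (`dyadema.windows`): prompt pairing, the 45-min
  prompt-matched window anchored 15 min after the mother's prompt, and the
  inclusion funnel (answered reports → ≥ 30 valid wear minutes →
  child-with-mother occasions → complete pairs).
* **scoring** (`dyadema.scoring`): affect composites, McDonald's ω,
  person-mean (group-mean) centering, Box-Cox transform of skewed MVPA
  minutes (λ = 0.06 by default, ML and log options).
* **descriptives** (`dyadema.descriptives`): ICCs from null two-level
  models and hybrid between/within correlation tables.
* **apim** (`dyadema.apim`): the computational core — the stacked
  two-intercept design and a maximum-likelihood fitter for the dyadic
  mixed model with correlated random intercepts and correlated,
  heteroscedastic member residuals.

## The model

For window *t* of dyad *d*, stack the mother (m) and child (c) outcomes.
With member dummies and no global intercept,

```
y_mdt = x'_mdt β_m + a_m PA^dev_mdt + ... + p_m PA^dev_cdt + ... + b_md + ε_mdt
y_cdt = x'_cdt β_c + a_c PA^dev_cdt + ... + p_c PA^dev_mdt + ... + b_cd + ε_cdt

(b_md, b_cd)' ~ N(0, G),   G = [[σ²_bm, r σ_bm σ_bc], [r σ_bm σ_bc, σ²_bc]]
(ε_mdt, ε_cdt)' ~ N(0, S), S = [[σ²_m, ρ σ_m σ_c], [ρ σ_m σ_c, σ²_c]]
```

where each affect predictor is split into a within-person deviation
(`*_dev`) and a between-person mean (`*_pm`), *a* are actor and *p*
partner coefficients, *r* is the correlation between the members' random
intercepts and *ρ* the within-window residual correlation. Because every
window is a complete pair, the per-dyad marginal covariance
`I ⊗ S + J ⊗ G` factorizes exactly into 2×2 blocks, so the profiled ML /
REML fit of ~9,000 window pairs takes about a second. Inference is Wald-z;
CIs for *r* and *ρ* use the atanh scale.

## Worked example

Simulate one study-scale analysis set (185 dyads, ~50 paired windows per
dyad) with the published MVPA-model estimates as generating truth, refit
it with the package's estimator, and read off the headline parameters:

```python
from dyadema import pipeline
from dyadema.simulate import GeneratorConfig

fit = pipeline.recovery_experiment("mvpa", seeds=[1],
                                   config=GeneratorConfig())[0]
print(f"windows: {fit.n_windows}, dyads: {fit.n_dyads}")
stars = fit.fixed_effects()["stars"]
for term in ["c:pa_dev", "m:partner_pa_dev", "c:partner_na_pm"]:
    i = fit.columns.index(term)
    print(f"{term:18s} b = {fit.beta[i]: .3f}  SE = {fit.se[i]:.3f}  {stars[i]}")
print(f"intercept correlation r = {fit.r_intercepts:.3f}  "
      f"(95% CI {fit.r_ci[0]:.2f}-{fit.r_ci[1]:.2f})")
print(f"residual correlation rho = {fit.rho:.3f}  "
      f"(95% CI {fit.rho_ci[0]:.2f}-{fit.rho_ci[1]:.2f})")
```

Output for seed 1:

```
windows: 9250, dyads: 185
c:pa_dev           b =  0.087  SE = 0.010  ***
m:partner_pa_dev   b =  0.038  SE = 0.008  ***
c:partner_na_pm    b = -0.231  SE = 0.096  *
intercept correlation r = 0.399  (95% CI 0.23-0.54)
residual correlation rho = 0.066  (95% CI 0.05-0.09)
```

Reading: when the child's momentary positive affect is higher than their
own usual level, the child's transformed MVPA in the prompt-matched
window rises (`c:pa_dev`, actor effect) and so does the mother's
(`m:partner_pa_dev`, partner effect); mothers with higher average
negative affect have children with less MVPA (`c:partner_na_pm`,
between-subject partner effect). The single-replicate estimates scatter
around the generating truths (0.071, 0.030, −0.201, r = 0.546, ρ = 0.06)
with the sampling error a 185-dyad study implies; averaging replicates
(see below) centers them tightly.

The full pipeline — epoch rendering, wear rules, windowing, funnel,
centering, Box-Cox, fit, report files — runs from the shell:

```
dyadema reproduce --outcome mvpa --seed 1 --out out/
dyadema simulate --n-dyads 25 --n-waves 2 --seed 5 --out bundle/
dyadema process --in bundle/ --outcome sedentary --out out2/
```

`reproduce` at study scale takes ~30 s and ~1.4 GB; it writes the funnel,
a descriptives table (means/SDs/ICCs and between/within correlations),
fixed- and random-effect tables, a JSON fit record and a run log with
every threshold and transform actually used.

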