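# ptarmigan-rsf

Resource selection functions (RSF) for willow ptarmigan (*Lagopus lagopus*)
estimated from line-transect distance-sampling surveys, with a synthetic
survey simulator so the entire analysis is testable end to end.

## The problem

Willow ptarmigan is a red-listed alpine grouse in Norway. National
line-transect surveys (pointing-dog crews walking systematic 500-m-spaced
transects, recording each detection's perpendicular distance to the line)
yield thousands of bird locations — but detection declines with distance
from the line, survey effort differs between areas, and bird density varies
regionally. This package implements the full chain needed to turn such
surveys into a habitat-suitability model and map:

1. **Quality control** — discard locations beyond the 200-m transect buffer
   and locations whose reported perpendicular distance deviates more than
   30 m from the geometry-derived distance, with a full accounting ledger.
2. **Detection-adjusted availability** — generate 3 available points per km
   of effort uniformly in the buffers, fit a half-normal detection function
   g(d) = exp(−d²/2σ²) to the used distances, and keep each available point
   *i* only when a uniform draw Pᵢ < g(dᵢ). Used and available points then
   share the same distance distribution, so the used–available contrast is
   detection-free.
3. **Covariates** — vegetation class (25 satellite map codes pooled to 16
   modelling classes + non-habitat), deviation from the regional empirical
   timberline (elevation − RET), slope, and aspect (cos/sin components and
   a 5-level category), standardized to zero mean and unit SD.
4. **Selection model** — a mixed-effects logistic regression of used (1)
   vs available (0) locations with a random intercept per survey area:

       logit P(y = 1 | x, area j) = β'x + uⱼ,   uⱼ ~ N(0, σᵤ²)

   fitted by maximizing the Laplace-approximated marginal likelihood
   (cross-checked in tests against adaptive Gauss–Hermite quadrature and,
   in the zero-variance limit, against the plain logistic MLE). Candidate
   models (vegetation always included; timberline, slope, aspect terms
   optional; quadratics for timberline and slope) are compared by AIC with
   the parsimony rule: among models within ΔAIC < 2, take the fewest
   parameters.
5. **RSF and map** — the exponential RSF w(x) = exp(β₁x₁ + β₂x₂ + …)
   (no intercept, no random effects), max-scaled to (0, 1], cut into 10
   quantile bins ranked 1 (low) to 10 (high relative probability of
   selection), and pushed across the raster landscape.
6. **Validation** — Boyce-style k-fold and spatial-block cross-validation:
   Spearman rank correlation between bin rank and the count (or
   area-adjusted count) of used locations per bin.

Because the national survey database and rasters are not redistributable,
the package ships a first-class simulator (`ptarmigan_rsf.synthetic`) that
generates landscapes, systematic transect layouts, and observations with
exactly the statistical structure the model assumes — including known true
β, per-area intercepts, and half-normal detection — plus a packaged
fixture with the published per-class used/available counts (12,146 used,
38,149 available).

## Worked example

```python
from ptarmigan_rsf import synthetic as syn, covariates as cov
from ptarmigan_rsf.rsf import ModelSpec, build_design, fit_mixed_logistic
from ptarmigan_rsf.validation import cv_boyce

cfg = syn.RecoveryConfig(rows=320, cols=320, n_areas=8,
                         expected_candidates_per_km=3.5)
data, params, truth, extras = syn.simulate_modelling_data(cfg, seed=1)
print(extras["n_used"], extras["n_available"])   # 1122 811

spec = ModelSpec(timberline="quadratic", slope="quadratic")
y, X, groups = build_design(data, spec)
levels = [cov.REFERENCE_CLASS] + [c[4:-1] for c in X.columns
                                  if c.startswith("veg[")]
fit = fit_mixed_logistic(y, X, groups, std_params=params,
                         spec=spec, veg_levels=levels)
print(round(fit.sigma_u, 3), fit.K)              # 0.349 11
print(round(fit.beta["veg[Herb-rich meadows]"], 3))   # 1.514
```

The herb-rich-meadow coefficient 1.514 (SE 0.319) is the log relative
selection strength versus the reference class (exposed alpine ridges):
meadows are selected ≈ e^1.5 ≈ 4.5× more strongly, matching the simulated
truth of 1.1 within two standard errors. The quadratic timberline and
slope terms place the fitted selection optima at 17.7 m above the
timberline and 8.3° slope (truth: 25 m and 10°), recovered via
`-β₁/(2β₂)` back-transformed through the stored standardization. Five-fold
cross-validation of this fit gives per-fold Spearman ρ of
0.926, 0.997, 0.988, 0.988, 0.960 — used locations pile up in high-ranked
bins, as they should under strong simulated selection.

The survey-summary fixture is available from the command line:

```bash
ptarmigan-rsf fixture        # totals 12146 / 38149 and naive ratios
ptarmigan-rsf run --seed 1 --output-dir runs/demo   # full pipeline
```

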