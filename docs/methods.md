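# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices and the known limitations of `ptarmigan-rsf`.

## The selection model

Used locations (survey detections that pass QC) are contrasted with
available locations in a logistic regression. Writing x for the covariate
vector and j for the survey area,

    logit P(y = 1 | x, area j) = α + β'x + u_j,   u_j ~ N(0, σ_u²).

The per-area random intercept absorbs between-area differences in density
and in the used:available ratio (available counts are driven by effort,
not by bird numbers). The exponential RSF used for prediction,
w(x) = exp(β'x), deliberately excludes both α and u_j: only relative
selection strength transfers beyond the surveyed areas, and after
max-scaling a constant factor is immaterial anyway.

Fixed-effect structure: vegetation class is always included (treatment
coding, 16 classes, exposed alpine ridges as reference — the sparsest
natural baseline). Timberline deviation and slope may enter linearly or
with an added quadratic; aspect may enter as a 5-level category (flat as
reference, a documented choice — the category of level ground) or as the
standardized cos/sin components. The default candidate grid crosses
timberline {linear, quadratic} × slope {none, linear, quadratic} × aspect
{none, categorical, N–S, N–S + E–W} = 24 models; the grid is configurable.
Model choice is by AIC with the parsimony rule: among models within
ΔAIC < 2 of the best, the one with smallest K wins (K counts fixed effects
plus the random-intercept variance, so the vegetation + timberline² +
slope² structure has K = 1 + 15 + 4 + 1 = 21).

### Fitting

The marginal likelihood integrates each u_j out. With a scalar random
intercept the integrand is unimodal and log-concave, so we maximize the
Laplace approximation: per-area posterior modes û_j by damped Newton
(vectorized across areas, warm-started), and an outer L-BFGS-B over
(β, log σ_u) with fully analytic gradients (envelope term plus the
curvature correction obtained by implicit differentiation of the mode).
Convergence requires gradient sup-norm below 1e-4 after an optimizer run
with gtol 1e-8; log σ_u is bounded in [−8, 3], so a zero-variance truth
drives the estimate to the boundary where the fit coincides with the plain
logistic MLE (verified to 1e-3 in tests). Standard errors come from the
observed information, obtained by central finite differences of the
analytic gradient. An independent evaluator of the same marginal
likelihood by adaptive Gauss–Hermite quadrature (mode-centred,
curvature-scaled, 51 nodes) serves as the oracle in tests; on small
two-group data the Laplace log-likelihood agrees to < 0.05.

Separation (a binary term whose support contains only one response value)
is detected and warned about, not silently regularized.

## Quality control

Two filters, applied in order, with every step appended to a ledger
(counts of used locations, surveys, transects, areas):

1. buffer rule — geometry-derived perpendicular distance > 200 m removes
   the location (boundary inclusive: exactly 200 m is kept);
2. deviation rule — |reported − computed| > 30 m removes the location
   (strict: exactly 30 m is kept). 30 m is the vegetation raster
   resolution.

The buffer test uses the computed, not the reported, distance; locations
are only kept or removed, never moved or snapped. Surveys left without
observations are dropped from the used side only — their transects still
generate availability, since absence of detections is information about
effort, not about habitat.

## Detection-adjusted availability

Per survey, round(3 × transect km) candidate points are drawn uniformly on
the flat-capped 200-m buffer polygon (nearest-integer rounding, ties away
from zero, so 2.5 km → 8). A half-normal detection function is fitted to
the used perpendicular distances; untruncated, its MLE is the closed form
σ̂ = √(Σd²/n), which the numerical optimizer reproduces. A
likelihood-normalized-on-[0, W] truncated variant is available
(`truncation_m=`); with observations already cut at 200 m and σ ≈ 60 m the
difference is negligible, and the closed-form default keeps the estimator
exactly checkable. Candidates are kept when an independent uniform draw
falls below g(d) = exp(−d²/2σ̂²); the post-thinning distance distribution
is the truncated half-normal on [0, 200], verified by KS test. One pooled
detection function is fitted across all areas (the minimal reading of the
protocol); per-survey RNG substreams are keyed by a CRC of the survey id,
so adding a survey never perturbs another survey's points.

## Covariates

Vegetation codes 1–5 (lowland/coniferous forest) pool into one class;
codes 6–20 are kept as published; 21–25 (water, agriculture, built-up,
unclassified/shadow) are non-habitat, removed from both sides of the
contrast. Aspect a (degrees clockwise from north) yields N = cos r,
E = sin r with r = a·2π/360, plus a category with half-open sectors
(north [315°, 360°) ∪ [0°, 45°), east [45°, 135°), south [135°, 225°),
west [225°, 315°)) and "flat" whenever slope ≤ a configurable threshold
(default exactly 0 — appropriate for the smooth synthetic DEM; real DEMs
may need a small positive value). Timberline deviation is elevation − RET,
positive above the treeline. Slope and aspect derive from the elevation
raster by Horn's 8-neighbour method (row 0 = north, replicate-padded
edges); extraction is cell-containing lookup with no interpolation, as
appropriate for categorical rasters.

Continuous terms are standardized to mean 0, SD 1 (sample SD, n−1) on the
combined used+available modelling set; the parameters are stored with the
fit so map prediction and the quadratic-optimum back-transform
x* = m + s·(−β₁/2β₂) are well defined. Quadratic model terms are squares
of the standardized value, not re-standardized. The aspect components are
standardized after the trigonometric transform (they are the model terms).

## Validation and mapping

K-fold plans partition used and available points jointly, stratified on
the response so each fold's used:available ratio matches the global one
(stabilizes small folds). Per fold: standardization and model are refitted
on the training folds; the held-out predictions are max-scaled and cut at
their own 10-quantile edges; the Spearman rank correlation between bin
rank (1–10) and the per-bin count of used locations is the fold's score
(t-approximation p-values, the conventional report for 10 ranks).
Spatial blocking replaces random folds with leave-one-region-out; region
geometry is user input. A test-fold vegetation class unseen in training
cannot be predicted; such points are dropped with a warning.

Mapping evaluates w(x) on every habitat cell, scales by the map maximum,
and applies the quantile edges computed from the modelling-sample
predictions unchanged — so the map's bins are *not* equal-area by
construction, which is exactly what makes the per-bin coverage table
informative. Non-habitat and nodata cells are nodata in the bin raster.
Independent point sets are validated by dividing per-bin counts by per-bin
areal availability before rank correlation.

## The synthetic generator

The generator reproduces the structure the analysis assumes, on a planar
metre grid (no geodesy; buffers and distances are Euclidean at survey
scale, 30-m cells):

* **Elevation**: Gaussian-filtered white noise with a fixed amplitude
  factor, ≈120 m SD at the default smoothness of 6 cells; relief (and
  hence slope) shrinks as smoothness grows, so the infinite-smoothness
  limit is flat terrain. The timberline raster varies smoothly over a
  ±~80 m range around 900 m.
* **Vegetation**: argmax over per-class smoothed noise fields shifted by
  log class weights — spatially autocorrelated patches (default
  correlation scale 4 cells ≈ 120 m) whose marginal frequencies track the
  weights. Default weights follow the availability shares of the national
  survey summary; simulation runs directly on the 16 modelling classes
  plus one non-habitat code, with a 25-code mode to exercise
  reclassification.
* **Transects**: parallel lines every 500 m (the national protocol's map
  grid), both extent edges included, partitioned into rectangular survey
  areas.
* **Observations**: an inhomogeneous Poisson process with intensity
  ∝ exp(β'x + a_j) in a 250-m band around each transect (wider than the
  200-m buffer so the buffer filter has work to do), normalized per area
  so the configured candidates-per-km is the area-mean rate; detection
  thins candidates by exp(−d²/2σ²) with σ = 60 m. σ = 60 m is a simulation
  choice — the survey protocol implies detection decay but no published
  scale; 60 m puts ~62 % of detections within one σ of the line on a
  200-m half-width, a realistic figure for pointing-dog surveys. Reported
  distances add N(0, 5 m) noise plus 2 % gross outliers (SD 80 m) to
  exercise the 30-m deviation filter.

Because availability points are thinned by the *same* detection law that
generated the observations, the used–available logistic contrast recovers
β on the link scale; truth-implied coefficients for standardized terms
follow from x = m + s·z (a linear raw term b₁ with quadratic b₂
contributes (b₁ + 2b₂m)s to z and b₂s² to z²).

What the generator does **not** emulate: covey/brood clustering (each
location independent), sex/age structure, observer or dog behaviour,
functional responses (availability-dependent selection), geodesic
distortion, and real-map artefacts such as misregistered rasters. Passing
recovery tests therefore demonstrate correctness of the estimators under
the model's own assumptions, not robustness to their violation.

## Study conditions for the recovery experiment

The default recovery configuration uses a 14.4 × 14.4 km landscape
(480×480 cells), 29 transects in 12 survey areas, 4 annual surveys,
and a reduced six-class vegetation mixture with a well-populated reference
class, giving ≈2000–2500 used and ≈1800 available locations per replicate
— large enough for stable coefficient estimates, small enough that a
50-replicate experiment completes in about a minute. Truth: meadow/bog
selection ≈ +1 on the log scale, heathland avoidance −0.3, quadratic
optima 25 m above the timberline and at 10° slope, area-intercept SD 0.5.
The cross-validation null experiments use a smaller 6.7-km landscape with
β = 0, where the Boyce correlation should (and does) centre on zero.

## Numerical details and edge cases

* Quantile bins: interior edges at the 10 %…90 % empirical quantiles;
  assignment by right-closed search so each bin holds 10 % ± 1 of the
  binning sample; massive ties collapse bins with a warning rather than
  an error.
* RSF scaling requires at least one finite value; constant inputs scale
  to all-ones.
* `fit_halfnormal` requires ≥2 strictly positive distances; all-zero
  input is degenerate and rejected.
* Rasters: ESRI ASCII grid text format (ncols/nrows/xllcorner/yllcorner/
  cellsize/NODATA_value), row 0 at the north edge; transects as GeoJSON
  LineStrings; every tabular artifact as CSV.
* All pipeline randomness flows from one seed through named
  `SeedSequence` substreams (landscape, simulation, availability;
  per-survey keys), so reruns are bit-identical across processes.

## Limitations

* The Laplace approximation is known to bias variance components slightly
  downward for binary data with few observations per group; with hundreds
  of locations per survey area (the regime here) the effect is
  negligible, and the quadrature oracle bounds the likelihood error in
  tests.
* The map applies modelling-sample quantile edges to map-maximum-scaled
  predictions; if the mapped landscape contains better habitat than any
  modelling sample point, top-bin coverage is compressed. This mirrors
  the published procedure and is documented rather than "fixed".
* Spatial blocking requires user-supplied region labels; the package does
  not infer climatic regions.
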