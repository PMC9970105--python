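# Methods

`pyrocast` links three modelling scales to ask a single question: over what
range of remotely sensed burn severity (RdNBR) does a wildfire leave a dry
conifer stand looking like its historical reference condition?

## Species-level mortality models

Tree death within a few years of fire is modelled per species group as a
Bernoulli outcome with a logit link:

    logit P(dead_ij) = b0 + b1 DBH_ij + b2 RdNBR_i + b3 Years_i
                       [+ b4 DBH_ij * RdNBR_i] + u_i,   u_i ~ N(0, sigma^2)

where `i` indexes field plots and `j` trees.  Severity and survey time vary
at the plot level (severity is estimated on a grid cell approximating the
plot footprint), so a Gaussian plot random intercept `u_i` absorbs the
within-plot correlation that would otherwise deflate standard errors.

The marginal likelihood integrates `u_i` out of each plot's Bernoulli
product.  The integral is one-dimensional per plot and is evaluated by
**adaptive Gauss–Hermite quadrature**: the integrand's mode is found per plot
with a damped Newton iteration (it is strictly concave), the curvature at
the mode sets the quadrature scale, and 15 probabilists'-Hermite nodes
(configurable; one node recovers the Laplace approximation) are combined by
log-sum-exp.  The design matrix is column-scaled before optimization
(severity spans O(1000), DBH O(100)), L-BFGS-B optimizes `(beta, log sigma)`
with `log sigma` bounded in [-8, 3], and up to `n_restarts` jittered starts
guard against local optima.  Standard errors come from the observed
information — a central-difference Hessian of the marginal log-likelihood at
the optimum — with a fixed-effect-block fallback when `sigma` sits at its
boundary.  On shared data the fit agrees with `lme4::glmer` (nAGQ = 15) to
five or more significant digits in coefficients, standard errors, the
random-intercept SD and the log-likelihood (one test runs that cross-check
directly through `Rscript`).

Candidate models (main effects vs. an added DBH × severity interaction) are
compared by AICc; the interaction is only considered for species with more
than 2,000 records, and is retained only if it improves AICc by at least 2.
`k` counts the fixed effects plus the random-intercept SD; whether the
reference software counts the variance parameter is not knowable from a
printed AICc difference, so the choice is documented here rather than
asserted.  Goodness of fit is summarized by the theoretical-variance
marginal/conditional R² on the link scale: with `s2_f` the variance of the
fixed-effect predictor over the data, `s2_a = sigma^2` and the logistic
distribution-specific variance `pi^2/3`,

    R2_marginal    = s2_f / (s2_f + s2_a + pi^2/3)
    R2_conditional = (s2_f + s2_a) / (s2_f + s2_a + pi^2/3).

`s2_f` uses the population variance (ddof = 0); at the sample sizes involved
the distinction from the sample variance is immaterial.

Standardized effect tables refit each model with DBH, severity and years
z-scored within species, making coefficient magnitudes comparable across
predictors and species.  Z-scoring is an affine reparameterization, so the
maximized log-likelihood is unchanged (tested to 1e-6).

## Monte Carlo uncertainty propagation

Estimation uncertainty is pushed downstream by replacing every fixed-effect
point estimate with an independent draw from Normal(estimate, SE) before
each probability evaluation; probabilities are the inverse logit of the
resulting linear predictor.  Draws deliberately ignore the estimator
covariance (independent marginals); a covariance-aware option exists but is
off by default, since independent resampling is the propagation rule the
pipeline is built around.  The plot random intercept is fixed at zero for
prediction — the population-level curve — with an option to add plot-effect
draws from Normal(0, sigma) for sensitivity analysis.

Species curves evaluate 10/20/60 cm size classes across −50..1350 RdNBR in
10-unit steps, 75 draws per grid point, three years post-fire; classes above
the species' maximum observed DBH are omitted rather than extrapolated.  Per
severity, the sample mean and SD of the drawn probabilities are smoothed
with a tricube-weighted local **linear** smoother at span 0.25 (statsmodels
`lowess`; the SD band is the smoothed per-severity sample SD).

## Stand-level fire simulation

Contemporary stand tree lists are standardized to 1-ha conifer lists:
species codes pool to modelling groups (ponderosa + Jeffrey pine → yellow
pine; grand + white fir → white fir), hardwoods and trees below 15 cm DBH
are removed (15.0 cm exactly is retained), and per-tree expansion factors
convert records to per-hectare weights.  A record's whole weight lives or
dies with a single Bernoulli draw — fractional weights are never split — so
live and dead pools partition the pre-fire stand by construction.  Dead
totals are stored as the complement of live totals within the pre-fire
total, which keeps the conservation identity exact in floating point; live
totals are additionally clamped into [0, pre-fire] because vectorized
reduction order can differ from the scalar total by an ulp when every tree
survives.

Each tree gets its own coefficient draw (independent per tree, per the
propagation design above); an optional mode shares one draw per species and
iteration to represent systematic rather than independent parameter error.
Mortality is decided by comparing the drawn probability with a uniform(0,1)
deviate at years-post-fire fixed to 3 (delayed mortality), and the sweep
covers −50..1000 RdNBR in 5-unit steps with 5 iterations per stand (both
configurable; convergence-sensitive tests use far more iterations).
Outcomes record live/dead basal area (`pi (DBH/200)^2` per tree) and
density, and the live-basal-area shares of yellow pine, Douglas-fir, white
fir, western larch and other.  Composition profiles average shares over
outcomes with positive live basal area, smooth each share across severity
with the module-wide smoother, and renormalize; severities where every
outcome was zero are reported as gaps, never interpolated.

## Restoration assessment

The historical range of variation (HRV) is the reference mean ± 1 SD,
floored at zero; endpoint membership is inclusive throughout.  The
restoration probability at a grid severity is the fraction of stand ×
iteration outcomes inside the HRV, and the restorative window at a
threshold (0.90/0.75/0.50) is the **longest contiguous run** of qualifying
grid severities, ties broken toward lower severity, empty when nothing
qualifies.  On the unimodal probability curves the sweep produces,
qualifying sets are single intervals and windows nest across thresholds;
the longest-run rule alone does not guarantee nesting on arbitrary
non-monotone curves, which is why the nesting property is tested on
sweep-like curves.  Windows are combined two ways: an unweighted mean of
endpoints across forest × type groups (empty members excluded with a
warning), and a generalization as the interquartile range of all grid
severities pooled, with multiplicity, from every group's ≥75% window
(linear-interpolation percentiles).  Window width divided by the observed
severity span of the model-building plots, × 100 and rounded to the nearest
integer, expresses a window as a percent of the observed range; the
published 75% basal-area, 90% density and 75% density windows reproduce as
22%, 6% and 12% under this rule, while the published 10% for the 90%
basal-area window is inconsistent with nearest-integer rounding
(152/1446 → 10.5 → 11) and is documented rather than reconciled.

Validation matches each independent plot to the simulated outcomes of its
forest × type at the nearest grid severity.  Mean Bias Error is
mean(observed − modelled mean), so negative values mean overestimation.
Prediction intervals are empirical 2.5–97.5 percentile bands of the matched
simulated outcomes — the model's own predictive distribution, not a
parametric formula — with lower bounds below 1 m²/ha (basal area) or 5
trees/ha (density) rounded down to zero, because a 1-ha simulation favours
near-zero but nonzero remnants at high severity.  Classification accuracy is
the agreement rate between "observed metric inside the HRV" and "plot
severity inside the ≥75% window".

## Landscape classification

Severity rasters are reclassified per unmasked forest pixel by vegetation
type: inside the ≥75% window → `restorative_ge75`; otherwise inside the
≥50% window → `cold_50_to_75` or `hot_50_to_75` depending on the side of
the 75% window; otherwise `too_cold_lt50` or `too_hot_lt50`; non-forest
("other") vegetation is masked.  Basal area is the default classification
metric, density available by flag; no filtering beyond vegetation type is
applied.  Class summaries report proportions on two bases (forest pixels
and all pixels), with the ≥50% share cumulating the ≥75% class.  Residual
structure tables average per-tree simulation outcomes into species × DBH-bin
live basal area at selected severities; their totals agree with sweep means
within Monte Carlo error (tested).  Rasters are read and written as
headered ASCII grids with integer class codes and a legend carried on the
class-map object.

## Synthetic data: what it emulates, and what it does not

All inputs are generated with known ground truth so that every stage is
testable offline:

* **Burned plots** — 300 plots × 70 trees by default, severity uniform on
  −52..1340 RdNBR per plot, survey time 0–13 years, DBH truncated-lognormal
  with a 7 cm floor, one standard-normal plot effect per plot scaled by each
  species' random-intercept SD (default 0.5), and Bernoulli death under the
  generating coefficients.  Per-tree generating probabilities are stored so
  empirical rates can be checked against them exactly.
* **Generating coefficients** are configuration, not estimates: every
  species dies more at higher severity; fire-tolerant species (yellow pine,
  western larch, Douglas-fir) gain strong protection from size
  (strongly negative DBH effects), lodgepole pine almost none; hardwoods are
  most vulnerable to delayed mortality.  Magnitudes were chosen once so that
  moderate severities (roughly 400–650 RdNBR) thin overstocked stands toward
  historical structure while sparing large trees.
* **Contemporary stands** — 1-ha conifer lists targeting historical density
  × 4.7 and basal area × 2.3 (ponderosa pine type: 4.6 / 2.3), with ~12%
  between-stand lognormal variation.  Equal per-record expansion factors
  make the density target exact; diameters are rescaled to hit the
  basal-area target and re-floored at 15 cm (the re-flooring bias is well
  inside the tested tolerances).
* **Historical references** — fixed mean ± SD structure and composition per
  forest × type (dry mixed conifer 16 ± 5 m²/ha, 80 ± 25 trees/ha;
  ponderosa pine 12 ± 4, 65 ± 20; scaled ±10% across forests), yellow-pine
  dominated as reconstructions of frequent-fire landscapes are.
* **Landscape** — Gaussian noise smoothed at a controllable correlation
  scale, rescaled to mean 450 / SD 280 RdNBR; vegetation patches from the
  argmax of three smoothed noise fields biased toward 45/35/20%
  mixed-conifer/pine/other.
* **Validation plots** — one simulated post-fire outcome per record, either
  a draw from the fitted predictive distribution itself (used for the
  coverage-calibration check, where 95% nominal coverage must be recovered)
  or a draw under the generating truth with a fresh plot effect.

The generator reproduces the statistical structure the method relies on —
hierarchical noise, severity gradients, overstocking, species sorting by
fire tolerance — but not real species frequency tables, climate or
topographic covariates, spatial tree arrangement within stands, regeneration
or reburn dynamics.  Passing tests therefore demonstrate that the machinery
is correct and calibrated under its own assumptions, not that any particular
fitted coefficient describes a real forest.

## Numerical choices and problem sizes

Quadrature uses 15 adaptive nodes; inner Newton runs to a 1e-11 step
tolerance; the optimizer's convergence tolerance is configurable with a
1e-6 target on the projected gradient.  Probabilities are clamped into
(0, 1) at 1e-15 from each end.  Percentiles interpolate linearly.  The test
suite and the acceptance script size their simulations to what the checks
need: parameter recovery runs 20 replicates of the default 300 × 70 design;
the logistic-oracle comparison uses 50,000 trees; coverage calibration uses
500 validation plots against 30-iteration prediction bands; the conservation
check sweeps 35 stands × 211 severities × 5 iterations; the analysis
scripts run 72 stands across four forests.

## Known limitations

* No random slopes, spatial covariance beyond the plot intercept, or
  survival-time modelling of delayed mortality beyond the linear years term.
* Coefficient draws are independent across parameters by design; where
  estimator correlations are strong this overstates predictive spread.
* The longest-run window rule yields a single interval even when the
  underlying probability curve is multimodal; gaps inside a window are not
  detected (they do not occur in the swept scenarios).
* Historical references enter as summary statistics only; no uncertainty in
  the reconstructions themselves is propagated.
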