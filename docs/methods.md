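# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `cpuestd`.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The standardization model

Both CPUE responses (biomass, kg/km²; density, N/km²) are strictly
positive and right-skewed, so they are modelled with a Gamma family.  The
link is logarithmic: every factor coefficient β then has the direct
reading "100·(exp(β)−1) % change of mean CPUE relative to the reference
level", which is how the package reports effects (`effect_percent`).

The linear predictor is additive in penalized cubic regression splines of
latitude, depth, bottom temperature, oxygen saturation, salinity and week
of the year, a per-management-level spline of year (a factor-by-smooth
interaction), and parametric factors for management level (reference:
open fishery `Y`) and time of day (reference: sunrise).  Basis dimension
is capped at k = 6 per smooth — appropriate for ~90 observations — giving
each smooth at most 5 effective degrees of freedom after the sum-to-zero
constraint.

### Spline basis and penalty

The basis is the classical natural-cubic-spline parametrization by values
at k knots placed at evenly spaced quantiles of the covariate; the
penalty is the exact integrated squared second derivative (rank k−2;
straight lines are free).  Evaluation outside the knot range extrapolates
linearly.  Identifiability: the constant function lies in both the basis
span and the penalty null space, so each smooth is reparametrized onto
the orthogonal complement of its sum-to-zero constraint (computed over
the training rows; for a by-factor smooth, over the rows of its own
level, so the factor's intercepts remain estimable).  Each penalty block
is rescaled to the Frobenius norm of its data cross-product so that a
unit smoothing parameter is comparable across terms.

### Fitting

For the Gamma family with log link the Fisher weights are identically 1,
so penalized IRLS reduces to repeated penalized least squares on the
working response, stabilized by step-halving on the penalized deviance
(convergence: relative change < 1e-8, cap 200 iterations; a capped fit
whose criterion is still moving by more than 1e-5 relative is reported as
a convergence failure).  A data-scaled ridge of 1e-10 guards against
exactly singular degenerate folds.

Smoothing parameters minimize the restricted marginal likelihood (REML)
of the converged working Gaussian model, with the scale profiled out —
for this family the working model is exact up to the local
linearization, and the criterion needs only the penalized residual sum
of squares, the log-determinant of the penalized normal equations and
the block-wise penalty pseudo-determinant.  Optimization is L-BFGS-B
over log smoothing parameters with numerical gradients, **started from
heavy smoothing** (log λ = 8 on the rescaled penalties) and descending:
the restricted likelihood is nearly flat in λ for effect-free terms, and
a mid-range start occasionally strands such terms at spuriously wiggly
local optima.  Generalized cross validation is available
(`method="GCV"`) but is not the default precisely because of its known
occasional-undersmoothing failure mode, which we observed to inflate
null-term significance.  On a shared data set the fits agree closely
with an independent reference GAM implementation (matching edf patterns
and AIC within a few units).

### Dispersion, AIC, inference

The dispersion φ is the Pearson estimate on n − edf degrees of freedom;
the Gamma shape for the likelihood is estimated by maximum likelihood
given the fitted means (a 1-D monotone root-find on the digamma
equation).  AIC = −2·loglik + 2·(total edf + 1), the +1 accounting for
the estimated shape.  Coefficient covariance is the Bayesian posterior
φ(XᵀX + S)⁻¹.  Parametric terms use t-tests on n − edf degrees of
freedom.  Smooth terms use a Wald-type statistic on the smooth evaluated
at the training covariates, with a pseudo-inverse of its covariance
truncated at rank ≈ edf (rounded, minimum 1), referred to an F
distribution — the variant *without* smoothing-parameter-uncertainty
correction, which the test suite checks empirically for calibration
(type-I rate within 0.02–0.08 at nominal 0.05 over 500 null datasets).

## Selection cascade

1. **VIF screen.** Backward elimination on the continuous covariates:
   drop the highest VIF (= 1/(1−R²) against the others) until all are
   below 3; alphabetical tie-break, including perfectly collinear pairs.
2. **Candidates.** Four fixed candidates: the full model; without
   environmental terms; without management terms; without both.
3. **Repeated k-fold CV.** Default 10 folds × 10 repeats.  Each training
   fit records its AIC (in-sample parsimony per refit — the AIC of the
   *trained* model, deliberately, not a held-out likelihood), per-term
   p-values, and held-out RMSE.  Partitions are simple random, redrawn
   (bounded retries) if a training fold loses a factor level; a
   stratified-by-survey option exists behind a flag, default off.
4. **AIC comparison.** Levene's test gates a one-way ANOVA with Tukey
   HSD; if variances are heterogeneous the cascade falls back to Welch's
   ANOVA with Games–Howell pairs rather than proceeding invalidly.  The
   lowest-mean-AIC candidate wins only if it differs significantly from
   every other; otherwise the candidate with fewest distinct covariates
   is chosen (deterministic order for ties).
5. **Retention.** A term is kept iff significant (p < α = 0.05) in at
   least 80 % of the CV fits.  A factor-by-smooth interaction is kept if
   *any* of its level smooths passes, and the parent factor's intercepts
   are kept whenever the interaction is.  Retention is applied per
   response; a joint "drop only if dropped for both responses" variant is
   available by flag.
6. **RMSE head-to-head.** Refined vs full model on identical partitions;
   lower mean held-out RMSE wins.

## Prediction grid and standardized indices

Cells are squares of constant area (default 2×2 nautical miles) in a
local Lambert azimuthal equal-area projection centred on the domain
centroid — "2×2 nm" is an area statement and latitude/longitude squares
are not equal-area.  Cells intersecting the study polygon are kept, with
both nominal and clipped areas recorded.  Mean depth is computed by
quadrature over the analytic surface (6×6 interior points restricted to
the polygon); the management level is resolved at the cell centre on a
per-survey reference date (May 1 for spring, October 1 for autumn —
mid-window choices); environmental values come from ordinary kriging of
the survey's CTD stations (exponential variogram, zero nugget, sill and
range by Cressie-weighted least squares on the binned empirical
semivariogram), computed at the cell centre in the projected frame.
Duplicate station locations are deterministically jittered apart.

Survey/years without their own environmental data are proxy-filled from
the nearest *following* year of the same season, parameter-wise, with
provenance recorded per layer; observed layers are never overwritten and
proxy layers never donate onward.

The standardized index for a survey/year/response is the arithmetic mean
of per-cell response-scale predictions at sunrise over the in-domain
cells (autumn: western cells only).  Its standard error is
√(Σ SEᵢ²)/n over the per-cell delta-method standard errors — an
independence approximation that ignores between-cell prediction
covariance and therefore understates the index uncertainty somewhat;
per-cell SEs are response-scale by default (link-scale values are
available from the same fit).  Observed-vs-predicted differences are
reported as 100·(predicted − observed)/predicted by default, with the
observed-denominator convention behind a flag.

## Synthetic-data generator

The generator's purpose is to make the pipeline's *recovery behaviour*
testable: it simulates from exactly the additive structure the model
assumes, with two planted null covariates (bottom temperature and week),
so the selection cascade has a known right answer.

* **Geometry.** A rectangular domain (≈ 1.4° × 0.9°) with an analytic
  depth surface: a 130 m shelf plus three Gaussian depressions, the
  deepest reaching ≈ 268 m (validated ≤ 270 m).  Management zones are a
  disc (ban zone A) and two annuli (buffers B, C) around the deepest pit,
  clipped to the domain; a meridian splits west from east.
* **Timeline.** Open fishery everywhere until 2015-07-01, then A→N,
  B→L, C→L (a simplification of the real sequence of decrees into one
  persistent regime; levels before any episode default to open).
* **Environment.** Each parameter is a deterministic trend (seasonal and
  annual offsets, spatial gradients, a depth association for oxygen)
  plus a correlated field with exponential variogram, realized by 600
  random Fourier features (frequencies from the kernel's spectral
  density, a bivariate t with 1 df), giving a consistent callable
  surface without large factorizations.  Oxygen is clipped to a
  configured band (default 40–120 %) so documented low-oxygen scenarios
  are representable.  Within-season variances are deliberately
  comparable to the seasonal offsets: if bottom temperature varies only
  *between* seasons it becomes collinear with week's two seasonal
  clusters and the pair soaks up noise jointly.
* **Hauls.** Placement is zone-stratified (25 % ban, 20 %+15 % buffers,
  40 % anywhere; uniform within zone, restricted to the 100–270 m
  trawlable band) because the surveys allocate effort across management
  regimes; fully uniform placement is available but leaves the ban zone
  with too few hauls to identify its factor level.  Week numbers are
  uniform in the season windows (spring: weeks 14–22; autumn: 36–48 —
  the published design gives the months, not the weeks, so the windows
  are configuration).  Both CPUEs are drawn from Gamma distributions
  with mean exp(η) from the generating effects (the "error term" is
  Gamma sampling variability on the response, matching the stated
  family) and shape 4.0; catch weight and count are back-computed from a
  drawn swept area (uniform 0.05–0.08 km²).  The count is stored as a
  float — survey counts raised by subsampling factors are not integers —
  which keeps count/swept-area an exact inverse of the draw.
* **Effort.** The default plan mirrors the real modelled sample: 56
  spring hauls (2013–2019, 2018 generated then withheld as the cancelled
  survey) plus 36 autumn hauls (2015–2019); spring 2012 is generated but
  loses its oxygen values, so filtering removes the whole year.
* **Effect sizes.** The generating magnitudes (latitude slope −2.0/°,
  depth bump +1.9 peaked at 185 m over a −0.8 baseline, oxygen
  −0.03·(O−85) + 3.0·softplus((O−85)/8), salinity −4.5/PSU, sunset
  −0.55/−0.50, buffer/ban offsets +0.65/+0.66 (biomass) and +0.46/+0.72
  (density), year-by-level slopes −0.25/0/+0.40) are configured once so
  that, at the design's sample size, the planted effects are detected at
  rates comparable to the very strong term-significance profile the
  method's published applications report, while the two null terms stay
  near nominal.  They are conditions of the study, not tuning knobs.

**What passing tests do and do not show.**  The generator draws from the
model family being fitted, with independent Gamma noise and no spatial
autocorrelation of catches, no catchability drift, no size structure,
and environmental fields smoother than reality.  Passing recovery tests
therefore demonstrates the *correctness of the machinery* (filters,
basis, penalized fitting, CV bookkeeping, retention logic, kriging,
aggregation) — not that the model is adequate for any real survey.  The
synthetic CPUE scale is also larger than the published survey's (the
planted covariate effects compound multiplicatively on the log scale).

## Problem sizes in tests and the acceptance script

The test suite runs the full cascade at the design scale (n = 92, 10×10
CV) for the final-model term-set recovery invariant (20 replicate datasets),
and uses reduced 5×2 CV for the model-selection rate check (20
replicates), 200 datasets for coverage calibration, 500 small datasets
for the type-I rate, and 50 seeds for the variogram and end-to-end
conservation checks — sizes chosen to keep the whole suite in the
ten-minute range on one CPU while leaving the Monte-Carlo bands
meaningful.  `scripts/acceptance.py` runs one full pipeline at 10×10 CV
plus the printed-input worked examples.

## Known limitations

* Smooth-term p-values ignore smoothing-parameter uncertainty; their
  empirical calibration is verified only under the simulated designs.
* The index SE ignores between-cell covariance (documented above).
* The kriging variogram is always exponential with zero nugget; no
  alternative interpolators are provided.
* The management timeline is one persistent post-2015 regime, not the
  historical sequence of decrees; zone geometry is synthetic.
* No tensor-product smooths and no spatially autocorrelated error
  structure; extending the standardization in that direction is future
  work, not a configuration option.
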