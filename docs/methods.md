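# Methods

This note documents the statistical procedures, the choices made where the
design was genuinely open, and what the synthetic-data generators do and do
not emulate.

## Soil-moisture reconstruction

Sensor readings (two depths, several sensors per plot) are pooled to a
single plot-day mean; depth is retained in the raw table but never analysed
separately because no downstream quantity distinguishes depths.  The sensor
count behind each mean is carried as a regression weight.

A *rain day* is any day with measurable precipitation, or the day after
one, whose mean temperature exceeds 3 °C — the temperature gate excludes
snowfall, which wets the soil on a different timescale.  *Seasons* are
meteorological quarters (DJF/MAM/JJA/SON); only the existence of four named
seasons is essential, not the exact boundaries.

Treatment deviations are standardized per plot group by the standard
deviation of that group's ambient series taken over all of its observed
days (a per-window s.d. would make deviations incomparable across seasons).
The deviation model regresses the standardized deviations on treatment,
season, rain-day and all two-way interactions.  Fixed effects are estimated
by weighted least squares with date-cluster-robust standard errors; the
group and date random-intercept variances reported alongside are
method-of-moments estimates from residual cluster means.  Only the
fixed-effect predictions are consumed downstream (treatment-level daily
means), so the reconstruction does not depend on the random-effect
machinery.  Predictions therefore set the group and date effects to zero.

Because a *standardized* deviation is unit-free while the ambient daily
mean is in VWC units, the predicted deviation is rescaled before being
added: the back-transform scale is the cross-group mean of the ambient
standard deviations used in the standardization.  Negative back-transformed
VWC is clipped to zero with a logged warning.  Days lacking any ambient
measurement cannot be reconstructed; they are reported as gaps and filled
from a surrogate process-model daily series, with source flags
(`observed` / `statistical` / `surrogate`) preserved per day.

The response covariate is the cumulative sum of daily VWC over
March 1 – June 30 (122 days outside leap years).  The sum is linear in the
daily values, so proportional treatment effects on daily VWC propagate
exactly to the covariate.

Water-year precipitation extremes are characterized by a two-parameter
gamma distribution fitted by maximum likelihood (location fixed at zero);
the 1% and 99% quantiles are reported with their percent deviation from the
fitted distribution mean.

## ANPP calibration

The greenness index is (NIR − Red)/(NIR + Red).  Band-pair assignment
defaults to MODIS = (652, 859 nm) and AVHRR = (626, 875 nm); both red
wavelengths fall inside both instruments' red windows, so the assignment is
configurable.  Per year, dry calibration biomass is regressed on the index
for each pairing by OLS and the higher-R² fit is retained; exact ties break
to MODIS for determinism.  ANPP predictions below 1 g m⁻² are floored there
with a warning because the response model takes log(ANPP).

## Hierarchical functional-response model

Response and covariate are standardized to mean 0, unit variance using the
population (n) convention, pooling all treatments; log(ANPP) is transformed
before standardization.  The design row is
(1, I_drought, I_irr, v, I_drought·v, I_irr·v), so control is the reference
level and the remaining coefficients are intercept/slope offsets.

Priors: β ~ Normal(0, 5) per coefficient; σ and σ_year ~ half-Cauchy(2.5);
Σ is decomposed into scale × correlation with half-Cauchy(2.5) scales and a
uniform prior on the correlation (equivalent to LKJ(1) in two dimensions).
The 2.5 scale is a weakly-informative default appropriate for standardized
data.

Sampling is by a blocked Gibbs sampler.  All linear coefficients
(β, the per-plot γ pairs, the year effects η) are drawn *jointly* each
iteration from their exact multivariate-normal conditional — the design
cross-product is precomputed, so each draw is one Cholesky factorization of
a (6 + 2J + T)-dimensional precision matrix.  The joint block matters:
updating β, γ and η one at a time mixes extremely slowly because the
intercept and slope are confounded with the means of the plot and year
effects.  With the joint update the effective sample size of the β draws is
essentially the number of saved draws.  The scale parameters (σ, σ_year,
the two Σ scales) are updated by univariate slice sampling on the log scale
and the correlation on the arctanh scale, all with their exact conditional
densities.  A prior-only mode (likelihood switched off) exists for prior
recovery checks.

Defaults mirror a 4-chain × 10,000-iteration, discard-half, thin-10
protocol; reduced runs (2 × 2,000, thin 1) are used in the validation
experiments, where the joint block update keeps the effective sample size
near nominal.  Convergence is gated on rank-normalized split R-hat < 1.1
(computed with arviz); the pipeline refuses to write summaries past the gate
unless forced, in which case the violation is downgraded to a warning.

Summaries report, for each of intercept and slope, the control coefficient
and the treatment-level coefficient formed by summing control + offset *per
draw* and then summarizing (means, medians, equal-tailed 95% intervals).
Hypothesis probabilities are one-tailed posterior masses on the slope
offsets (drought > 0, irrigation < 0); intercept offsets use the direction
of their posterior median.

## Sensitivity

Sensitivity of a treated plot-year is
(mean control ANPP − plot ANPP)/(ambient VWC − treated VWC) in g m⁻² per
VWC unit.  Ambient VWC per year is the control treatment's shared
cumulative spring VWC (treatment-level, matching the shared-covariate
structure).  The trend test is an OLS of sensitivity on year of treatment
within each treatment, pooling plots, with a two-sided t-test on the slope.
Exact fits (zero residual variance) return p = 1 for a zero slope and p = 0
otherwise rather than an undefined t-ratio.

## Community composition

Species columns are z-scored (population s.d.), which weights rare and
common species equally; zero-variance columns are dropped with a warning.
A +2 shift makes values positive for Bray–Curtis; a z-score below −2 would
still be non-positive, so such values are floored at 0.01 with a warning
(the shift alone cannot guarantee positivity).

Bray–Curtis, PERMANOVA and PERMDISP are implemented from first principles.
PERMANOVA partitions the total sum of squared distances (Σd²/n within
groups and overall) into among/within components and permutes raw group
labels freely; the p-value uses the (1 + exceedances)/(1 + permutations)
estimator so it is never exactly zero.  Tests are run within each year
separately, which sidesteps the repeated-measures structure the same way
the per-year analysis design does.  PERMDISP embeds the distance matrix by
principal coordinates, keeping axes for negative eigenvalues as "imaginary"
components whose squared contributions are subtracted (floored at zero) —
the standard correction for semi-metric distances.  Group centroids are
spatial means in that space; a one-way ANOVA F on the centroid distances is
evaluated against permutations of the distances (and a parametric F p-value
is reported alongside).  Default 999 permutations.

NMDS minimizes Kruskal stress-1 in two dimensions by alternating isotonic
regression of configuration distances on the rank order of the input
dissimilarities with Guttman-transform updates, run from several random
starts plus a metric PCoA start; the lowest-stress solution is returned
with its stress trajectory, centered scores, and a convergence flag.  No
abundance auto-transformation is applied (the matrix is already
standardized).

## Synthetic data

The generators reproduce the statistical structure the estimators assume,
with defaults matching the study design: 14 control / 8 drought /
8 irrigation plots over 5 years; four sensor-equipped plot pairs with four
sensors per plot and ~30% sensor dropout; 12–16 calibration plots;
treatment VWC offsets of −12% (drought) and +19% (irrigation).

Weather is an annual temperature sinusoid (January ≈ −5 °C, July ≈ 22 °C)
with Bernoulli rain days and gamma rain amounts.  Ambient soil moisture is
a spring-peaking sinusoid plus exponentially decaying rain pulses and AR(1)
noise; treated series displace the ambient series by a configurable number
of ambient standard deviations with season and rain interactions.  The
noise-free latent series is always returned so recovery tests compare
against truth.  ANPP records are drawn from the hierarchical model's own
generative equations and mapped to g m⁻² through exp(5 + 0.5·y), giving
biomass near 150 g m⁻².  Community matrices are lognormal abundances around
species means stable across years; a shift parameter displaces treated
plots' log-means along a fixed species direction for power experiments, and
zero shift gives exchangeable (null) composition.

What the generators do *not* emulate: spatial plot geometry and
autocorrelation, snowpack and infiltration physics (the surrogate series in
the synthetic pipeline is the generator's own latent truth, standing in for
a process-model product), instrument-specific radiometer noise, and
community temporal autocorrelation beyond stable species means.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the assumed data-generating structure, not robustness to field
misspecification.

## Validation experiment sizes

The validation experiments are sized for a single CPU: 20 replicate fits of
30 plots × 20 years with 2 chains × 2,000 iterations for interval coverage;
two years of daily sensor data for deviation recovery; 50 random 8×6
matrices for distance exactness; 500 null community simulations with 199
permutations for the type-I rate; 12-point configurations for ordination
checks.  Coverage measured over larger replicate counts (60) is 95–98% per
coefficient; at 20 replicates the per-coefficient coverage count retains
visible binomial noise, which is inherent to that replicate count.

## Known limitations

- The deviation model's fixed effects come from weighted OLS with clustered
  errors rather than a full crossed-random-effects likelihood; variance
  components are moment estimates and should be treated as descriptive.
- The R-hat gate uses the reduced-protocol draws; very short runs can flag
  scale parameters (τ) whose posteriors are heavy-tailed under weak data.
- PERMANOVA permutes labels freely; designs with strong repeated-measures
  dependence need restricted permutation schemes outside this scope.
- The +2-shift community standardization follows the original analysis
  convention; the 0.01 floor for extreme negative z-scores is this
  package's guard and slightly compresses extreme outliers.
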