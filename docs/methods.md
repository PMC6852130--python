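# Methods

## The problem

Environmental assessment schemes score a site against a *benchmark*: a target
value of a biodiversity metric for the site's vegetation type and region.
`vegbench` estimates *best-on-offer* benchmarks — upper quantiles of the
contemporary distribution of native species richness and summed percent cover
for six plant growth forms (fern, forb, grass and grass-like, not-otherwise-
classified "other", shrub, tree) — from archives of floristic plot surveys.
Benchmarks vary by vegetation class (nested in vegetation formation),
bioregion, survey month, and rainfall over the preceding 12 months, so a site
surveyed in a dry autumn is not scored against a target attainable only in a
wet spring.

## Model

For survey *i*, let **y**_i be the 6-vector of native richness per growth
form and **z**_i the 6-vector of summed native cover.  Separate models are
fitted per response:

    y_i          ~ Poisson(lambda_i)                     (richness)
    log(z_i + 0.001) ~ Normal(log lambda_i, sigma)       (cover)
    log lambda_i ~ MVN(mu_i, Sigma)

The 0.001 offset makes zero covers finite on the log scale (a Box-Cox
transform with lambda1 = 0, lambda2 = 0.001); benchmark predictions are
back-transformed as exp(log lambda) − 0.001, floored at 0.  The multivariate
normal overdispersion Sigma = diag(sigma_s) Phi diag(sigma_s) induces
extra-Poisson variance and residual correlation among growth forms.

Two linear predictors are supported.  The *dynamic* variant lets monthly
trends differ by bioregion:

    mu_i = alpha + beta_v(i) + gamma_[m(i),b(i)] + r_i delta_b(i)
           + e_i eps + zeta_y(i) + eta_p(i)

The *static* variant uses regionally consistent month effects:

    mu_i = alpha + beta_v(i) + gamma_b(i) + r_i delta_b(i) + e_i eps
           + zeta_y(i) + eta_p(i) + kappa_m(i)

All bold parameters are 6-vectors over growth forms; r_i is standardized
12-month accumulated rainfall and e_i standardized nonnative cover
(standardized with population-sd scaling, stored and reapplied at prediction
time, because effects are reported per one standard deviation).

Priors: beta_v ~ N(theta_f(v), sigma_v) with theta_f ~ N(0, sigma_f) nesting
classes in formations; delta_b ~ N(iota, sigma_r) with iota ~ N(0, 10);
eps ~ N(0, 10); zeta_y ~ N(0, sigma_y); eta_p ~ N(0, sigma_p); static
gamma_b ~ N(0, sigma_b) and kappa_m ~ N(0, sigma_m).  In the dynamic variant
the months of each bioregion follow a first-order random walk starting in
July (gamma_Jul,b ~ N(0, sigma_rw,b)), stepping August through May, with June
tied to the mean of May and July so the seasonal cycle closes smoothly.
Every scale parameter is a 6-vector with elementwise HalfNormal(0, 2) priors.
The residual correlation Phi has an LKJ prior implemented as
log p(Phi) = a log det(Phi) + const with a = 4 by default; under this
convention a = 0 weights all correlation matrices equally and larger a
concentrates mass near the identity.  (The source literature for this prior
is commonly parameterized with exponent eta − 1; the package exposes the
exponent directly.)  All Normal(0, 10) priors take 10 as the standard
deviation.  Two priors the model needs are not pinned down elsewhere and are
package choices: alpha gets the same vague N(0, 10) as iota and eps, and the
cover observation sd sigma gets HalfNormal(0, 2) like every other scale.

## Inference

Sampling is by the package's own gradient-based MCMC: a multinomial No-U-Turn
sampler with dual-averaging step-size adaptation (target acceptance 0.8) and
windowed diagonal mass-matrix estimation, running on an unconstrained
parameterization with hand-derived analytic gradients:

* all hierarchical deviations are non-centered (z ~ N(0,1), deviation =
  scale * z), including the seasonal random walk (innovations are sampled);
* scales are log-transformed; Phi is parameterized through the tanh/Cholesky
  correlation transform with its exact Jacobian;
* the survey-level overdispersion is non-centered through the Cholesky factor
  of Sigma: log lambda_i = mu_i + diag(sigma_s) L_Phi u_i.

Correctness is established two ways in the test suite: finite-difference
checks of the gradient at random states for all four response/variant
combinations, and exact parity between the sampler's log density and an
independent term-by-term scipy evaluation on the constrained scale (up to the
analytically computed transform Jacobian).  States whose latent log rates
exceed |60| are rejected as divergent before exponentiation can overflow.

Convergence is assessed with split-Rhat and bulk effective sample size
(computed by arviz), with the gates Rhat < 1.01 and a configurable ESS floor
(1,000 by default).  Chains are seeded from a single integer via
`numpy.random.SeedSequence`, so runs are exactly reproducible.

The default sampler preset is 4 chains of 1,000 warmup + 1,000 retained
iterations; a long preset (5,000 + 5,000) matching the original analysis is a
configuration choice.  The correlation matrix Phi and overdispersion scales
sigma_s are the slowest-mixing block of this posterior — they are weakly
identified for low-richness growth forms and are coupled to one latent
6-vector per survey — and they, not the regression effects, set the chain
length needed to meet the Rhat gate.

## Rainfall covariates and levels

The rainfall covariate is total rainfall over the half-open window
[survey_date − 12 months, survey_date): calendar-anchored, excluding the
survey day, so a window containing February 29 has 366 days.  Rainfall
*levels* for benchmark reporting are the 10th, 50th and 90th empirical
quantiles (linear, type-7 interpolation) of historical 12-month accumulations
anchored at the first day of the survey month across a year range
(e.g. 1900-2015).  For bioregion x class combinations with no surveyed
location, levels are imputed by three separate least-squares regressions (one
per quantile) with bioregion and vegetation class as additive categorical
predictors; imputed triples that come out inverted are re-sorted and logged.
Grid-to-location interpolation of gridded rainfall products is out of scope:
the module consumes per-location daily series.

## Benchmarks

A benchmark cell is a bioregion x class combination (static) or
bioregion x class x month (dynamic).  For each posterior draw the cell's
linear predictor is evaluated at the cell's rainfall level (standardized
through the stored scaling) and at raw 0% nonnative cover (also standardized,
not set to standardized zero); the benchmark distribution is the posterior of
the *expected response for a new plot in an average year*:

* year and plot deviations are excluded (set to their zero means),
* the MVN overdispersion is included (a site-level state a real plot can
  attain, drawn fresh per posterior draw),
* Poisson / lognormal observation noise is excluded (survey noise, not site
  quality), and
* in the static variant the month deviation kappa is set to its zero mean.

Each choice is a flag on `GridConfig`, because reasonable analyses could
marginalize differently.  Benchmarks are the marginal 55th, 65th and 75th
empirical quantiles per growth form (multivariate quantiles have no
single-number-per-growth-form summary); richness benchmarks are reported as
real numbers, being quantiles of a latent rate.  Static tables use the
average (50th-quantile) rainfall level; dynamic tables emit all three levels.
Cells with no observed surveys are still emitted, flagged `extrapolated`.
Comparison against expert-elicited benchmarks reports, per (bioregion, class,
growth form): the modeled 55-75 band, the elicited mean and 10th-90th range,
whether the bands intersect, and the signed difference of midpoints.

## Synthetic data

The generator simulates the full generative process so every module is
testable without the (external) plot archive.  Default conditions mimic the
study system at desk scale: mean richness per growth form (1, 6, 5, 1, 6, 2)
and mean covers (0.05, 2.63, 8.25, 0.19, 6.43, 3.01)%, rainfall multipliers
1.05-1.24 per sd for richness and 1.11-2.17 for cover, weakly negative
nonnative effects on richness (0.88-0.99), class variation (sd 0.4) exceeding
formation (0.3) and bioregion (0.2) variation, overdispersion scale 0.3, and
a lognormal observation sd of 0.7 for cover; per-bioregion annual rainfall
regimes span 400-1100 mm.  Species-level records are emitted by splitting
each growth form's cover uniformly over `sp_<growthform>_<k>` pseudo-species
so that re-aggregation reproduces the survey table exactly; cover is set to
zero where a growth form has no species (cover requires presence).  Daily
rainfall series allocate each calendar year's total (drawn from the
bioregion's regime) across days with a Dirichlet split, so annual totals
match the regime exactly.  One RNG stream per component (parameters, surveys,
rainfall) is derived from the master seed.

What the generator does not emulate: realistic species-abundance
distributions (pseudo-species share cover equally), taxonomic synonymy,
spatial autocorrelation within bioregions, observer effects, and the
ordinal-cover measurement process (records carry numeric covers; the
ordinal-class converter is exercised with explicit tables).  Passing tests
therefore demonstrate statistical correctness of the machinery, not
robustness to those features of real archives.

## Verification design and problem sizes

Tests run at sizes chosen for a single CPU.  The convergence-gate check fits
the richness model to a synthetic dataset of 120 surveys (5 classes, 2
formations, 3 bioregions, 3 years, 30 plots) with 4 chains of 800 warmup +
800 retained iterations at target acceptance 0.9; the chain length, warmup
length and acceptance target are set by the slow-mixing (Phi, sigma_s) block
discussed above — which both needs the most effective samples and produces
occasional divergences at the default 0.8 acceptance — not by the regression
effects, which converge within a few hundred iterations.  Parameter
recovery and simulation-based calibration use 20 replicate datasets of 50
surveys each; these replicates draw the grand means and every scale
hyperparameter from the model's own priors with prior scales set to
calibration-friendly values (vague sd 0.5, half-normal scale 0.25) rather
than the analysis defaults (10 and 2), because rank-uniformity of the truth
within the posterior is exact only when the truth is drawn from the priors
actually fitted, and draws from N(0, 10) intercepts produce degenerate count
data.  The acceptance script re-runs the grid arithmetic at the full study
dimensions (18 bioregions x 95 classes), the multiplicative-effect
conversions, a recovery experiment, and the desk-scale convergence gate.

## Known limitations

* The sampler is pure numpy; it is roughly an order of magnitude slower per
  gradient than compiled MCMC engines, which bounds feasible problem sizes.
* Slow mixing of (Phi, sigma_s) means short chains can leave their Rhat above
  1.01 even when every regression-level parameter has converged; the long
  sampler preset exists for production use.
* Unobserved vegetation classes are not given posterior-predictive beta
  draws from their formation mean; extrapolated cells reuse the fitted class
  structure and are flagged, and classes absent from the fitted data entirely
  are not emitted.
* The ordinal-cover conversion is a user-supplied midpoint table, not a
  fitted measurement model.
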