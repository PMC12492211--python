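# Methods

This note records the models implemented in `evorescue`, the parameter
conventions they use, and the design choices made where the underlying
analysis was genuinely open.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Selection inference

Selection on a quantitative trait is summarized by the selection
differential, the covariance of relative fitness with the trait.  We
estimate it as the least-squares coefficient of the trait in a linear model
of relative fitness (fitness divided by mean fitness), optionally with site
indicator variables; with the trait standardized to sample SD 1 (n−1
denominator throughout) the coefficient is the SD-standardized differential
S′, and without covariates it equals the sample covariance exactly.  The
raw-scale differential is reported in trait units (cm²/g): the covariance
with the raw trait, so S = S′·σ with σ the sample trait SD.  Quadratic
selection gradients are twice the squared-term coefficient of a model with
linear + squared standardized trait + site.

Because the fitness component is binary survival, significance uses a
binomial-family logit-link GLM (statsmodels, IRLS) on the same design
matrix, reporting two-sided Wald p-values; effect sizes stay on the
least-squares scale.  Wald rather than likelihood-ratio tests match the
default summary of the standard GLM fitting routines.  Perfect separation
is detected (non-finite standard errors, |coef| > 30, or the fitter's own
warning) and reported as NaN with a warning rather than a spurious p-value.

Two analysis scopes are provided.  The *overall mean-trait* analysis
averages each plant's trait over its measurement years, standardizes
globally and includes site as a fixed factor.  The *yearly* analysis
standardizes and relativizes within each year (each year analyzed alone,
sites pooled with a site factor).  Yearly differentials — raw scale — are
then regressed by OLS on that year's snowmelt day to give the environmental
sensitivity line S(d); the same machinery fits yearly b/v (slope of
absolute survival on raw trait over mean survival) against snowmelt day.
Records with missing trait or fitness are dropped listwise with a logged
count.

## Step-change model

An abrupt, permanent shift to harsh early-snowmelt conditions drops mean
absolute fitness to W̄₀ (default 0.88, the mean of the two study
populations' fitness in the most extreme observed drought year).  The trait
responds to constant directional selection by the breeder's equation, so
the cumulative response after t generations is Δz_t = t·h²·S, and fitness
recovers as W̄_t = W̄₀·max(0, 1 + (b/v)·Δz_t) with b the slope of absolute
fitness on the raw trait and v mean fitness.  The bracket is floored at 0:
the model is silent on negative fitness and a floor is the only meaningful
choice.  Population updates are N_{t+1} = W̄_t·N_t, generation 1 carrying
the initial population (so without evolution N_t = N₁·W̄₀^{t−1}); this
indexing is the one consistent with the model's closed-form extinction
identity, extinction step = 1 + ⌈ln(threshold/N₁)/ln W̄₀⌉.

Defaults: b = −0.0034 per cm²/g, v = 0.554, with b/v taken as the
two-significant-figure −0.0061 (passing `b_over_v=None` uses the exact
ratio −0.006137; near-threshold milestones such as the halved-heritability
extinction generation are sensitive to this rounding, and the rounded
value is the published operating point).  S = −5.866 cm²/g, the strongest
observed yearly selection (S′ = −0.23), giving the trait scale
σ = 5.866/0.23 ≈ 25.5 cm²/g used to map standardized sweep grids to raw
differentials.  h² = 0.10 (field estimate), N₁ = 200, functional
extinction below 2 individuals (self-incompatible species), horizon 75
generations.

Demographic stochasticity replaces the update by N_{t+1} ~ Poisson(N_t·W̄_t)
— the sum of independent Poisson(W̄_t) offspring counts.  Replicates draw
independent generators spawned from a root seed, so results are
order-independent.  At Poisson means above 1e8 the draw is replaced by the
rounded mean; relative sampling error there is below 1e-4.

## Gradual environmental change model

Calendar-year snowmelt at the reference climate station follows
d(t) = 539.2 − 0.20·t days-since-January-1, with optional untruncated
Normal(0, 11.4 d) residuals (the observed scatter around the trend).
Site-level functions of d parameterize the dynamics: a quadratic baseline
fitness W̄₀(d) (from long-term demographic projections), a linear selection
function S(d) and a linear fitness-slope function b(d).

Generations remain discrete with a 5-year generation time, so the model
iterates yearly: Δz accumulates by h²·S(d_t)/5 each year, and once per
5-year generation the population is updated at the parent generation's
year, N ← N·W̄ with W̄ = W̄₀(d)·max(0, 1 + (b(d)/W̄₀(d))·displacement),
or Poisson(N·W̄) under demographic stochasticity.  The start year is 2023
(generation 0); updates at the parent generation's year, with Δz taken
after that year's increment, are the conventions consistent with the
model's own no-evolution product form N_g = N₀·∏ W̄₀(d(yearⱼ)).

**Snowmelt reference of the regression lines.**  W̄₀(d) and S(d) are
functions of the *reference-station* snowmelt day: the demographic fits
were made against station days, and the selection line is pinned to the
station scale by its intersection with the step model's S.  The yearly
fitness-slope estimates b, however, derive from plants experiencing their
own site's snow conditions, and the sites melt out later than the station
(hybrid site +17 d, *I. aggregata* site +6 d).  The model therefore
evaluates b at the site-referenced day d + offset (`b_day_offset`).  This
calibration is the only convention we found that jointly reproduces the
full set of deterministic hybrid trajectories (extinction years with and
without evolution, persistence at h² = 0.30, and the qualitative
plasticity outcomes); evaluating b at the station day weakens nothing
structurally but shifts the evolution-dependent extinction year by two
generations.  Set `b_day_offset=0` to use the station day everywhere.

Plasticity adds 1.323 cm²/g per day of snowmelt difference, accumulated as
slope·(d_t − d_first) — the telescoped sum of year-over-year differences,
with d_first the first simulated year's (possibly stochastic) day.  The
plastic displacement is a property of the current environment and is not
reset at generation turnover.  Under stochastic snowmelt this makes the
trait track each year's deviation, which is what produces the large
run-to-run variation in when population growth turns positive.  Total
displacement (genetic + plastic) enters the fitness bracket; an optional
`min_displacement` floor represents a minimum attainable SLA and is off by
default (most runs do not approach it before fitness recovers).

A replicate is *rescued* if N never falls below the threshold through the
horizon (end year 2400); extinction is absorbing.  Rescue probabilities
report the rescued fraction with a 95% Wilson interval.  With both
stochasticity flags off, runs are bit-identical and seed-independent.

## Fisher bound

Fisher's fundamental theorem bounds the per-generation gain in mean
fitness by V_A(W)/W̄.  Published additive genetic coefficients of variation
for fitness in this system (26% for survival-based fitness, 15% seed-to-
seed) convert to variances as V_A = (CV_A·W̄)²; which W̄ to scale by is
ambiguous, so it is an explicit argument.  The realized adaptation rate of
a trajectory is (W̄ with evolution − W̄ without)/W̄ without at a given
generation; for the step model this equals (b/v)·Δz_t in closed form
(saturating at −1 if the bracket floors), and at generation 1 of the
reference parameterization it is about 0.36% — two orders of magnitude
below the squared-CV bound, the basis for concluding that other heritable
traits must carry most of the adaptive potential.

## Synthetic data generator

The generator emulates the field panels' structure: two sites with
different mean survival, traits Normal(250, 25.5²) cm²/g, and binary
survival from logit p = site intercept + β·z with z the trait in SD units.
Defaults are the study conditions: site intercepts (0.63, −0.17) give mean
survival ≈ 0.555 (field v = 0.554), and β = −0.5694 — solved by
Gauss–Hermite quadrature of E[z·p(z)]/E[p(z)] — gives an expected
standardized differential of −0.23, the strongest observed yearly
selection.  Ground truth for each generated table is the *realized*
differential computed from the plants' survival probabilities (the
covariance oracle on expected relative fitness), eliminating any mapping
error between the logit effect size and the covariance-scale differential.
Multi-year panels vary β linearly with each year's snowmelt day and return
the per-year realized truths for sensitivity-recovery tests.

What the generator does not emulate: repeated measurements of the same
plant across years (plasticity in the data), pedigree structure (h² is an
input constant, not estimated), overdispersion relative to the logistic
model, and spatial structure within sites.  Passing recovery tests
therefore show estimator correctness under the generating model, not
robustness to those features of real data.

## Numerical and testing notes

- Standardization and covariances use the n−1 denominator everywhere,
  pinning the identity raw = standardized × sample SD.
- OLS and GLM fits go through statsmodels; the test oracles (hand
  covariances, `numpy.polyfit`, closed forms, direct product formulas) are
  kept independent of that path.
- Simulation sizes in the suite (400 null tables for the GLM type-I rate,
  500 tables for differential calibration, 200 twelve-year panels for
  sensitivity recovery, 300–400 replicates for rescue probabilities) were
  chosen to keep the full suite under a minute while leaving Monte-Carlo
  margins well inside the asserted bounds.
- With 12-year panels the "within 2 SE in ≥93% of panels" calibration
  check sits essentially at its theoretical value: a 2-SE interval with 10
  residual degrees of freedom has t-coverage ≈ 92.7%.
- Degenerate inputs fail loudly: zero trait variance names the offending
  group; all-zero fitness, single-site covariate requests, collinear
  designs, non-binary survival and non-positive traits raise errors naming
  the row or group.

## Known limitations

Single trait, linear selection and plasticity extrapolated indefinitely;
no moving-optimum (stabilizing) variant, no overlapping generations, no
gene flow or dispersal, no cost of plasticity, no nonlinear climate
scenarios.  The printed site-level coefficient sets are rounded, and
several trajectory milestones sit near thresholds (the *I. aggregata*
baseline quadratic has a near-zero discriminant), so evolution-dependent
extinction years can shift by a generation or two under coefficient
perturbations at the printed precision.
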