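# Methods

## Model

The all-cause hazard of patient *i* with covariates Z = (Z1, Z2) is
decomposed into expected and excess parts,

    h(t | Z = z_i) = h*(t | Z1 = z1_i) + λ(t | Z2 = z2_i),

so that all-cause survival factorizes as S(t|Z) = S\*(t|Z1) · R(t|Z2)
with R the relative survival. h\* comes from a population life table and
carries no model parameters; λ is modelled parametrically on the log
cumulative excess hazard scale:

    ln Λ(t | z) = η(ln t, z)
                = s0(ln t; γ) + x'β + Σ_k z_k · s_k(ln t; δ_k),

with s0 a restricted cubic spline (RCS) in log time, x'β proportional
covariate effects, and the optional interactions s_k time-dependent
effects. Then R = exp(−Λ) and λ = Λ · (∂η/∂ ln t) / t. Right-censored
data give the log likelihood

    ℓ = Σ_i d_i ln(h*(t_i) + λ(t_i)) − Λ(t_i)

after dropping the parameter-free ln S\*(t_i) terms. The formulation
permits λ(t) < 0 at some times; only positivity of the *total* hazard
at observed event times is required, which is standard practice for
this model family.

Delayed entry (left truncation) is not supported: cohorts are incident
cases followed from diagnosis.

## Life-table conventions

A life table is a complete grid of rates (person-year⁻¹) over
single-year ages, single calendar years, sex and optional strata.
Attained age and year advance continuously from the (possibly
fractional) values at diagnosis; lookups truncate to integer bands, so
the expected hazard is a step function along follow-up and the expected
cumulative hazard is integrated *exactly*, segment by segment, with
breakpoints at integer crossings of attained age and attained year.
Ages and years beyond the grid are capped at the edge band with a
logged warning (tables end in an open age band in practice). Readers
accept either hazard rates or annual death probabilities q (converted
as −ln(1−q)); completeness of the declared grid is enforced, and the
first missing cell is named in the error. The interpolation convention
is a documented package choice, not a property of any particular
published table.

## Spline basis

The RCS basis is the textbook truncated-power form: K knots give K−1
columns, cubic between the boundary knots, linear beyond them, with
continuous value, first and second derivatives at interior knots; with
two knots the basis is a single linear column. Analytic first
derivatives supply ∂η/∂ ln t for the hazard. Baseline knots default to
equally spaced centiles of the uncensored log event times (boundary
knots at min/max); time-dependent-effect splines default to fewer
degrees of freedom (3) than the 5-df baseline — both are configuration,
chosen per the usual flexible-parametric-model conventions. Basis
columns are orthogonalized by default (a QR-based affine map frozen at
construction): this improves the conditioning of the optimization and
is invisible to predictions, because the column span (plus intercept)
is unchanged; coefficients are reported on the orthogonalized scale
with the transform stored for prediction and serialization.

## Fitting

Maximum likelihood with the analytic score, quasi-Newton (BFGS), and a
derivative-free Nelder–Mead fallback if the gradient norm remains
large. Start values are deterministic — a crude constant-excess-hazard
fit: the excess event count (events minus expected deaths) over total
person-time gives λ₀, and the coefficients are initialized by least
squares against η = ln(λ₀ t) — so refitting the same data reproduces
the coefficients bit for bit. Inside the likelihood, ln(h\*+λ) is
extended linearly below 10⁻⁸: the extension is continuous and
differentiable, strongly penalizes inadmissible regions, and slopes
back toward them; the optimum is verified to have strictly positive
total hazard at every event time, else a convergence error (with
diagnostics) is raised. The linear predictor is clipped at ±200 before
exponentiation purely as overflow protection. The coefficient
covariance is the inverse observed information, with the Hessian taken
by central differences of the analytic score (step 1e−5·(1+|θ_k|));
rank-deficient designs are rejected up front with the collinear columns
named.

## Standardization estimators

Every marginal measure is an average of conditional model predictions
over the empirical covariate distribution of the standardization set
(no model for the covariates), optionally reweighted to an external
group distribution (weights = reference/study proportion ratios, which
average to one) and optionally with the exposure column forced to a
counterfactual level before prediction. Contrasts standardize both
counterfactual curves over the *same* covariate set. For measures
involving S\*, two scenario flavours exist: `vary_both` also switches
the exposure in the life-table lookup (meaningful only when the
exposure is declared as a life-table stratum — with an
exposure-invariant table the two flavours coincide identically), while
`vary_r_only` holds S\* at the set's own characteristics and switches
only R ("eliminate cancer-related differences"). Requesting
`vary_r_only` for a net measure is an error, since net measures already
exclude other-cause mortality. Positivity is checked only as a support
proxy (a warning when an exposure level is absent from the
standardization set); formal identification diagnostics are out of
scope.

Avoidable deaths scale the all-cause scenario contrast among the
exposed by N\*, the number of exposed patients diagnosed in a typical
year. N\* defaults to the count of exposed patients in the most recent
diagnosis year; an exposed-total-divided-by-years rule and a free
numeric override are also provided. The partition reports *avoidable
cancer deaths* and the *increase in other-cause deaths* separately,
with the identity AD = cancer − other_increase: patients spared the
cancer remain at risk of dying of other causes, so the other-cause
term is non-negative and grows with follow-up when the reference excess
hazard is lower. (Storing the increase with a positive sign is a
deliberate choice; the signed convention AD = cancer + other would
force the "increase" curve negative.)

## Crude-probability quadrature

θ_c and θ_o require ∫₀ᵗ S\* R g du per patient (g = λ̂ or h\*). The
integrand jumps wherever the patient crosses a life-table band, and a
fitted excess hazard behaves like u^(γ−1) near u = 0, so a single
Gauss–Legendre rule on [0, t] stalls at ~10⁻³–10⁻⁴ accuracy. The
package instead uses composite Gauss–Legendre whose panels follow the
patient's band crossings (plus the requested output times), with the
node budget `n_nodes` (default 30 per [0, t_max]) distributed over
panels proportionally to length (minimum 2 per panel), and the graded
substitution u = a·s⁴ on the panel touching zero, which removes the
endpoint singularity. The partition identity
crude-cancer + crude-other + all-cause survival = 1 serves as the
built-in accuracy oracle: closure is ~10⁻⁴ at 10 nodes, <10⁻⁴ at 30
and <10⁻⁶ at 100 across constant-hazard, Weibull and time-dependent
scenarios, and the test suite demonstrates that convergence. Negative
fitted excess-hazard mass inside the integral triggers a logged
warning, not an error.

## Uncertainty

Delta method by default: the gradient of a measure with respect to the
coefficients is taken by central finite differences (step
1e−5·(1+|θ_k|)), the variance is g'Vg, and intervals are built on a
transformed scale — log(−log) for survival-type, logit for
probability-type, identity for differences and death counts — then
back-transformed, keeping survival/probability intervals inside [0,1].
The nonparametric bootstrap (resample patients with replacement, refit
from scratch including knot placement, percentile intervals) is the
reference method; replicates that fail to converge are skipped, and
more than 10% failures is an error. The two routes agree on simulated
data (SE ratio within 15% in the acceptance suite) and both achieve
nominal-range coverage in the repeated-sampling tests. Which method an
original analysis of this kind used for its figures is typically
unstated; both are provided, with the delta method as the fast default.

## Synthetic-data generator

The generator emulates the structure of a population-based colon-cancer
cohort: two deprivation groups (most deprived = exposed, prevalence
0.445), both sexes (46.8% female), continuous ages drawn within
registry-like bands concentrated at 65–85, one diagnosis year (2008),
and five years of administrative censoring. Expected rates are Gompertz
in age, a·exp(b·age) with a = 5e−5, b = 0.09, female multiplier 0.6 and
most-deprived multiplier 1.3, capped at 0.7/yr — typical of a
high-income national life table. The excess hazard is Weibull,
λ₀κt^(κ−1) with λ₀ = 0.15 and κ = 0.9, with a log-linear age effect
(0.25 per decade, centred at 70), a proportional exposure effect
(hazard ratio 1.5) and an optional time-dependent exposure effect
(β_td·ln t multiplying x; the `illustrative()` preset uses β_td = −0.2,
a deprivation gap that is widest early in follow-up). Potential cancer
times come from inverse-transform sampling of the closed-form Weibull
cumulative hazard; potential other-cause times are drawn from the same
piecewise-constant life-table path later used in fitting (a
misspecification multiplier exists for robustness studies), and the two
are conditionally independent given covariates — precisely the
assumption the framework makes, so default tests isolate estimator
correctness from assumption violations. The observed record keeps only
the all-cause event indicator; the true cause lives on the truth object
for oracle checks. Truth marginals are computed by brute-force
trapezoid integration (10⁴ steps) of the defining integrals using the
closed-form R and exact S\*.

What passing tests therefore show: the estimators are unbiased and
their intervals calibrated *when the life table is correct, censoring
is administrative and competing risks are conditionally independent*.
Real registry data add informative censoring, life-table
misspecification, cure fractions and dependent competing risks that the
generator deliberately does not model; results here say nothing about
robustness to those.

## Problem sizes and numerical tolerances used in testing

Repeated-sampling checks use 200 replicates of n = 2000 (contrast bias
< 0.01 absolute at t = 5; delta SE within 20% of the empirical SE),
100 replicates of n = 800 for null-effect interval coverage, and 100
datasets of n = 500 with a 60-replicate bootstrap for coverage of the
constant-hazard truth — sizes chosen to keep Monte Carlo error well
below the tolerances being asserted while the full suite stays
comfortably runnable on one CPU. Analytic oracles are held to tight
tolerances: RCS closed form 1e−10, likelihood gradient 1e−4 relative,
λ̂ versus −d ln R̂/dt 1e−5.

## Known limitations

- No delayed entry, cure models, frailty, or alternative relative-
  survival families (piecewise constant, Poisson-spline).
- No mediation decomposition or inverse-probability weighting;
  identification assumptions are the user's responsibility beyond
  support warnings.
- No simultaneous confidence bands; all intervals are pointwise.
- Life tables are consumed, never constructed or smoothed.
- The bootstrap refits every replicate from scratch and is accordingly
  slow for large cohorts or many time points.
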