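# relstand

Regression standardization in the relative-survival framework: marginal
net and all-cause survival, crude probabilities of death, causal
contrasts between exposure groups, and avoidable deaths under
hypothetical scenarios — all from a flexible parametric excess-hazard
model fitted against a population life table.

## Who this is for

Population-based cancer survival studies usually care about death *due
to the cancer*, but cause-of-death codes are unreliable, especially in
the elderly. The relative-survival framework sidesteps them: a
patient's all-cause hazard is decomposed as

    h(t | Z) = h*(t | Z1) + λ(t | Z2)

where h\* is the expected mortality of a comparable disease-free person,
looked up in a population life table matched on age, sex, calendar year
and (optionally) strata such as deprivation group, and λ is the excess
hazard attributable to the cancer. All-cause survival factorizes as
S(t|Z) = S\*(t|Z1) · R(t|Z2), with R the relative survival.

`relstand` fits λ with a flexible parametric survival model — the log
cumulative excess hazard is a restricted cubic spline in log time plus
covariate effects and optional time-dependent effects — and then turns
the conditional predictions into population summaries by **regression
standardization**: averaging model-based predictions over the empirical
covariate distribution of a standardization set, optionally with
exposure X forced to a counterfactual level x:

- marginal relative (net) survival  θ(t) = E[R(t | X=x, Z2)]
- marginal all-cause survival       θ(t) = E[S\*(t | Z1) R(t | X=x, Z2)]
- marginal crude probability of death from cancer
  θ_c(t) = E[∫₀ᵗ S\*(u) R(u) λ(u) du], and from other causes with
  h\*(u) in place of λ(u)
- differences of these between counterfactual exposure assignments
  (interpretable as average causal effects under conditional
  exchangeability, consistency and positivity)
- avoidable deaths AD(t) = D₁(t|X=1) − D_R0(t|X=1): deaths among N\*
  exposed patients per typical diagnosis year minus the deaths expected
  if the exposed had the reference group's relative survival, partitioned
  into avoidable cancer deaths and the offsetting increase in
  other-cause deaths.

Pointwise 95% intervals come from the delta method (default) or a
nonparametric bootstrap.

## Worked example

Simulate a registry-like cohort (two deprivation groups, Gompertz
expected rates, Weibull excess hazard with an exposure hazard ratio of
1.5), fit the model, and standardize:

```python
import relstand as rs

sc = rs.SimulationScenario(n=2000, seed=11)
cohort, table, truth = rs.simulate_cohort(sc)

spec = rs.ModelSpec(baseline_df=3,
                    terms=[rs.linear("dep"), rs.linear("age")])
results = rs.ExcessHazardModel(cohort, table, spec).fit()
print(results.summary())

net = results.marginal_relative_survival([5.0], as_probability=True)
d   = results.marginal_difference([5.0], measure="net_probability",
                                  scenario="vary_both")
ad  = results.avoidable_deaths([5.0], n_star="latest_year")
```

Output:

```
Excess hazard model (log cumulative excess hazard scale)
  n = 2000, events = 1274, log-likelihood = -2817.351
  converged: grad_norm = 3.82e-06, iterations = 16

term                            coef          se        z    P>|z|
intercept                   -3.40503     0.22154  -15.370   0.0000
ln_t_rcs1                    1.10188     0.04319   25.514   0.0000
ln_t_rcs2                   -0.00564     0.03087   -0.183   0.8551
ln_t_rcs3                   -0.00882     0.01260   -0.700   0.4840
dep                          0.44236     0.07129    6.205   0.0000
age                          0.02365     0.00291    8.132   0.0000

5-year net probability of death: 0.553 (95% CI 0.528-0.579)
most vs least deprived difference: 0.153 (95% CI 0.105-0.200)
avoidable deaths at 5 years (N*=921): 105.0 (95% CI 72.2-137.7)
```

The `dep` coefficient estimates the log excess-hazard ratio of the most
deprived group (truth ln 1.5 ≈ 0.405). The 5-year standardized net
probability of death, 0.553, sits next to its simulation truth 0.557.
The contrast forces *everyone* in the cohort to be most deprived and
then least deprived — the same covariate average both times — so 0.153
is the cancer-related survival disadvantage itself, not a mixture of
group compositions. If the 921 most-deprived patients diagnosed in the
latest year had the least-deprived group's relative survival (expected
mortality unchanged), about 105 deaths would be avoided — strictly,
postponed — within five years.

A command-line interface covers the same workflow from delimited text
files and a YAML config (`relstand simulate|fit|standardize|contrast|
avoidable config.yaml`); outputs are delimited tables with CI columns
plus a run manifest.

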