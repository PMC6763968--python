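# arcfa — autoregressive confirmatory factor analysis

Survey respondents answer items one after another, and an item can leave a
transient trace — activated memories, primed affect — on the responses
that follow it. A conventional independent-clusters CFA (IC-CFA) ignores
these sequential "context effects": every item is modeled as its latent
trait plus independent noise, and whatever serial dependence exists in
the data is forced into inflated loadings and factor correlations, or
shows up as misfit.

`arcfa` implements the **AR-CFA**: a CFA whose item residuals carry a
first-order autoregressive structure ordered by item administration
position. For person *i*,

```
y_i   = nu + Lambda eta_i + eps_i          eta_i ~ MVN(0, Psi)
eps_i = kappa eps_i + u_i                  u_i   ~ MVN(0, Theta)
```

so the model-implied covariance matrix is

```
Sigma = Lambda Psi Lambda' + (I - kappa)^-1 Theta (I - kappa)'^-1
```

with `kappa` strictly lower triangular under administration order. An
entry `kappa[a2 <- e2]` is the effect of the residual of an earlier item
on the residual of a later one; indirect effects multiply along AR paths
and therefore fade with distance — the signature simplex pattern that
distinguishes an AR structure from free residual correlations.

The package is aimed at psychometricians and survey methodologists who
want to (a) fit AR-CFA, IC-CFA, and correlated-residual (RC-CFA)
comparison models to a covariance or correlation matrix, (b) test
hypotheses about context effects via averages and equality constraints on
AR terms, and (c) study estimator behaviour by simulation.

## What is in the box

- **Model builders** — IC-CFA; AR-CFA with an `adjacent` topology
  (consecutive items) or `adjacent_plus_construct` (consecutive items
  plus same-trait predecessors); RC-CFA (each AR path reparameterized as
  a free residual covariance, same degrees of freedom); equality
  constraint schemes that pool AR terms by effect type or by effect type
  and item scoring.
- **ML estimator** — analytic-gradient quasi-Newton minimization of the
  normal-theory discrepancy, log-scale residual variances, multi-start on
  non-convergence, observed-information standard errors, standardized
  solutions, delta-method averages of AR effects, chi-square difference
  tests with structural nesting checks.
- **Fit indices** — chi-square, CFI, TLI, RMSEA, SRMR, AIC, BIC, with a
  closed-form independence baseline.
- **Simulator** — unit-variance AR-CFA population models, reproducible
  data generation (optionally Likert-discretized), and a Monte Carlo
  harness reporting bias, RMSE, convergence rates and mean fit indices.
- **Embedded example** — the published mini-IPIP Big Five moments
  (20 items, printed SDs and two-decimal correlations, N = 8,569) as
  `arcfa.minipip_fixture()`; no download needed.

## Worked example

```python
import arcfa

layout  = arcfa.minipip_layout()          # 20 items, 5 traits, cycled order
moments = arcfa.minipip_fixture()         # printed moments, N = 8,569

ic = arcfa.fit(arcfa.build_ic_cfa(layout), moments)
ar = arcfa.fit(arcfa.build_ar_cfa(layout, "adjacent_plus_construct"), moments)

base = arcfa.baseline_fit(moments)
print(arcfa.compute_indices(ic, base))
print(arcfa.compute_indices(ar, base))
print("e2 -> a2:", round(ar.ar_estimate("e2", "a2"), 3))
print("mean |factor r|:", round(arcfa.mean_abs_factor_correlation(ar), 3))
print(arcfa.likelihood_ratio_test(ic, ar))
```

prints (abridged):

```
FitIndices(chi2=7030.38, df=160, ..., cfi=0.803, tli=0.766, rmsea=0.071, srmr=0.056, ...)
FitIndices(chi2=3555.62, df=126, ..., cfi=0.902, tli=0.852, rmsea=0.056, srmr=0.044, ...)
e2 -> a2: 0.097
mean |factor r|: 0.147
{'nested': True, 'delta_chi2': 3474.77, 'delta_df': 34, 'p_value': 0.0, ...}
```

Reading: the IC-CFA fits these personality data poorly (CFI 0.80,
RMSEA 0.07). Adding the 34 AR terms — 19 between adjacent items, 15
between same-trait items — improves every index (CFI 0.90, RMSEA 0.06)
at the cost of 34 degrees of freedom, and the difference test rejects
the IC-CFA decisively. The fitted `e2 -> a2` coefficient of 0.097 means a
one-unit residual deviation on "Don't talk a lot" carries about a tenth
of a unit into the next item's residual; the two-step indirect effect
`e2 -> a2 -> c2` is the product of the links (~0.009), i.e. context
effects fade fast. The AR-CFA's mean absolute factor correlation of 0.15
(vs 0.18 for the IC-CFA) indicates better discriminant validity once
serial dependence is modeled.

The same pipeline is scriptable from a shell:

```sh
arcfa fixture --name minipip --out minipip.csv
arcfa compare --models ic.yaml --models ar.yaml --moments minipip.csv --n 8569 --out out/
arcfa simulate --design design.yaml --out sim/
```

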