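# Methods

## Model

The AR-CFA combines an ordinary independent-clusters measurement model
with a first-order autoregressive structure among item residuals:

    y_i   = nu + Lambda eta_i + eps_i,     eta_i ~ MVN(0, Psi)
    eps_i = kappa eps_i + u_i,             u_i   ~ MVN(0, Theta)

`Lambda` (p x m) has one free loading per item, `Psi` (m x m) holds the
latent covariances, `kappa` (p x p) is strictly lower triangular under
the administration order, and `Theta` is the innovation covariance
(diagonal except in the RC-CFA variant, where former AR paths become
free off-diagonal residual covariances). The implied covariance is

    Sigma = Lambda Psi Lambda' + (I - kappa)^-1 Theta (I - kappa)'^-1.

Because `kappa` is strictly triangular, `(I - kappa)` is unit triangular:
its inverse always exists, has unit determinant, and its (r, c) entry is
the sum over all directed AR paths from item c to item r of the product
of coefficients along the path. We compute it by forward substitution on
the triangular system, never by generic inversion. Entries of `kappa`
are unconstrained in sign and magnitude; fitted within-construct effects
are frequently negative for mixed normal/reverse-scored item pairs.

Assumptions worth keeping in mind: items are treated as continuous
multivariate normal; all respondents receive the same item order (the
topology of `kappa` is shared); context effects are first-order — an
item influences later items only through chains of single-step paths.

### Identification and mean structure

Factor variances are fixed at 1 and all loadings are free, so raw `Psi`
off-diagonals are already factor correlations and the standardized
solution is direct. Marker-item identification would give identical df
and fit; only unstandardized estimates differ, and standardized output
is what we report for comparability. The mean structure is omitted
entirely: intercepts are saturated and carry no information at the
covariance level, so models are fit to covariances only.

### Topologies and constraint schemes

`adjacent` places one AR term per consecutive position pair (p - 1
terms). `adjacent_plus_construct` adds a term from each item's previous
same-trait item, skipping pairs that are already adjacent (blocked
administrations), so both effect types are never double-counted. On the
cycled 20-item mini-IPIP layout this gives 19 between-construct plus 15
within-construct terms.

Equality constraints are implemented by parameter sharing — entries with
one label occupy one optimization slot — so they hold exactly.
`by_type` pools AR terms by (source trait -> target trait); 10 groups on
the mini-IPIP. `by_type_and_scoring` splits each group into a
similar-scoring cell (normal->normal with reversed->reversed) and a
different-scoring cell; 13 cells on the mini-IPIP. Terms whose target
item has no within-trait predecessor (the four first-cycle links
e1->a1, a1->c1, c1->n1, n1->o1) receive only a between-construct effect
and are not comparable to later terms of their group, so both schemes
leave them free. This rule is stated structurally ("no within-trait
predecessor") so it generalizes beyond this particular layout, and it
reproduces the published constraint counts (34 -> 14 and 34 -> 17 free
AR parameters).

## Estimation

The estimator minimizes the normal-theory discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

with an analytic gradient assembled matrix-by-matrix from
dF = tr[Sigma^-1 (Sigma - S) Sigma^-1 dSigma], using L-BFGS-B.
Residual variances are optimized on the log scale, which keeps `Theta`
positive without constraints; points where `Sigma` loses positive
definiteness return a large penalty value and are backtracked over.
Start values are conventional: loadings 0.7 x item SD, factor
correlations 0.2, AR terms 0, residual variances half the item variance.
On non-convergence up to two jittered restarts (scale 0.1, seeded) are
attempted; the documented small-sample fragility of the AR-CFA makes
this worthwhile, and a fit that still fails is returned with
`converged=False` rather than raised.

Convergence requires an infinity-norm gradient below 1e-6 and a positive
definite observed information matrix. chi2 = (N - 1) F_min (Wishart
convention; at N = 8,569 the N vs N - 1 choice is immaterial at printed
precision). Standard errors invert ((N - 1)/2) x the Hessian of F
(central differences of the analytic gradient) and are delta-method
propagated through the log-variance reparameterization. Averages of AR
effects get delta-method SEs from the full parameter covariance;
individual parameters use the normal reference for t and p values.

Nested chi-square difference tests verify nesting structurally (same
layout; every cell free in the restricted spec is free in the full one).
The RC-CFA is deliberately non-nested with the AR-CFA (equal df); the
nested test refuses such pairs and the comparison falls back to
AIC/BIC differences.

## Fit indices

CFI = 1 - max(chi2 - df, 0)/max(chi2_b - df_b, chi2 - df, 0);
TLI = ((chi2_b/df_b) - (chi2/df)) / ((chi2_b/df_b) - 1), clamped to
[0, 1] by default (unclamped behind a flag);
RMSEA = sqrt(max(chi2 - df, 0)/(df (N - 1))); the independence baseline
(Sigma = diag(S), df = p(p-1)/2, chi2 = -(N-1) ln|R|) is closed form.
SRMR is the root mean square of residual correlations including the
diagonal terms by default; the off-diagonal-only dialect is available
via a flag — on the embedded example the two differ by < 0.003.
AIC = -2 lnL + 2q and BIC = -2 lnL + q ln N use the covariance-only
multivariate-normal likelihood (no mean block), so absolute values
differ by a constant from software that includes a saturated mean
structure; differences and orderings between models on the same moments
are the supported contract.

## The embedded example and printed precision

The mini-IPIP moments ship as printed standard deviations and a
two-decimal lower-triangular correlation matrix (N = 8,569), expanded to
a covariance as D R D. Two consequences:

- Refit statistics match published values at printed precision only.
  The test suite compares CFI/RMSEA after rounding to two decimals,
  allowing one unit in the last printed digit.
- The published chi-squares were computed with a robust (scaled)
  correction, which shrinks chi2 by a model-specific factor and
  propagates into CFI/TLI; plain ML from the same moments therefore
  gives somewhat larger chi2 (7030 vs 6053 for the IC-CFA) while
  parameter estimates, df arithmetic, index magnitudes, and every
  model-comparison direction agree. Robust corrections require raw-data
  fourth moments that a printed correlation matrix cannot supply, so
  they are deliberately out of scope.

Also out of scope: Bayesian estimation (posterior-predictive p, DIC,
pD), exploratory/ESEM rotation machinery, latent-interaction moderation
of AR effects, missing-data FIML, and ordinal-item (polychoric) 
estimation.

## Simulator

`make_population` builds a unit-variance AR-CFA population: standardized
loadings 0.8, factor correlations 0.2, and a common AR coefficient from
{0, 0.1, 0.2, 0.3} on the chosen topology — the default grid also spans
sample sizes {250, 500, 1000}. Residual innovation variances are solved
per item in administration order so that diag(Sigma) = 1 exactly
(earlier items' innovations feed later items' totals through kappa); an
infeasible variance budget (e.g. loading 1.0) raises immediately.

`simulate_dataset` draws eta and u and applies the generating equations;
data are continuous normal by default, since that is the cleanest
surface for parameter recovery, with optional equal-probability Likert
discretization (k = 5) for realism studies. The generator reproduces
the population covariance in large samples but does not emulate real
response styles, acquiescence, person-varying AR effects, or
missingness — passing recovery tests therefore demonstrates estimator
correctness under the model, not robustness to such features.

`run_monte_carlo` derives per-replication seeds from the master seed via
a seed sequence, fits each requested model with a fast single-start
profile (gradient tolerance 1e-4, no standard errors), records
non-converged replications against the convergence rate, and summarizes
bias, RMSE and Monte Carlo SE per parameter class plus mean fit indices
per cell. The full summary is bit-reproducible for a fixed design. The
default design uses 500 replications per cell; the test suite exercises
the documented reduced profile of 100 replications at N = 1000, which
reproduces the qualitative findings (no-harm of the AR-CFA under an
IC-CFA truth; inflated IC-CFA factor correlations and degraded fit as
the true AR effect grows) in under a minute.

## Known limitations

- First-order AR only; higher-order AR and moving-average residual
  structures are not implemented.
- One shared `kappa` topology across respondents; randomized item orders
  would need person-specific AR matrices.
- Plain (non-robust) chi-square and SEs; kurtotic data will understate
  uncertainty.
- Equality constraints apply to AR terms; general cross-matrix
  constraints are not exposed.
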