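"""Maximum-likelihood estimation of covariance-structure models.

Fits any :class:`~arcfa.model.ModelSpec` to a sample covariance matrix by
minimizing the normal-theory ML discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

with chi2 = (N - 1) * F_min (Wishart convention).  Residual variances are
optimized on the log scale so Theta stays positive; standard errors come
from the observed information ((N-1)/2 times the Hessian of F), propagated
back to the natural scale by the delta method.  Equality constraints are
parameter sharing (one slot per label), so they hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .covariance import ParameterIndex, ar_propagator, materialize
from .model import AR, FACTOR_COV, LOADING, RESIDUAL_COV, RESIDUAL_VAR, ModelSpec, assert_nested, model_df
from .moments import SampleMoments

__all__ = [
    "FitOptions",
    "FitResult",
    "DerivedEstimate",
    "ml_discrepancy",
    "fit",
    "standard_errors",
    "standardize",
    "derived_group_mean",
    "mean_abs_factor_correlation",
    "likelihood_ratio_test",
    "compare_fits",
    "NotNestedError",
]

_BIG = 1e12


class NotNestedError(ValueError):
    """Raised when a nested test is requested for structurally non-nested specs."""


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy between a sample and a model covariance.

    Returns ``inf`` when Sigma is singular or not positive definite (an
    inadmissible point during optimization, not an exception).
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    if S.shape != Sigma.shape or Sigma.shape != (p, p):
        raise ValueError("S and Sigma must be square matrices of the same order")
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("S must be positive definite")
    try:
        c = cho_factor(Sigma, lower=True)
    except LinAlgError:
        return np.inf
    logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return logdet_sigma + float(np.trace(cho_solve(c, S))) - logdet_s - p


# ---------------------------------------------------------------------------
# Objective with analytic gradient
# ---------------------------------------------------------------------------

def _theta_from_phi(phi: np.ndarray, var_slots: np.ndarray) -> np.ndarray:
    theta = phi.copy()
    theta[var_slots] = np.exp(phi[var_slots])
    return theta


def _objective(phi, index, S, logdet_s, var_slots):
    """F(phi) and its analytic gradient, phi = theta with log residual variances."""
    p = S.shape[0]
    theta = _theta_from_phi(phi, var_slots)
    lam, psi, kappa, theta_mat = materialize(index, theta)
    g = ar_propagator(kappa)
    resid = g @ theta_mat @ g.T
    sigma = lam @ psi @ lam.T + resid
    sigma = (sigma + sigma.T) / 2.0
    try:
        c = cho_factor(sigma, lower=True)
    except LinAlgError:
        return _BIG, np.zeros_like(phi)
    logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    siginv = cho_solve(c, np.eye(p))
    f_value = logdet_sigma + float(np.sum(siginv * S)) - logdet_s - p

    # dF = tr(W dSigma) with W = Sigma^-1 (Sigma - S) Sigma^-1
    w = siginv - siginv @ S @ siginv
    m_load = w @ lam @ psi                  # loadings
    m_psi = lam.T @ w @ lam                 # factor covariances
    m_var = g.T @ w @ g                     # residual (co)variances
    m_ar = g.T @ w @ resid                  # AR coefficients

    grad = np.zeros_like(phi)
    for e, slot in zip(index.spec.entries, index.slot_of_entry):
        if slot < 0:
            continue
        if e.matrix == LOADING:
            grad[slot] += 2.0 * m_load[e.row, e.col]
        elif e.matrix == FACTOR_COV:
            grad[slot] += (1.0 if e.row == e.col else 2.0) * m_psi[e.row, e.col]
        elif e.matrix == AR:
            grad[slot] += 2.0 * m_ar[e.row, e.col]
        elif e.matrix == RESIDUAL_VAR:
            grad[slot] += m_var[e.row, e.row]
        else:
            grad[slot] += 2.0 * m_var[e.row, e.col]
    grad[var_slots] *= theta[var_slots]  # chain rule for log-variances
    return f_value, grad


def start_vector(index: ParameterIndex, moments: SampleMoments | None = None) -> np.ndarray:
    """Conventional start values: loadings 0.7 * item SD, factor
    covariances 0.2, AR terms 0, residual variances half the item variance."""
    spec = index.spec
    theta = np.zeros(index.n_free)
    sd = np.ones(spec.layout.p)
    if moments is not None:
        sd = np.sqrt(np.diag(moments.S))
    for e, slot in zip(spec.entries, index.slot_of_entry):
        if slot < 0:
            continue
        if e.matrix == LOADING:
            theta[slot] = 0.7 * sd[e.row]
        elif e.matrix == FACTOR_COV:
            theta[slot] = 0.2 if e.row != e.col else 1.0
        elif e.matrix == RESIDUAL_VAR:
            theta[slot] = 0.5 * sd[e.row] ** 2
        # ar and residual_cov start at 0
    return theta


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    gtol: float = 1e-6          # infinity-norm gradient tolerance for convergence
    maxiter: int = 5000
    n_starts: int = 3           # jittered restarts on non-convergence
    jitter: float = 0.1
    seed: int = 0               # seeds the restart jitter only
    compute_se: bool = True


@dataclass(frozen=True)
class DerivedEstimate:
    """A derived quantity with a delta-method standard error."""

    label: str
    estimate: float
    se: float
    t: float
    p_value: float


@dataclass
class FitResult:
    """Outcome of one ML fit."""

    spec: ModelSpec
    index: ParameterIndex
    moments: SampleMoments
    theta: np.ndarray
    f_min: float
    chi2: float
    df: int
    loglik: float
    converged: bool
    grad_norm: float
    hessian_pd: bool | None = None
    se: np.ndarray | None = None
    acov: np.ndarray | None = None  # parameter covariance, natural scale
    n_iter: int = 0
    message: str = ""
    _sigma_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.moments.n

    @property
    def q(self) -> int:
        """Distinct free parameters."""
        return self.index.n_free

    def sigma(self) -> np.ndarray:
        if self._sigma_cache is None:
            from .covariance import implied_covariance

            self._sigma_cache = implied_covariance(self.index, self.theta).sigma
        return self._sigma_cache

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return materialize(self.index, self.theta)

    def param(self, label: str) -> float:
        return float(self.theta[self.index.labels.index(label)])

    def param_se(self, label: str) -> float:
        if self.se is None:
            raise ValueError("standard errors unavailable for this fit")
        return float(self.se[self.index.labels.index(label)])

    def ar_estimate(self, source: str, target: str) -> float:
        return float(self.theta[self.index.ar_slot(source, target)])

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.q

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.q * np.log(self.n)


def _loglik(f_min: float, S: np.ndarray, n: int) -> float:
    """Covariance-only multivariate-normal log-likelihood at the optimum
    (Wishart N-1 convention; no mean structure)."""
    p = S.shape[0]
    _, logdet_s = np.linalg.slogdet(S)
    # F = logdet_sigma + tr(S Sigma^-1) - logdet_s - p  =>  recover the kernel
    kernel = f_min + logdet_s + p
    return -0.5 * (n - 1) * (kernel + p * np.log(2.0 * np.pi))


def fit(
    spec: ModelSpec,
    moments: SampleMoments,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit a model spec to sample moments by maximum likelihood.

    The moments are aligned to the layout's administration order by
    variable name.  Non-convergence is returned as a diagnosable result
    (``converged=False``), never as silent success.
    """
    options = options or FitOptions()
    moments = moments.reorder(spec.layout.names)
    S = moments.S
    p = moments.p
    sign, logdet_s = np.linalg.slogdet(S)
    index = ParameterIndex.for_spec(spec)
    var_slots = np.array(
        [k for k, kind in enumerate(index.kinds) if kind == RESIDUAL_VAR], dtype=int
    )

    theta0 = start_vector(index, moments)
    phi0 = theta0.copy()
    phi0[var_slots] = np.log(np.maximum(theta0[var_slots], 1e-8))

    rng = np.random.default_rng(options.seed)
    best = None
    for attempt in range(max(1, options.n_starts)):
        start = phi0 if attempt == 0 else phi0 + rng.normal(scale=options.jitter, size=phi0.shape)
        res = optimize.minimize(
            _objective,
            start,
            args=(index, S, logdet_s, var_slots),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": options.maxiter, "ftol": 1e-14, "gtol": 1e-9},
        )
        f_val, grad = _objective(res.x, index, S, logdet_s, var_slots)
        grad_norm = float(np.max(np.abs(grad)))
        candidate = (f_val, grad_norm, res)
        if best is None or f_val < best[0]:
            best = candidate
        if grad_norm < options.gtol and f_val < _BIG:
            best = candidate
            break

    f_min, grad_norm, res = best
    phi_hat = res.x
    theta_hat = _theta_from_phi(phi_hat, var_slots)
    converged = bool(grad_norm < options.gtol and np.isfinite(f_min) and f_min < _BIG)

    result = FitResult(
        spec=spec,
        index=index,
        moments=moments,
        theta=theta_hat,
        f_min=float(f_min),
        chi2=float((moments.n - 1) * f_min),
        df=model_df(spec),
        loglik=_loglik(float(f_min), S, moments.n),
        converged=converged,
        grad_norm=grad_norm,
        n_iter=int(res.nit),
        message=str(res.message),
    )
    if options.compute_se and converged:
        _attach_standard_errors(result, phi_hat, index, S, logdet_s, var_slots)
        if result.hessian_pd is False:
            result.converged = False
    return result


def _attach_standard_errors(result, phi_hat, index, S, logdet_s, var_slots) -> None:
    """Observed-information SEs: invert ((N-1)/2) * Hessian of F (central
    differences of the analytic gradient), delta-method back to the
    natural scale."""
    q = phi_hat.size
    hess = np.empty((q, q))
    for k in range(q):
        h = 1e-5 * max(1.0, abs(phi_hat[k]))
        up = phi_hat.copy()
        dn = phi_hat.copy()
        up[k] += h
        dn[k] -= h
        _, g_up = _objective(up, index, S, logdet_s, var_slots)
        _, g_dn = _objective(dn, index, S, logdet_s, var_slots)
        hess[:, k] = (g_up - g_dn) / (2.0 * h)
    hess = (hess + hess.T) / 2.0
    n = result.moments.n
    try:
        info_chol = cho_factor((n - 1) / 2.0 * hess, lower=True)
        acov_phi = cho_solve(info_chol, np.eye(q))
        pd_ok = True
    except LinAlgError:
        result.hessian_pd = False
        return
    jac = np.ones(q)
    theta = result.theta
    jac[var_slots] = theta[var_slots]  # d theta / d phi for log-variances
    acov = acov_phi * np.outer(jac, jac)
    result.hessian_pd = pd_ok
    result.acov = acov
    result.se = np.sqrt(np.maximum(np.diag(acov), 0.0))


def standard_errors(result: FitResult) -> np.ndarray:
    """Standard errors of the free parameters (natural scale)."""
    if result.se is None:
        raise ValueError("fit carries no standard errors (non-converged or disabled)")
    return result.se


# ---------------------------------------------------------------------------
# Standardization and derived quantities
# ---------------------------------------------------------------------------

def standardize(result: FitResult) -> pd.DataFrame:
    """Standardized solution as a tidy table.

    Loadings are rescaled to unit observed and latent variance; factor
    correlations equal the raw Psi off-diagonals under unit-variance
    identification; AR coefficients are rescaled by the residual standard
    deviations of source and target items; residual variances are
    expressed as proportions of total item variance.
    """
    lam, psi, kappa, theta_mat = result.matrices()
    sigma = result.sigma()
    g = ar_propagator(kappa)
    resid_cov = g @ theta_mat @ g.T
    item_sd = np.sqrt(np.diag(sigma))
    resid_sd = np.sqrt(np.diag(resid_cov))
    fac_sd = np.sqrt(np.diag(psi))

    rows = []
    theta = result.theta
    se = result.se
    for e, slot in zip(result.spec.entries, result.index.slot_of_entry):
        if slot < 0:
            est = e.fixed_value
            se_k = np.nan
        else:
            est = float(theta[slot])
            se_k = float(se[slot]) if se is not None else np.nan
        if e.matrix == LOADING:
            std = est * fac_sd[e.col] / item_sd[e.row]
        elif e.matrix == FACTOR_COV:
            std = est / (fac_sd[e.row] * fac_sd[e.col])
        elif e.matrix == AR:
            std = est * resid_sd[e.col] / resid_sd[e.row]
        elif e.matrix == RESIDUAL_VAR:
            std = theta_mat[e.row, e.row] / sigma[e.row, e.row]
        else:
            std = est / (item_sd[e.row] * item_sd[e.col])
        label = (
            result.index.labels[slot]
            if slot >= 0
            else f"fixed[{e.matrix},{e.row},{e.col}]"
        )
        t_stat = est / se_k if slot >= 0 and np.isfinite(se_k) and se_k > 0 else np.nan
        rows.append(
            {
                "label": label,
                "matrix": e.matrix,
                "row": e.row,
                "col": e.col,
                "estimate": est,
                "se": se_k,
                "t": t_stat,
                "p": 2.0 * stats.norm.sf(abs(t_stat)) if np.isfinite(t_stat) else np.nan,
                "std": float(std),
                "free": e.free,
            }
        )
    return pd.DataFrame(rows)


def mean_abs_factor_correlation(result: FitResult) -> float:
    """Average absolute latent factor correlation (discriminant validity)."""
    _, psi, _, _ = result.matrices()
    d = 1.0 / np.sqrt(np.diag(psi))
    corr = psi * np.outer(d, d)
    m = corr.shape[0]
    off = corr[np.tril_indices(m, k=-1)]
    return float(np.mean(np.abs(off)))


def derived_group_mean(
    result: FitResult, group: list[tuple[str, str]], label: str = ""
) -> DerivedEstimate:
    """Arithmetic mean of a group of AR coefficients, with a delta-method
    standard error from the parameter covariance matrix.

    ``group`` is a list of (source item, target item) name pairs; all must
    be free AR parameters of the fit.
    """
    if not group:
        raise ValueError("empty group")
    slots = [result.index.ar_slot(src, tgt) for src, tgt in group]
    a = np.zeros(result.q)
    for s in slots:
        a[s] += 1.0 / len(slots)
    estimate = float(a @ result.theta)
    if result.acov is None:
        raise ValueError("fit carries no parameter covariance matrix")
    se = float(np.sqrt(a @ result.acov @ a))
    t = estimate / se if se > 0 else np.nan
    return DerivedEstimate(
        label=label or " + ".join(f"{s}->{t_}" for s, t_ in group),
        estimate=estimate,
        se=se,
        t=t,
        p_value=2.0 * stats.norm.sf(abs(t)) if np.isfinite(t) else np.nan,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def likelihood_ratio_test(fit_restricted: FitResult, fit_full: FitResult) -> dict:
    """Chi-square difference test for nested fits on the same moments.

    Nesting is verified structurally; non-nested pairs raise
    :class:`NotNestedError` (compare those descriptively with
    :func:`compare_fits`).
    """
    try:
        assert_nested(fit_restricted.spec, fit_full.spec)
    except ValueError as exc:
        raise NotNestedError(str(exc)) from exc
    d_chi2 = fit_restricted.chi2 - fit_full.chi2
    d_df = fit_restricted.df - fit_full.df
    p_value = float(stats.chi2.sf(d_chi2, d_df)) if d_df > 0 else (1.0 if d_chi2 <= 0 else 0.0)
    return {
        "nested": True,
        "delta_chi2": float(d_chi2),
        "delta_df": int(d_df),
        "p_value": p_value,
        "delta_aic": fit_restricted.aic - fit_full.aic,
        "delta_bic": fit_restricted.bic - fit_full.bic,
    }


def compare_fits(fit_a: FitResult, fit_b: FitResult) -> dict:
    """Descriptive comparison; runs the nested test when the pair nests."""
    try:
        return likelihood_ratio_test(fit_a, fit_b)
    except NotNestedError:
        return {
            "nested": False,
            "delta_chi2": float(fit_a.chi2 - fit_b.chi2),
            "delta_df": int(fit_a.df - fit_b.df),
            "p_value": None,
            "delta_aic": fit_a.aic - fit_b.aic,
            "delta_bic": fit_a.bic - fit_b.bic,
        }
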