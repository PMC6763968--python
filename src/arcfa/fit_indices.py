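"""Global fit statistics: chi-square, CFI, TLI, RMSEA, SRMR, AIC, BIC.

Incremental indices (CFI, TLI) are computed against the independence
baseline (free variances, all covariances zero), whose ML solution is
available in closed form: Sigma = diag(S), so chi2_baseline =
-(N - 1) ln|R| with R the sample correlation matrix.

Absolute AIC/BIC values use the covariance-only multivariate-normal
likelihood (no mean structure); differences and orderings between models
fitted to the same moments are the supported contract, since absolute
values depend on the likelihood-constant convention of the software.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .estimate import FitResult, _loglik
from .model import ModelSpec, ParameterEntry, RESIDUAL_VAR
from .covariance import ParameterIndex
from .moments import SampleMoments

__all__ = ["FitIndices", "baseline_fit", "compute_indices", "comparison_table"]


@dataclass(frozen=True)
class FitIndices:
    chi2: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    aic: float
    bic: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def _independence_spec(names: tuple[str, ...]) -> ModelSpec:
    from .layout import Item, ItemLayout

    items = tuple(
        Item(name=nm, trait=nm, position=k + 1) for k, nm in enumerate(names)
    )
    layout = ItemLayout(items=items)
    entries = [ParameterEntry(RESIDUAL_VAR, i, i, start=1.0) for i in range(len(names))]
    return ModelSpec(layout=layout, entries=tuple(entries), name="independence")


def baseline_fit(moments: SampleMoments) -> FitResult:
    """Independence-model fit, solved in closed form.

    The ML solution of the diagonal model is Sigma = diag(S); the model
    has p free variances and df = p(p-1)/2.
    """
    S = moments.S
    p = moments.p
    corr = moments.correlations()
    sign, logdet_r = np.linalg.slogdet(corr)
    f_min = float(-logdet_r)  # ln|diag S| - ln|S| = -ln|R|
    spec = _independence_spec(moments.names)
    index = ParameterIndex.for_spec(spec)
    theta = np.diag(S).copy()
    return FitResult(
        spec=spec,
        index=index,
        moments=moments,
        theta=theta,
        f_min=f_min,
        chi2=float((moments.n - 1) * f_min),
        df=p * (p - 1) // 2,
        loglik=_loglik(f_min, S, moments.n),
        converged=True,
        grad_norm=0.0,
        hessian_pd=True,
    )


def _srmr(S: np.ndarray, sigma: np.ndarray, include_diagonal: bool = True) -> float:
    """Root mean square of residual correlations.

    Residuals are (s_ij - sigma_ij) / sqrt(s_ii s_jj) over the lower
    triangle; the diagonal terms (which vanish only if the model
    reproduces the observed variances) are included by default, with the
    off-diagonal-only dialect behind the flag.
    """
    d = 1.0 / np.sqrt(np.diag(S))
    resid = (S - sigma) * np.outer(d, d)
    k = 0 if include_diagonal else -1
    tri = resid[np.tril_indices(S.shape[0], k=k)]
    return float(np.sqrt(np.mean(tri**2)))


def compute_indices(
    fit: FitResult,
    baseline: FitResult | None = None,
    *,
    srmr_include_diagonal: bool = True,
    clamp_tli: bool = True,
) -> FitIndices:
    """Assemble the fit-index block for one fitted model.

    ``baseline`` defaults to the closed-form independence fit on the same
    moments.  For a saturated model (df = 0), RMSEA is reported as 0 and
    TLI as not-applicable (NaN).
    """
    if baseline is None:
        baseline = baseline_fit(fit.moments)
    if baseline.moments.n != fit.moments.n or set(baseline.moments.names) != set(fit.moments.names):
        raise ValueError("fit and baseline must be computed on the same moments")
    chi2, df, n = fit.chi2, fit.df, fit.n
    chi2_b, df_b = baseline.chi2, baseline.df

    num = max(chi2 - df, 0.0)
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - num / denom if denom > 0 else 1.0
    cfi = float(min(max(cfi, 0.0), 1.0))

    if df > 0 and df_b > 0 and chi2_b / df_b > 1.0:
        tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
        if clamp_tli:
            tli = min(max(tli, 0.0), 1.0)
        tli = float(tli)
    else:
        tli = float("nan")

    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0
    srmr = _srmr(fit.moments.S, fit.sigma(), include_diagonal=srmr_include_diagonal)
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return FitIndices(
        chi2=float(chi2),
        df=int(df),
        p_value=p_value,
        cfi=cfi,
        tli=tli,
        rmsea=rmsea,
        srmr=srmr,
        aic=float(fit.aic),
        bic=float(fit.bic),
        n=n,
    )


def comparison_table(fits: dict[str, FitResult]) -> "pd.DataFrame":
    """Fit-statistic comparison table: rows = statistics, columns = models."""
    import pandas as pd

    columns = {}
    for name, f in fits.items():
        baseline = baseline_fit(f.moments)
        idx = compute_indices(f, baseline)
        columns[name] = {
            "chi2": idx.chi2,
            "df": idx.df,
            "cfi": idx.cfi,
            "tli": idx.tli,
            "rmsea": idx.rmsea,
            "srmr": idx.srmr,
            "aic": idx.aic,
            "bic": idx.bic,
        }
    return pd.DataFrame(columns)
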