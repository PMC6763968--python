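"""Readers and writers: moment matrices, raw data, model configs, reports.

Moment files are CSV with a header row and a leading name column; the
matrix block may be full or lower-triangular (published matrices are
usually printed lower-triangular; the upper triangle is mirrored exactly).
When an ``sd`` column is present the block is interpreted as correlations
and the covariance is rebuilt as D R D.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .layout import Item, ItemLayout, minipip_layout
from .model import (
    ModelSpec,
    apply_equality_constraints,
    build_ar_cfa,
    build_ic_cfa,
    build_rc_cfa,
)
from .moments import SampleMoments

__all__ = [
    "read_moments",
    "write_moments",
    "read_raw",
    "read_model_config",
    "spec_from_config",
    "fit_report",
    "write_report",
]

log = logging.getLogger("arcfa")


def _mirror(block: np.ndarray, names: list[str]) -> np.ndarray:
    """Mirror a lower-triangular block; reject asymmetric full matrices."""
    filled = ~np.isnan(block)
    lower_only = not filled[np.triu_indices_from(block, k=1)].any()
    if lower_only:
        out = np.where(np.isnan(block), 0.0, block)
        out = out + out.T - np.diag(np.diag(out))
        return out
    if np.isnan(block).any():
        raise ValueError("matrix block must be full or strictly lower-triangular")
    if not np.allclose(block, block.T, atol=1e-9):
        delta = float(np.max(np.abs(block - block.T)))
        raise ValueError(f"full matrix is asymmetric beyond tolerance (max |a-a'| = {delta:.3e})")
    return (block + block.T) / 2.0


def read_moments(path: str | Path, n: int, kind: str = "auto") -> SampleMoments:
    """Load a covariance or correlation-plus-SD matrix from CSV.

    ``kind`` is ``"covariance"``, ``"correlation"`` (requires an ``sd``
    column) or ``"auto"`` (correlation iff an ``sd`` column is present).
    Positive definiteness is verified at load; the smallest eigenvalue is
    logged so near-singular inputs are diagnosable.
    """
    table = pd.read_csv(path, index_col=0)
    has_sd = "sd" in table.columns
    if kind == "auto":
        kind = "correlation" if has_sd else "covariance"
    if kind == "correlation" and not has_sd:
        raise ValueError("correlation input requires an 'sd' column")
    names = [str(x) for x in table.index]
    block = _mirror(table[names].to_numpy(dtype=float), names)
    if kind == "correlation":
        sds = table["sd"].to_numpy(dtype=float)
        cov = block * np.outer(sds, sds)
    else:
        cov = block
    moments = SampleMoments(S=cov, names=tuple(names), n=int(n))
    log.info(
        "loaded %d x %d moments (N=%d), smallest eigenvalue %.3e",
        moments.p, moments.p, moments.n, moments.smallest_eigenvalue,
    )
    return moments


def write_moments(moments: SampleMoments, path: str | Path, kind: str = "covariance") -> None:
    """Write moments as CSV; the file round-trips through
    :func:`read_moments`.

    ``kind="covariance"`` writes the full covariance block (no ``sd``
    column, bit-faithful round trip); ``kind="correlation"`` writes the
    published-table style: an ``sd`` column plus the correlation block.
    """
    if kind == "covariance":
        table = pd.DataFrame(moments.S, index=list(moments.names), columns=list(moments.names))
    elif kind == "correlation":
        table = pd.DataFrame(
            moments.correlations(), index=list(moments.names), columns=list(moments.names)
        )
        table.insert(0, "sd", moments.sds())
    else:
        raise ValueError(f"unknown kind {kind!r}")
    table.to_csv(path, float_format="%.17g")


def read_raw(
    path: str | Path, group_col: str | None = None
) -> SampleMoments:
    """Sample covariance (N-1 denominator) from case-level CSV data.

    Rows with missing values are dropped listwise (with a logged count).
    ``group_col`` names a clustering column whose group means are removed
    before computing the covariance (fixed-effects / group-mean centering,
    as used for multi-site samples).
    """
    data = pd.read_csv(path)
    if group_col is not None:
        groups = data[group_col]
        data = data.drop(columns=[group_col])
    n_before = len(data)
    if not all(pd.api.types.is_numeric_dtype(t) for t in data.dtypes):
        bad = [c for c in data.columns if not pd.api.types.is_numeric_dtype(data[c])]
        raise ValueError(f"non-numeric item columns: {bad}")
    mask = data.notna().all(axis=1)
    if group_col is not None:
        mask &= groups.notna()
        groups = groups[mask]
    data = data[mask]
    dropped = n_before - len(data)
    if dropped:
        log.warning("listwise deletion removed %d incomplete cases", dropped)
    if group_col is not None:
        data = data.groupby(groups.to_numpy()).transform(lambda x: x - x.mean())
    zero_var = [c for c in data.columns if float(data[c].var(ddof=1)) == 0.0]
    if zero_var:
        raise ValueError(f"zero-variance columns: {zero_var}")
    S = data.cov(ddof=1).to_numpy()
    return SampleMoments(S=S, names=tuple(str(c) for c in data.columns), n=len(data))


# ---------------------------------------------------------------------------
# Model configuration files
# ---------------------------------------------------------------------------

def read_model_config(path: str | Path) -> dict:
    """Read a YAML or JSON model configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _layout_from_config(config: dict) -> ItemLayout:
    items_cfg = config.get("items", "minipip")
    if items_cfg == "minipip" or config.get("layout") == "minipip":
        return minipip_layout()
    items = tuple(
        Item(
            name=str(it["name"]),
            trait=str(it["trait"]),
            position=int(it["position"]),
            scoring=it.get("scoring", "normal"),
            text=it.get("text", ""),
        )
        for it in items_cfg
    )
    return ItemLayout(items=items)


def spec_from_config(config: dict) -> ModelSpec:
    """Build a ModelSpec from a configuration mapping.

    Keys: ``items`` (list of descriptors, or the reserved name
    ``minipip``), ``model`` (ic_cfa | ar_cfa | rc_cfa), ``topology``
    (adjacent | adjacent_plus_construct), ``constraints`` (none |
    by_type | by_type_and_scoring).
    """
    layout = _layout_from_config(config)
    model = config.get("model", "ic_cfa")
    topology = config.get("topology", "adjacent_plus_construct")
    if model == "ic_cfa":
        spec = build_ic_cfa(layout)
    elif model == "ar_cfa":
        spec = build_ar_cfa(layout, topology)
    elif model == "rc_cfa":
        spec = build_rc_cfa(build_ar_cfa(layout, topology))
    else:
        raise ValueError(f"unknown model {model!r}")
    constraints = config.get("constraints", "none") or "none"
    if constraints != "none":
        spec = apply_equality_constraints(spec, constraints)
    return spec


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def fit_report(fit_result, indices=None) -> dict:
    """Structured (JSON-serializable) report for one fit."""
    from .estimate import standardize

    params = standardize(fit_result)
    report = {
        "model": fit_result.spec.name,
        "n": fit_result.n,
        "converged": bool(fit_result.converged),
        "grad_norm": float(fit_result.grad_norm),
        "fit": {
            "f_min": fit_result.f_min,
            "chi2": fit_result.chi2,
            "df": fit_result.df,
            "loglik": fit_result.loglik,
            "aic": fit_result.aic,
            "bic": fit_result.bic,
        },
        "parameters": params.where(pd.notna(params), None).to_dict(orient="records"),
    }
    if indices is not None:
        report["indices"] = indices.as_dict()
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
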