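"""Model specifications: parameter tables for IC-CFA, AR-CFA and variants.

A :class:`ModelSpec` is a list of :class:`ParameterEntry` rows describing
which elements of the loading matrix Lambda, factor covariance matrix Psi,
autoregressive matrix kappa and residual covariance matrix Theta are free,
fixed, or constrained equal.  The covariance engine materializes these into
matrices; :func:`model_df` does the degrees-of-freedom bookkeeping.

Identification convention: factor variances are fixed at 1 (all loadings
free), so raw factor covariances are already correlations and the
standardized solution is direct.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

from .layout import ItemLayout

__all__ = [
    "ParameterEntry",
    "ModelSpec",
    "build_ic_cfa",
    "build_ar_cfa",
    "build_rc_cfa",
    "apply_equality_constraints",
    "model_df",
]

Matrix = Literal["loading", "factor_cov", "ar", "residual_var", "residual_cov"]

LOADING = "loading"
FACTOR_COV = "factor_cov"
AR = "ar"
RESIDUAL_VAR = "residual_var"
RESIDUAL_COV = "residual_cov"

FREE = "free"
FIXED = "fixed"


@dataclass(frozen=True)
class ParameterEntry:
    """One cell of a model parameter matrix.

    ``row``/``col`` are 0-based indices: items in administration order for
    ``loading`` rows and for both indices of ``ar`` / ``residual_*``
    entries; factors in trait order for ``loading`` columns and both
    indices of ``factor_cov`` entries.  Entries sharing an ``eq_label``
    are constrained equal (one free parameter).
    """

    matrix: Matrix
    row: int
    col: int
    status: str = FREE
    fixed_value: float = 0.0
    eq_label: str | None = None
    start: float = 0.0

    def __post_init__(self) -> None:
        if self.status == FIXED and self.eq_label is not None:
            raise ValueError("an entry cannot be both fixed and equality-labeled")
        if self.matrix == AR and not self.row > self.col:
            raise ValueError("ar entries must run from an earlier item (col) to a later one (row)")
        if self.matrix == RESIDUAL_COV and self.row == self.col:
            raise ValueError("residual_cov entries must connect two distinct items")
        if self.matrix == RESIDUAL_VAR and self.row != self.col:
            raise ValueError("residual_var entries are diagonal (row == col)")

    @property
    def free(self) -> bool:
        return self.status == FREE


@dataclass(frozen=True)
class ModelSpec:
    """A measurement-model specification bound to an item layout."""

    layout: ItemLayout
    entries: tuple[ParameterEntry, ...]
    name: str = "model"

    def __post_init__(self) -> None:
        p, m = self.layout.p, self.layout.m
        bounds = {
            LOADING: (p, m),
            FACTOR_COV: (m, m),
            AR: (p, p),
            RESIDUAL_VAR: (p, p),
            RESIDUAL_COV: (p, p),
        }
        seen: set[tuple[str, int, int]] = set()
        for e in self.entries:
            nr, nc = bounds[e.matrix]
            if not (0 <= e.row < nr and 0 <= e.col < nc):
                raise ValueError(f"entry {e} out of bounds for {e.matrix} ({nr}x{nc})")
            key = (e.matrix, e.row, e.col)
            if key in seen:
                raise ValueError(f"duplicate entry for {key}")
            seen.add(key)

    def select(self, matrix: str) -> tuple[ParameterEntry, ...]:
        return tuple(e for e in self.entries if e.matrix == matrix)

    @property
    def n_free_distinct(self) -> int:
        """Number of distinct free parameters (each eq_label counts once)."""
        labels: set[str] = set()
        count = 0
        for e in self.entries:
            if not e.free:
                continue
            if e.eq_label is None:
                count += 1
            elif e.eq_label not in labels:
                labels.add(e.eq_label)
                count += 1
        return count

    def ar_pairs(self) -> tuple[tuple[str, str], ...]:
        """(source, target) item-name pairs of the AR entries."""
        names = self.layout.names
        return tuple((names[e.col], names[e.row]) for e in self.select(AR))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _ic_entries(layout: ItemLayout) -> list[ParameterEntry]:
    entries: list[ParameterEntry] = []
    for it in layout.items:
        i = layout.index(it.name)
        f = layout.trait_index(it.trait)
        entries.append(ParameterEntry(LOADING, i, f, start=0.7))
    # factor variances fixed at 1; covariances free
    for f in range(layout.m):
        entries.append(ParameterEntry(FACTOR_COV, f, f, status=FIXED, fixed_value=1.0))
    for f in range(layout.m):
        for g in range(f):
            entries.append(ParameterEntry(FACTOR_COV, f, g, start=0.2))
    for i in range(layout.p):
        entries.append(ParameterEntry(RESIDUAL_VAR, i, i, start=0.5))
    return entries


def build_ic_cfa(layout: ItemLayout) -> ModelSpec:
    """Independent-clusters CFA: one loading per item, free factor
    correlations, diagonal residual covariance, no AR terms."""
    return ModelSpec(layout=layout, entries=tuple(_ic_entries(layout)), name="ic_cfa")


def _ar_pairs(layout: ItemLayout, topology: str) -> list[tuple[int, int]]:
    """(row, col) = (target, source) item indices of the AR entries."""
    if topology not in ("adjacent", "adjacent_plus_construct"):
        raise ValueError(f"unknown topology {topology!r}")
    pairs: list[tuple[int, int]] = [(i, i - 1) for i in range(1, layout.p)]
    if topology == "adjacent_plus_construct":
        existing = set(pairs)
        for trait in layout.traits:
            ordered = layout.trait_items(trait)
            for prev, cur in zip(ordered, ordered[1:]):
                pair = (layout.index(cur.name), layout.index(prev.name))
                if pair not in existing:  # blocked layouts: already adjacent
                    pairs.append(pair)
                    existing.add(pair)
    return sorted(pairs)


def build_ar_cfa(layout: ItemLayout, topology: str = "adjacent_plus_construct") -> ModelSpec:
    """IC-CFA plus autoregressive terms among item residuals.

    ``topology="adjacent"`` links each consecutively administered pair
    (p - 1 terms).  ``topology="adjacent_plus_construct"`` additionally
    links each item to the previous item of the same trait, skipping
    pairs that are already adjacent.
    """
    entries = _ic_entries(layout)
    for row, col in _ar_pairs(layout, topology):
        entries.append(ParameterEntry(AR, row, col, start=0.0))
    return ModelSpec(layout=layout, entries=tuple(entries), name=f"ar_cfa[{topology}]")


def build_rc_cfa(ar_spec: ModelSpec) -> ModelSpec:
    """Reparameterize every AR term of a spec as a free residual covariance.

    The result has exactly the same free-parameter count and hence the
    same degrees of freedom, but no indirect (fading) effects: each
    former AR path becomes one correlated residual.
    """
    entries: list[ParameterEntry] = []
    for e in ar_spec.entries:
        if e.matrix == AR:
            entries.append(replace(e, matrix=RESIDUAL_COV))
        else:
            entries.append(e)
    return ModelSpec(layout=ar_spec.layout, entries=tuple(entries), name="rc_cfa")


# ---------------------------------------------------------------------------
# Equality constraints on AR terms
# ---------------------------------------------------------------------------

def _exempt(spec: ModelSpec, entry: ParameterEntry) -> bool:
    """First-cycle terms whose target item has no within-trait predecessor.

    Such targets receive only a between-construct effect, so their AR term
    is not comparable to later terms of the same type and stays free.
    """
    layout = spec.layout
    target = layout.items[entry.row]
    return all(it.position >= target.position for it in layout.trait_items(target.trait))


def apply_equality_constraints(spec: ModelSpec, scheme: str) -> ModelSpec:
    """Pool AR terms via equality constraints.

    ``scheme="by_type"`` shares one parameter per (source trait -> target
    trait) group.  ``scheme="by_type_and_scoring"`` splits each type group
    into a similar-scoring cell (normal->normal pooled with
    reversed->reversed) and a different-scoring cell (normal->reversed
    pooled with reversed->normal).  Terms whose target has no within-trait
    predecessor are exempt and stay free.
    """
    if scheme not in ("by_type", "by_type_and_scoring"):
        raise ValueError(f"unknown constraint scheme {scheme!r}")
    if not spec.select(AR):
        raise ValueError("constraint scheme requires a spec with ar entries")
    layout = spec.layout
    entries: list[ParameterEntry] = []
    for e in spec.entries:
        if e.matrix != AR or _exempt(spec, e):
            entries.append(e)
            continue
        src, tgt = layout.items[e.col], layout.items[e.row]
        label = f"{src.trait}->{tgt.trait}"
        if scheme == "by_type_and_scoring":
            cell = "similar" if src.scoring == tgt.scoring else "different"
            label = f"{label}|{cell}"
        entries.append(replace(e, eq_label=label))
    return ModelSpec(layout=layout, entries=tuple(entries), name=f"{spec.name}+{scheme}")


def model_df(spec: ModelSpec) -> int:
    """Degrees of freedom: p(p+1)/2 sample moments minus distinct free
    parameters.  Raises on over-parameterized (negative-df) specs."""
    p = spec.layout.p
    df = p * (p + 1) // 2 - spec.n_free_distinct
    if df < 0:
        raise ValueError(f"over-parameterized spec: df = {df}")
    return df


def ar_entries_by_group(spec: ModelSpec) -> dict[str, list[ParameterEntry]]:
    """AR entries grouped by (source trait -> target trait) type, useful
    for building averages of similar effects."""
    groups: dict[str, list[ParameterEntry]] = {}
    layout = spec.layout
    for e in spec.select(AR):
        key = f"{layout.items[e.col].trait}->{layout.items[e.row].trait}"
        groups.setdefault(key, []).append(e)
    return groups


def assert_nested(restricted: ModelSpec, full: ModelSpec) -> None:
    """Structural nesting check: same layout; every free cell of the
    restricted spec is free in the full spec; df_restricted >= df_full."""
    if restricted.layout.names != full.layout.names:
        raise ValueError("specs are not on the same layout")
    full_free = {(e.matrix, e.row, e.col) for e in full.entries if e.free}
    for e in restricted.entries:
        if e.free and (e.matrix, e.row, e.col) not in full_free:
            raise ValueError(
                f"not nested: restricted frees {(e.matrix, e.row, e.col)} which the full spec does not"
            )
    if model_df(restricted) < model_df(full):
        raise ValueError("not nested: restricted spec has fewer df than the full spec")
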