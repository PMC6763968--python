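"""Model-implied covariance structure and AR path effects.

The covariance structure of the AR-CFA is

    Sigma = Lambda Psi Lambda' + (I - kappa)^-1 Theta (I - kappa)'^-1

where Lambda holds factor loadings, Psi the factor covariances, kappa the
strictly lower-triangular (in administration order) matrix of
autoregressive effects among item residuals, and Theta the covariance of
the innovations u.  Because kappa is strictly triangular, (I - kappa) is
unit triangular, its inverse exists for any kappa, and entry (r, c) of the
inverse is the sum over all directed AR paths from item c to item r of the
product of the kappa coefficients along the path — the "propagator" that
makes context effects fade multiplicatively with distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .model import (
    AR,
    FACTOR_COV,
    LOADING,
    RESIDUAL_COV,
    RESIDUAL_VAR,
    ModelSpec,
    ParameterEntry,
)

__all__ = [
    "ParameterIndex",
    "ImpliedMoments",
    "ar_propagator",
    "materialize",
    "implied_covariance",
    "path_effect",
]


@dataclass(frozen=True)
class ParameterIndex:
    """Mapping between a ModelSpec and its free-parameter vector theta.

    Distinct free parameters occupy one slot each; entries sharing an
    eq_label share a slot.  Slot order is the entry order of the spec.
    """

    spec: ModelSpec
    slot_of_entry: tuple[int, ...]  # -1 for fixed entries
    labels: tuple[str, ...]  # human-readable slot names
    kinds: tuple[str, ...]  # matrix kind of each slot

    @classmethod
    def for_spec(cls, spec: ModelSpec) -> "ParameterIndex":
        names = spec.layout.names
        traits = spec.layout.traits
        slot_of_entry: list[int] = []
        labels: list[str] = []
        kinds: list[str] = []
        label_slot: dict[str, int] = {}
        for e in spec.entries:
            if not e.free:
                slot_of_entry.append(-1)
                continue
            if e.eq_label is not None and e.eq_label in label_slot:
                slot_of_entry.append(label_slot[e.eq_label])
                continue
            slot = len(labels)
            if e.eq_label is not None:
                label_slot[e.eq_label] = slot
                labels.append(f"kappa[{e.eq_label}]" if e.matrix == AR else e.eq_label)
            elif e.matrix == LOADING:
                labels.append(f"lambda[{names[e.row]}~{traits[e.col]}]")
            elif e.matrix == FACTOR_COV:
                labels.append(f"psi[{traits[e.row]},{traits[e.col]}]")
            elif e.matrix == AR:
                labels.append(f"kappa[{names[e.col]}->{names[e.row]}]")
            elif e.matrix == RESIDUAL_VAR:
                labels.append(f"theta[{names[e.row]}]")
            else:
                labels.append(f"theta[{names[e.row]},{names[e.col]}]")
            kinds.append(e.matrix)
            slot_of_entry.append(slot)
        return cls(
            spec=spec,
            slot_of_entry=tuple(slot_of_entry),
            labels=tuple(labels),
            kinds=tuple(kinds),
        )

    @property
    def n_free(self) -> int:
        return len(self.labels)

    def slot(self, matrix: str, row: int, col: int) -> int:
        """Slot index of the entry at (matrix, row, col)."""
        for e, s in zip(self.spec.entries, self.slot_of_entry):
            if (e.matrix, e.row, e.col) == (matrix, row, col):
                if s < 0:
                    raise KeyError(f"entry {(matrix, row, col)} is fixed")
                return s
        raise KeyError(f"no entry at {(matrix, row, col)}")

    def ar_slot(self, source: str, target: str) -> int:
        layout = self.spec.layout
        return self.slot(AR, layout.index(target), layout.index(source))


@dataclass(frozen=True)
class ImpliedMoments:
    """Implied covariance matrix and AR propagator at one parameter point."""

    sigma: np.ndarray
    propagator: np.ndarray


def ar_propagator(kappa: np.ndarray) -> np.ndarray:
    """(I - kappa)^-1 for strictly lower-triangular kappa.

    Computed by forward substitution on the unit-triangular system rather
    than generic inversion; rejects non-strictly-triangular input, which
    would imply feedback loops in administration time.
    """
    kappa = np.asarray(kappa, dtype=float)
    p = kappa.shape[0]
    if kappa.shape != (p, p) or np.any(np.triu(kappa) != 0.0):
        raise ValueError("kappa must be square and strictly lower triangular")
    return solve_triangular(np.eye(p) - kappa, np.eye(p), lower=True, unit_diagonal=True)


def materialize(
    index: ParameterIndex, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (Lambda, Psi, kappa, Theta) from a free-parameter vector."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (index.n_free,):
        raise ValueError(f"theta must have length {index.n_free}, got {theta.shape}")
    spec = index.spec
    p, m = spec.layout.p, spec.layout.m
    lam = np.zeros((p, m))
    psi = np.zeros((m, m))
    kappa = np.zeros((p, p))
    theta_mat = np.zeros((p, p))
    for e, slot in zip(spec.entries, index.slot_of_entry):
        value = e.fixed_value if slot < 0 else theta[slot]
        if e.matrix == LOADING:
            lam[e.row, e.col] = value
        elif e.matrix == FACTOR_COV:
            psi[e.row, e.col] = value
            psi[e.col, e.row] = value
        elif e.matrix == AR:
            kappa[e.row, e.col] = value
        elif e.matrix == RESIDUAL_VAR:
            theta_mat[e.row, e.row] = value
        else:
            theta_mat[e.row, e.col] = value
            theta_mat[e.col, e.row] = value
    return lam, psi, kappa, theta_mat


def implied_covariance(spec_or_index: ModelSpec | ParameterIndex, theta: np.ndarray) -> ImpliedMoments:
    """Sigma(theta) = Lambda Psi Lambda' + G Theta G' with G = (I-kappa)^-1.

    Symmetric exactly by construction (the two summands are built as
    A A'-style products of symmetric factors, then the average with the
    transpose removes the last-bit float asymmetry).
    """
    index = spec_or_index if isinstance(spec_or_index, ParameterIndex) else ParameterIndex.for_spec(spec_or_index)
    lam, psi, kappa, theta_mat = materialize(index, theta)
    g = ar_propagator(kappa)
    common = lam @ psi @ lam.T + g @ theta_mat @ g.T
    sigma = (common + common.T) / 2.0
    return ImpliedMoments(sigma=sigma, propagator=g)


def path_effect(index: ParameterIndex, theta: np.ndarray, chain: list[str]) -> float:
    """Indirect context effect along a chain of items: the product of the
    AR coefficients on consecutive links.  Raises if any link is not an
    AR entry of the spec."""
    if len(chain) < 2:
        raise ValueError("a chain needs at least two items")
    theta = np.asarray(theta, dtype=float)
    effect = 1.0
    for src, tgt in zip(chain, chain[1:]):
        try:
            slot = index.ar_slot(src, tgt)
            effect *= theta[slot]
        except KeyError:
            # fixed ar entries still contribute their fixed value
            layout = index.spec.layout
            for e, s in zip(index.spec.entries, index.slot_of_entry):
                if e.matrix == AR and e.row == layout.index(tgt) and e.col == layout.index(src):
                    effect *= e.fixed_value
                    break
            else:
                raise KeyError(f"no ar link {src} -> {tgt} in the spec") from None
    return effect
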