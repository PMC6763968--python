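"""Sample moments: the observed covariance matrix fed to the estimator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SampleMoments"]


@dataclass(frozen=True)
class SampleMoments:
    """A p x p sample covariance matrix with variable names and sample size.

    Validated at construction: symmetry, positive definiteness, and
    N >= p + 1 (fewer cases cannot yield a nonsingular covariance).
    """

    S: np.ndarray
    names: tuple[str, ...]
    n: int

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        p = len(self.names)
        if S.shape != (p, p):
            raise ValueError(f"S must be {p}x{p} to match names, got {S.shape}")
        if not np.allclose(S, S.T, atol=1e-9):
            raise ValueError("S must be symmetric")
        S = (S + S.T) / 2.0
        eigmin = float(np.linalg.eigvalsh(S)[0])
        if eigmin <= 0.0:
            raise ValueError(f"S must be positive definite; smallest eigenvalue {eigmin:.3e}")
        if self.n < p + 1:
            raise ValueError(f"sample size N={self.n} too small for p={p} variables")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def p(self) -> int:
        return len(self.names)

    @property
    def smallest_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.S)[0])

    def reorder(self, names: tuple[str, ...] | list[str]) -> "SampleMoments":
        """Return the moments with variables permuted to ``names`` order."""
        missing = set(names) - set(self.names)
        if missing:
            raise ValueError(f"variables not present in moments: {sorted(missing)}")
        idx = [self.names.index(nm) for nm in names]
        return SampleMoments(S=self.S[np.ix_(idx, idx)], names=tuple(names), n=self.n)

    def sds(self) -> np.ndarray:
        return np.sqrt(np.diag(self.S))

    def correlations(self) -> np.ndarray:
        d = 1.0 / self.sds()
        return self.S * np.outer(d, d)
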