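"""Substitution model and the ungapped scale parameter lambda_u.

A scoring matrix s_ij together with background frequencies P defines target
(joint) frequencies q_ij = P_i P_j exp(lambda_u * s_ij), where lambda_u is
the unique positive root of

    g(lambda) = sum_ij P_i P_j exp(lambda * s_ij) - 1 = 0.

g(0) = 0, g'(0) = E[s] < 0 for a sensible matrix, and g is convex, so a
single positive root exists whenever some score is positive.  The root is
found by Newton-Raphson with a bisection safeguard.  lambda_u converts
matrix scores into the target frequencies used for pseudocounts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alignment import AA_ALPHABET

#: Robinson & Robinson (1991) amino-acid frequencies, the NCBI BLAST
#: background for BLOSUM62, in AA_ALPHABET (matrix) order.
ROBINSON_BACKGROUND = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


class NoPositiveRootError(ValueError):
    """The constraint equation has no positive root (E[s] >= 0 or all s <= 0)."""


class LambdaConvergenceError(RuntimeError):
    """Root refinement failed to reach tolerance."""


@dataclass(frozen=True)
class SubstitutionModel:
    """Symmetric score matrix + background frequencies over an alphabet.

    `lambda_u` is None until solved (see :func:`solve_lambda_u`); use
    :meth:`with_lambda` to obtain a solved copy.
    """

    alphabet: str
    scores: np.ndarray            # (k, k) symmetric
    background: np.ndarray        # (k,) positive, sums to 1
    lambda_u: float | None = None

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        s = np.asarray(self.scores, dtype=float)
        p = np.asarray(self.background, dtype=float)
        if s.shape != (k, k):
            raise ValueError(f"scores must be {k}x{k}, got {s.shape}")
        if not np.allclose(s, s.T):
            raise ValueError("score matrix must be symmetric")
        if p.shape != (k,):
            raise ValueError(f"background must have length {k}")
        if (p <= 0).any():
            raise ValueError("background frequencies must be positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("background frequencies must sum to 1")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "background", p / p.sum())

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def expected_score(self) -> float:
        p = self.background
        return float(p @ self.scores @ p)

    def constraint_residual(self, lam: float) -> float:
        """g(lam) = sum_ij P_i P_j exp(lam s_ij) - 1."""
        p = self.background
        return float(p @ np.exp(lam * self.scores) @ p - 1.0)

    def with_lambda(self, **kwargs) -> "SubstitutionModel":
        return replace(self, lambda_u=solve_lambda_u(self, **kwargs))

    def target_frequencies(self) -> np.ndarray:
        """Joint target frequencies q_ij = P_i P_j exp(lambda_u s_ij)."""
        if self.lambda_u is None:
            raise ValueError("lambda_u not solved; call with_lambda() first")
        p = self.background
        return np.exp(self.lambda_u * self.scores) * np.outer(p, p)

    @classmethod
    def blosum62(cls) -> "SubstitutionModel":
        """BLOSUM62 over the 20 standard residues with the BLAST background."""
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        idx = [m.alphabet.index(a) for a in AA_ALPHABET]
        s = np.asarray(m)[np.ix_(idx, idx)]
        p = np.array([ROBINSON_BACKGROUND[a] for a in AA_ALPHABET])
        return cls(alphabet=AA_ALPHABET, scores=s, background=p / p.sum())


def solve_lambda_u(
    model: SubstitutionModel,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Unique positive root of the ungapped constraint, by safeguarded Newton.

    Raises :class:`NoPositiveRootError` when the expected score under the
    background is non-negative or no score is positive (g then never
    returns to zero on the positive axis).
    """
    if model.expected_score() >= 0:
        raise NoPositiveRootError("expected score under background is >= 0")
    if not (model.scores > 0).any():
        raise NoPositiveRootError("all scores non-positive: g is decreasing")

    p = model.background
    s = model.scores
    pp = np.outer(p, p)

    def g(lam: float) -> float:
        return float((pp * np.exp(lam * s)).sum() - 1.0)

    def dg(lam: float) -> float:
        return float((pp * s * np.exp(lam * s)).sum())

    # bracket: g < 0 just right of 0, g -> +inf as lam grows
    lo = 1e-8
    hi = 0.5
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise NoPositiveRootError("failed to bracket a positive root")

    lam = hi / 2.0
    for _ in range(max_iter):
        val = g(lam)
        if abs(val) <= tol:
            return lam
        if val < 0:
            lo = lam
        else:
            hi = lam
        deriv = dg(lam)
        step_ok = deriv > 0
        if step_ok:
            nxt = lam - val / deriv
            step_ok = lo < nxt < hi
        lam = nxt if step_ok else 0.5 * (lo + hi)  # bisection fallback
    if abs(g(lam)) <= 1e-9:
        return lam
    raise LambdaConvergenceError(f"no convergence after {max_iter} iterations")
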