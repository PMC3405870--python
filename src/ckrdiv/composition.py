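"""Site-specific amino-acid composition of one sequence group.

The composition p(i) of a group at an alignment column is estimated the way
PSI-BLAST builds profile columns:

1. sequences are weighted by the Henikoff & Henikoff position-based scheme
   (each column contributes 1/(r*m) to a sequence showing a letter shared
   by m sequences, r being the number of distinct letters in the column);
2. observed frequencies f are the weighted residue counts, renormalized
   over the non-gap mass;
3. f is mixed with data-dependent pseudocount frequencies
   g_i = sum_j (f_j / P_j) q_ij   (q_ij the lambda_u target frequencies)
   as q_reg = (alpha f + beta g) / (alpha + beta), with alpha = n_distinct-1
   (the column's independent-observation count) and pseudocount weight
   beta = 0.1 by default.

With beta > 0 the regularized composition is strictly positive, so the
Kullback-Leibler information between two groups is always finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import GAP, AA_INDEX
from .substitution import SubstitutionModel

DEFAULT_BETA = 0.1


class EmptyGroupError(ValueError):
    """A group has no sequences, or no residue mass where one is required."""


@dataclass(frozen=True)
class SiteComposition:
    """Observed and regularized composition of one group at one column."""

    f: np.ndarray            # weighted observed frequencies (sum 1)
    n_distinct: int          # distinct residue letters in the column
    q_reg: np.ndarray        # pseudocount-regularized composition (sum 1)


def henikoff_weights(rows) -> np.ndarray:
    """Position-based sequence weights for one group, normalized to sum 1.

    Gap positions contribute nothing; an all-gap sequence gets weight 0 and
    the remaining weights are renormalized.
    """
    rows = list(rows)
    if not rows:
        raise EmptyGroupError("cannot weight an empty group")
    if isinstance(rows[0], str):
        lut = np.full(128, -1, dtype=np.int8)
        for a, i in AA_INDEX.items():
            lut[ord(a)] = i
        enc = lut[np.frombuffer("".join(rows).encode(), np.uint8)].reshape(len(rows), -1)
    else:
        enc = np.asarray(rows)
    n, L = enc.shape
    w = np.zeros(n)
    for c in range(L):
        col = enc[:, c]
        nongap = col >= 0
        if not nongap.any():
            continue
        counts = np.bincount(col[nongap], minlength=20)
        r = int((counts > 0).sum())
        # each occurrence of letter a adds 1/(r * m_a)
        w[nongap] += 1.0 / (r * counts[col[nongap]])
    total = w.sum()
    if total == 0:
        raise EmptyGroupError("all sequences in the group are entirely gaps")
    return w / total


def weighted_frequencies(column, weights: np.ndarray, k: int = 20):
    """Weighted residue frequencies at one column.

    `column` is a string (letters + '-') or an integer-encoded vector with
    gaps as -1.  Returns (f, n_distinct); f sums to 1 over the non-gap
    mass.  A fully gapped column returns (None, 0) — the "empty" flag.
    """
    if isinstance(column, str):
        col = np.array([AA_INDEX.get(ch, -1) if ch != GAP else -1 for ch in column])
    else:
        col = np.asarray(column)
    weights = np.asarray(weights, dtype=float)
    if col.shape != weights.shape:
        raise ValueError("column and weight vector lengths differ")
    nongap = col >= 0
    if not nongap.any():
        return None, 0
    f = np.bincount(col[nongap], weights=weights[nongap], minlength=k).astype(float)
    mass = f.sum()
    if mass == 0:
        # non-gap letters present but all carried by zero-weight sequences
        return None, 0
    n_distinct = int((np.bincount(col[nongap], minlength=k) > 0).sum())
    return f / mass, n_distinct


def pseudocount_composition(
    f: np.ndarray,
    n_distinct: int,
    model: SubstitutionModel,
    beta: float = DEFAULT_BETA,
) -> np.ndarray:
    """PSI-BLAST-style regularized composition q_reg of one column.

    alpha = n_distinct - 1; the pseudocount vector is
    g_i = sum_j (f_j / P_j) q_ij = P_i * (exp(lambda_u s) f)_i.
    When alpha = 0 (single residue type) the mixture reduces to g alone;
    with beta = 0 and positive f the observed frequencies are returned
    unchanged (zeros in f then survive into q_reg).
    """
    if f is None:
        raise EmptyGroupError("no residue mass at this column for the group")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    f = np.asarray(f, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("f must sum to 1")
    alpha = max(n_distinct - 1, 0)
    if beta == 0 and alpha == 0:
        return f.copy()
    if beta == 0:
        return f.copy()
    if model.lambda_u is None:
        raise ValueError("model.lambda_u not solved; call model.with_lambda() first")
    g = model.background * (np.exp(model.lambda_u * model.scores) @ f)
    g = g / g.sum()
    if alpha == 0:
        q = g
    else:
        q = (alpha * f + beta * g) / (alpha + beta)
    return q / q.sum()


def site_composition(
    column,
    weights: np.ndarray,
    model: SubstitutionModel,
    beta: float = DEFAULT_BETA,
) -> SiteComposition | None:
    """Full pipeline for one group at one column; None when fully gapped."""
    f, n_distinct = weighted_frequencies(column, weights, k=model.size)
    if f is None:
        return None
    q = pseudocount_composition(f, n_distinct, model, beta=beta)
    return SiteComposition(f=f, n_distinct=n_distinct, q_reg=q)
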