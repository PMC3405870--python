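"""Symmetric Kullback-Leibler site scoring and top-quantile site selection.

Each evaluable alignment column is scored by the symmetrized KL information

    D(p||q) + D(q||p) = sum_i p_i log(p_i/q_i) + sum_i q_i log(q_i/p_i)

between the two groups' regularized compositions p and q.  Plain KL is not
symmetric; the sum restores symmetry so the score does not depend on which
group is called first.  Columns where more than half of all sequences
(both groups pooled) are gapped are skipped.  The top-quantile columns
(default 5%) are selected, and selected columns falling in a reference-
sequence gap are then discarded — in that order, so the selected count can
fall below the quantile ceiling.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .alignment import GroupedAlignment, ReferenceColumnMap
from .composition import DEFAULT_BETA, henikoff_weights, site_composition
from .substitution import SubstitutionModel

SKIP_NONE = "none"
SKIP_GAP_MAJORITY = "gap_majority"
SKIP_EMPTY_GROUP = "empty_group"


class InfiniteDivergenceError(ValueError):
    """One distribution has mass where the other has exactly zero."""


def symmetric_kl(p, q, log_base: float | None = None, epsilon: float | None = None) -> float:
    """Symmetrized KL information between two proper distributions.

    Natural log by default; pass ``log_base=2`` for bits.  Mismatched zero
    entries make the divergence infinite — an error unless an
    ``epsilon`` floor is supplied (both vectors floored and renormalized).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} is not a proper distribution")
    if epsilon is not None:
        p = np.maximum(p, epsilon)
        q = np.maximum(q, epsilon)
        p = p / p.sum()
        q = q / q.sum()
    val = float(rel_entr(p, q).sum() + rel_entr(q, p).sum())
    if not np.isfinite(val):
        raise InfiniteDivergenceError(
            "zero entry opposite positive mass; use beta > 0 or an epsilon floor"
        )
    if log_base is not None:
        val /= math.log(log_base)
    return val


def score_all_sites(
    aln: GroupedAlignment,
    model: SubstitutionModel | None = None,
    beta: float = DEFAULT_BETA,
    gap_skip_fraction: float = 0.5,
    log_base: float | None = None,
    pooled_weights: bool = False,
) -> pd.DataFrame:
    """Score every column of a two-group alignment.

    Returns a DataFrame with columns ``column``, ``kl_value`` (NaN when
    skipped) and ``skip_reason``.  Henikoff weights are computed once per
    group over the whole alignment (or pooled over both groups with
    ``pooled_weights=True``); lambda_u is solved once per alignment.
    """
    labels = aln.group_labels
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, found {labels}")
    if model is None:
        model = SubstitutionModel.blosum62()
    if model.lambda_u is None:
        model = model.with_lambda()

    enc = aln.encoded()
    groups = np.array([aln.group_of[i] for i in aln.ids])
    enc_a = enc[groups == labels[0]]
    enc_b = enc[groups == labels[1]]
    if enc_a.size == 0 or enc_b.size == 0:
        raise ValueError("each group must contain at least one sequence")

    if pooled_weights:
        w_all = henikoff_weights(enc)
        w_a = w_all[groups == labels[0]]
        w_b = w_all[groups == labels[1]]
        w_a = w_a / w_a.sum()
        w_b = w_b / w_b.sum()
    else:
        w_a = henikoff_weights(enc_a)
        w_b = henikoff_weights(enc_b)

    n_total = aln.n_sequences
    records = []
    for c in range(aln.length):
        gap_frac = (enc[:, c] < 0).sum() / n_total
        if gap_frac > gap_skip_fraction:
            records.append((c, np.nan, SKIP_GAP_MAJORITY))
            continue
        comp_a = site_composition(enc_a[:, c], w_a, model, beta=beta)
        comp_b = site_composition(enc_b[:, c], w_b, model, beta=beta)
        if comp_a is None or comp_b is None:
            records.append((c, np.nan, SKIP_EMPTY_GROUP))
            continue
        kl = symmetric_kl(comp_a.q_reg, comp_b.q_reg, log_base=log_base)
        records.append((c, kl, SKIP_NONE))
    return pd.DataFrame(records, columns=["column", "kl_value", "skip_reason"])


def select_top_sites(
    scores: pd.DataFrame,
    quantile: float = 0.05,
    ref_map: ReferenceColumnMap | None = None,
) -> pd.DataFrame:
    """Mark the top-quantile columns; then drop reference-gapped selections.

    Evaluable columns are ranked by ``kl_value`` descending (ties broken by
    ascending column index) and the top ceil(quantile * n_evaluable) are
    marked.  Marked columns where the reference sequence is gapped are then
    unmarked, so the final count may fall below the ceiling.  Adds
    ``ref_residue`` (nullable Int64) and ``selected`` columns.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    out = scores.copy()
    evaluable = out[out["skip_reason"] == SKIP_NONE]
    n_top = math.ceil(quantile * len(evaluable))
    ranked = evaluable.sort_values(
        ["kl_value", "column"], ascending=[False, True], kind="mergesort"
    )
    chosen = set(ranked["column"].head(n_top))
    if ref_map is not None:
        out["ref_residue"] = pd.array(
            [ref_map.residue_of(int(c)) for c in out["column"]], dtype="Int64"
        )
        chosen -= set(ref_map.gapped_columns)
    else:
        out["ref_residue"] = pd.array([None] * len(out), dtype="Int64")
    out["selected"] = out["column"].isin(chosen)
    return out
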