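"""Two-sample location tests for spatial bias and pocket enrichment.

All tests reduce to the Welch unequal-variance t-test (the default of R's
``t.test``), with the Welch-Satterthwaite degrees of freedom.  The
projection-bias test compares axis scores of selected residues against the
remaining residues; the alternative ``less`` encodes "selected sites sit
further toward the intracellular side".  The pocket-enrichment test
compares, across comparisons, the per-comparison fraction of selected
sites that fall in the ligand-binding pocket, treating the fractions as
plain real samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .structure import ProjectionResult

ALTERNATIVES = ("two-sided", "less", "greater")


class DegenerateSampleError(ValueError):
    """Both samples have zero variance; the t statistic is undefined."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    alternative: str
    n1: int
    n2: int
    mean1: float
    mean2: float


def welch_t_test(x, y, alternative: str = "two-sided", equal_var: bool = False) -> TestResult:
    """Two-sample t-test, Welch by default (Student with ``equal_var=True``).

    ``less`` tests mean(x) < mean(y); ``greater`` the reverse.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least two observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateSampleError("both samples have zero variance")
    mx, my = x.mean(), y.mean()
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    else:
        a, b = vx / nx, vy / ny
        se = np.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (nx - 1) + b**2 / (ny - 1))
    t = (mx - my) / se
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif alternative == "less":
        p = sps.t.cdf(t, df)
    else:
        p = sps.t.sf(t, df)
    return TestResult(
        statistic=float(t), df=float(df), p_value=float(p),
        alternative=alternative, n1=nx, n2=ny, mean1=float(mx), mean2=float(my),
    )


def projection_bias_test(
    proj: ProjectionResult, alternative: str = "two-sided", equal_var: bool = False
) -> TestResult:
    """Compare axis scores of selected residues against the remaining ones.

    The null is equal mean axis position; ``alternative='less'`` asks
    whether the selected sites lie further intracellular (more negative).
    """
    sel = proj.selected_scores()
    rest = proj.remaining_scores()
    if len(sel) < 2:
        raise ValueError(
            f"only {len(sel)} selected residue(s) carry a projection score; "
            "at least 2 are needed — check the selected-site list against the "
            "structure's residue numbering"
        )
    if len(rest) < 2:
        raise ValueError("fewer than 2 remaining residues to compare against")
    return welch_t_test(sel, rest, alternative=alternative, equal_var=equal_var)


def pocket_enrichment_test(
    pocket_counts_a,
    totals_a,
    pocket_counts_b,
    totals_b,
    alternative: str = "less",
    equal_var: bool = False,
) -> TestResult:
    """t-test on per-comparison pocket-site fractions between two receptor classes.

    Each comparison contributes count/total, the fraction of its selected
    sites lying in the binding pocket; the two fraction samples are then
    compared by :func:`welch_t_test`.  ``less`` asks whether class A's
    fractions are smaller (fewer pocket sites) than class B's.
    """
    ca = np.asarray(pocket_counts_a, dtype=float)
    ta = np.asarray(totals_a, dtype=float)
    cb = np.asarray(pocket_counts_b, dtype=float)
    tb = np.asarray(totals_b, dtype=float)
    if ca.shape != ta.shape or cb.shape != tb.shape:
        raise ValueError("counts and totals must align per comparison")
    if (ta <= 0).any() or (tb <= 0).any():
        raise ValueError("every comparison must have a positive total site count")
    if (ca > ta).any() or (cb > tb).any():
        raise ValueError("pocket counts cannot exceed totals")
    if len(ca) < 2 or len(cb) < 2:
        raise ValueError("need at least two comparisons per side")
    return welch_t_test(ca / ta, cb / tb, alternative=alternative, equal_var=equal_var)
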