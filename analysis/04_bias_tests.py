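#!/usr/bin/env python
"""Test the selected sites for intracellular spatial bias.

Welch t-tests compare the axis scores of selected residues against the
remaining residues: the two-sided test asks for any location difference,
the one-sided ('less') test specifically for an intracellular shift of the
selected sites.
"""

import argparse
from pathlib import Path

import pandas as pd

import ckrdiv as ck
from ckrdiv.structure import ProjectionResult


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = pd.read_csv(args.outdir / "projections.tsv", sep="\t")
    proj = ProjectionResult(
        score_of=dict(zip(table["residue"], table["axis_score"]))
    ).with_selected(table.loc[table["selected"], "residue"])

    rows = []
    for alternative in ("two-sided", "less"):
        r = ck.projection_bias_test(proj, alternative)
        rows.append(
            {
                "alternative": alternative,
                "t": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
                "mean_selected": r.mean1,
                "mean_remaining": r.mean2,
                "n_selected": r.n1,
                "n_remaining": r.n2,
            }
        )
        print(f"{alternative:>10}: t={r.statistic:+.3f}, df={r.df:.1f}, p={r.p_value:.3g}")
    out = pd.DataFrame(rows)
    out.to_csv(args.outdir / "bias_tests.tsv", sep="\t", index=False)
    if rows[1]["p_value"] < 0.05:
        print("selected sites are significantly biased toward the intracellular side")
    else:
        print("no significant intracellular bias of the selected sites")


if __name__ == "__main__":
    main()
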