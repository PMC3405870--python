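#!/usr/bin/env python
"""Project residues onto the extracellular<->intracellular axis.

Builds the axis from the loop geometric centers of the toy receptor,
projects every non-excluded residue, marks the residues matching the
selected sites, and plots the projected positions (selected vs remaining)
in the style of a sidedness diagram.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import ckrdiv as ck


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    (args.outdir / "figures").mkdir(parents=True, exist_ok=True)

    model = ck.read_structure(args.datadir / "toy_receptor.pdb", "A")
    cfg = ck.RegionConfig.from_yaml(args.datadir / "toy_regions.yaml")
    axis = ck.compute_axis(model, cfg)
    proj = ck.project_residues(model, axis, cfg)

    selected_sites = pd.read_csv(args.outdir / "selected_sites.tsv", sep="\t")
    selected_residues = selected_sites["ref_residue"].dropna().astype(int).tolist()
    proj = proj.with_selected(selected_residues)

    rows = [
        {
            "residue": r,
            "region": cfg.region_of(r),
            "axis_score": s,
            "selected": r in proj.selected,
        }
        for r, s in sorted(proj.score_of.items())
    ]
    out = pd.DataFrame(rows)
    out.to_csv(args.outdir / "projections.tsv", sep="\t", index=False)

    d_tm = ck.tm_center_distance(model, axis, cfg)
    print(f"projected {len(out)} residues; axis midpoint to TM centroid: {d_tm:.3f} A")
    sel = out[out["selected"]]
    rem = out[~out["selected"]]
    print(f"selected residues: n={len(sel)}, mean axis score {sel.axis_score.mean():+.2f} A")
    print(f"remaining residues: n={len(rem)}, mean axis score {rem.axis_score.mean():+.2f} A")

    fig, ax = plt.subplots(figsize=(3, 6))
    ax.hlines(rem["axis_score"], -0.45, -0.05, color="0.6", lw=0.6)
    ax.hlines(sel["axis_score"], 0.05, 0.45, color="crimson", lw=1.2)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks([-0.25, 0.25], ["remaining", "selected"])
    ax.set_ylabel("axis position (A, + = extracellular)")
    ax.set_xlim(-0.6, 0.6)
    fig.tight_layout()
    fig.savefig(args.outdir / "figures" / "axis_projection.png", dpi=150)
    print(f"figure: {args.outdir}/figures/axis_projection.png")


if __name__ == "__main__":
    main()
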