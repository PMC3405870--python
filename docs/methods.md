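# Methods

## The model

The pipeline asks, for two groups of aligned homologous receptor
sequences, at which alignment positions the groups prefer different amino
acids, and where those positions sit on the receptor's tertiary
structure. The per-site statistic is the symmetrized Kullback–Leibler
information

    KL(p, q) = Σ_i p(i) ln p(i)/q(i) + Σ_i q(i) ln q(i)/p(i),

summed over the 20 standard amino acids, between the two groups'
site-specific compositions. Plain relative entropy is asymmetric; the
symmetrized form makes the score independent of group order. This is the
two-group special case of cumulative relative entropy over multiple
groups; the multi-group generalization is deliberately out of scope.
A large value at a column means the groups conserve different residues
there — the signature of a changed functional constraint, i.e. a changed
intolerance to mutation.

## Composition estimation

Observed counts at a column are unreliable for groups of 10–100
homologous sequences (phylogenetic redundancy, sampling zeros), so each
group's composition is estimated the way PSI-BLAST builds profile
columns:

* **Sequence weights.** Henikoff & Henikoff position-based weights per
  group: at a column with `r` distinct non-gap letters, a sequence
  carrying a letter shared by `m` group members receives `1/(r·m)`;
  per-sequence totals are normalized to sum 1. Weights are computed once
  per group over all columns (whether to pool both groups is a config
  switch, `pooled_weights`; per-group is the default since each group's
  composition is defined per group). Columns later skipped by the gap
  rule are *not* excluded from the weight computation — the weights
  describe sequence redundancy, which gap-heavy columns still inform.

* **Observed frequencies.** `f_i` = weighted count of residue `i`,
  renormalized over the non-gap mass. Gaps contribute nothing (the KL
  sum runs over 20 residues only); `X` and other non-standard letters
  are normalized to gaps on input, keeping compositions proper
  distributions over exactly 20 categories.

* **Pseudocounts.** `q_reg = (α f + β g) / (α + β)` with
  `α = n_distinct − 1` (the column's independent-observation count;
  a single-residue column, α = 0, falls back to the pure pseudocount
  vector) and `β = 0.1`. The data-dependent pseudocount is
  `g_i = Σ_j (f_j / P_j) q_ij` with target frequencies
  `q_ij = P_i P_j exp(λ_u s_ij)`. Defaults: BLOSUM62 scores with the
  Robinson & Robinson background frequencies used by NCBI BLAST; matrix,
  background, α rule and β are all arguments.

* **λ_u.** The ungapped scale is the unique positive root of
  `Σ_ij P_i P_j e^{λ s_ij} = 1`, solved once per comparison alignment by
  Newton–Raphson bracketed with bisection (residual ≤ 1e-9; the toy
  two-letter matrix [[1,−2],[−2,1]] at uniform background has the closed
  form λ = ln((1+√5)/2), used as an oracle in the tests). Note the
  constraint fixes the double sum, not each row sum, so the identity
  "f = background ⇒ g = background" is exact only for matrices that are
  exact log-odds of a joint distribution; for integer-rounded BLOSUM62
  it holds to ~5e-3.

With β > 0 both regularized compositions are strictly positive and the
KL value is always finite. β = 0 is permitted; mismatched zeros then
raise, unless an explicit ε-floor is requested in `symmetric_kl`.

## Skipping, selection, reference mapping

Columns where more than half of all sequences (both groups pooled,
unweighted) are gapped are skipped. A column at most half-gapped overall
but entirely gapped *within one group* has no defined composition for
that group; it is skipped with its own reason (`empty_group`) rather
than raising, since skewed gap placement is legitimate in real
alignments.

Evaluable columns are ranked by KL value (ties broken by ascending
column index, for deterministic output) and the top
`ceil(0.05 × n_evaluable)` are marked. Marked columns falling in a gap
of the reference (structure-bearing) sequence are *then* unmarked — the
exclusion happens after ranking, so the final count may fall below the
ceiling. The 5% quantile is interpreted over evaluable columns (skipped
columns have no value to rank) and the ceiling convention is a
documented choice; natural log is the default base (base 2 available).
All user-facing output reports reference residue numbers (PDB author
numbering via a configurable offset); columns are 0-based internally.

## Structural projection

The reference structure is reduced to one Cα per residue (first altloc
kept, HETATM/waters ignored, insertion codes rejected). Topology is a
config, not code: inclusive residue intervals for N, TM1–7, ECL1–3,
ICL1–3 and C, plus excluded intervals (e.g. a fused T4-lysozyme insert)
and a C-terminal interval. The extracellular center is the unweighted
Cα mean over ECL1–3 + N; the intracellular center over ICL1–3, with the
C-terminal tail (which extends into the cytosol rather than capping the
helix bundle) and excluded inserts removed from the center computation
only. The axis unit vector points from the midpoint toward the
extracellular center; each residue's score is
`u · (Cα − midpoint)` (Å, positive = extracellular). C-terminal
residues are still projected; excluded-insert residues are not.

The packaged CXCR4/3ODU chain-A region config documents its boundary
provenance inline (GPCRDB-style structural elements reconciled with
Ballesteros–Weinstein anchors). Boundary hand-offs between helices and
loops are not uniquely defined in the literature, so quantities derived
from the real structure (e.g. the midpoint-to-TM-centroid distance)
carry a boundary-choice tolerance of a few tenths of an Å. The 3ODU
coordinates themselves are not distributed with the package and must be
fetched from the PDB; all geometry tests run on the synthetic bundle.

## Statistics

All tests are two-sample t-tests on plain real samples, Welch
(unequal-variance, Welch–Satterthwaite df) by default — matching the
default of R's `t.test` — with pooled-variance Student as an option.
The implementation is written out (statistic, df, tail probabilities
from the t distribution) and cross-checked in the tests against an
independent reference implementation to 1e-10, rather than delegating to
it. No multiple-testing correction is applied, deliberately.

* **Projection bias:** selected residues' axis scores vs. all remaining
  projected residues; `less` encodes "selected sites sit further
  intracellular".
* **Pocket enrichment:** per-comparison ratios (pocket sites / selected
  sites) compared across the two receptor classes as plain samples; a
  binomial model is out of scope. With the published counts
  (2,2,0,1,1 of 14,13,11,14,14 decoy vs. 3,2,5,3,4 of 9,13,14,11,14
  viral) the one-sided Welch p-value is 1.5 × 10⁻³; the published
  per-group totals are not printed outright and the E1 list length is
  ambiguous (9 rows against a stated "about 11∼14"), so this quantity
  is order-of-magnitude reproducible, not digit-exact (the printed
  value is 3.864 × 10⁻³; plausible totals give 1.4–2.8 × 10⁻³).

## Synthetic data

`generate_alignment` draws i.i.d. columns: a shared per-column
composition from a symmetric Dirichlet (concentration 0.5 — protein
columns are dominated by a few residues, and 0.5 gives realistic
low-entropy columns), identical in both groups except at planted
columns, where group B's composition is mixed with weight `divergence`
toward a uniform distribution on the 4 residues the shared composition
uses *least*. Moving mass to a (nearly) disjoint residue set makes KL
grow monotonically in the divergence knob, which the tests verify. Gaps
are injected i.i.d. per cell (default 5%); designated columns can be
forced above the 50% skip threshold. The reference sequence (first of
group A) receives no gaps: the structure anchor must cover every
detectable column — a planted site behind a reference gap would be
undetectable by construction, exactly as a planted site at a forced-gap
column is (both are rejected as invalid scenarios). Default sizes (40+40 sequences, 300
columns, 15 planted sites, divergence 0.9) are of the order of the real
comparisons (≈100–450 CKRs against 9–24 homologs over a ~350-residue
receptor alignment) while keeping every test and the acceptance script
in seconds.

What the generator does *not* emulate: phylogenetic correlation between
sequences (columns are i.i.d. and sequences are exchangeable within a
group), alignment error, and insertion-driven gap structure. Passing
recovery tests therefore demonstrate the scoring machinery, not
robustness to tree structure; on real data the Henikoff weights absorb
part (not all) of the phylogenetic redundancy.

`generate_structure` builds seven ideal helices (rise 1.5 Å/residue,
local Cα radius 2.3 Å, bundle radius 12 Å) alternating up/down through
a membrane slab, with GPCR topology N–TM1–ICL1–TM2–ECL1–…–TM7–C. Loop
and terminal residues sit on the bundle circle beyond the helix ends
(±(z_half + 2) Å), spread evenly around the axis so every region's xy
centroid vanishes: the loop-center midpoint then coincides with the TM
centroid *exactly*, making `tm_center_distance` a sensitive error
signal. Each helix's local spiral phase is offset by its bundle angle so
the seven spiral offsets cancel. The toy therefore reproduces sidedness
geometry, not real loop locality. Pocket residues default to the
extracellular half of the TM bundle.

## Numerical choices and degenerate inputs

* λ solver: bracket [1e-8, doubling], Newton step accepted only inside
  the bracket, else bisection; rejects matrices with non-negative
  expected score or no positive entry.
* Compositions renormalized after every mixing step; `q_reg` proper to
  1e-12.
* Selection ties at the quantile boundary: ascending column index.
* Degenerate t-test inputs (both variances zero, samples shorter
  than 2) raise typed errors instead of returning NaN.
* Coincident loop centers raise a degenerate-axis error.
* PDB round trips are exact to the format's 1e-3 Å precision.

## Problem sizes used in checks

Recovery checks use the default scenario (80 × 300) once at divergence
0.9 and over 50 seeds at divergence 0; type-I calibration uses 2000
replicates of fresh 210-score normal populations with 15-residue random
selections (fresh populations per replicate keep replicates independent;
reusing one population biases the empirical rate); monotone-recall uses
a 30 × 80 grid over three divergence levels × 20 replicates. These sizes
put the whole suite and the acceptance script within seconds on one
core while keeping Monte-Carlo errors well inside the asserted margins.
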