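# Topological regions of human CXCR4 on the 3ODU crystal structure, chain A
# (CXCR4 fused to T4 lysozyme; the lysozyme insert carries author residue
# numbers 1002-1161 and is excluded from all projection arithmetic).
#
# TM boundaries follow GPCRDB-style structural-element definitions for
# CXCR4, reconciled with Ballesteros-Weinstein anchors on the deposited
# numbering (N56 = 1.50, D84 = 2.50, R134 = 3.50, W161 = 4.50, P211 = 5.50,
# P254 = 6.50, P299 = 7.53 region).  Loop/helix hand-off points are not
# uniquely defined in the literature; these choices place the annotated
# loop residues (e.g. T73/D74 in ICL1, D133-S144 around the DRY motif in
# ICL2, C218-A237 in ICL3, Y190 in ECL2, K271/C274 in ECL3) in their
# conventional regions.
#
# The C-terminal range (303-328) extends into the cytosol and is excluded
# from the intracellular-center computation only (its residues are still
# projected onto the axis).
regions:
  N: [1, 41]
  TM1: [42, 65]
  ICL1: [66, 77]
  TM2: [78, 100]
  ECL1: [101, 111]
  TM3: [112, 132]
  ICL2: [133, 153]
  TM4: [154, 174]
  ECL2: [175, 195]
  TM5: [196, 217]
  ICL3: [218, 240]
  TM6: [241, 263]
  ECL3: [264, 280]
  TM7: [281, 302]
  C: [303, 328]
excluded_ranges:
  - [1002, 1161]   # T4 lysozyme fusion insert
cterm_range: [303, 328]
# Ligand-binding pocket membership (CASTp top pocket on CXCR4), as the
# residues flagged "Pocket" across the ten published comparisons.
pocket_residues: [31, 38, 94, 102, 112, 116, 120, 121, 123, 171, 190, 203, 207, 208, 248, 256]
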