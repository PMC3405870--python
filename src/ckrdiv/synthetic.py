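"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators make every pipeline stage testable without downloads:

* :func:`generate_alignment` draws a two-group alignment whose columns are
  i.i.d. categorical samples from per-column compositions.  Unplanted
  columns share one composition between the groups; at planted columns the
  second group's composition is pulled toward residues the shared
  composition barely uses, so the symmetric KL information grows
  monotonically with the ``divergence`` knob and the planted set is the
  ground truth for recovery measurements.

* :func:`generate_structure` builds a parametric seven-helix bundle with
  GPCR topology: helices span z in [-z_half, +z_half] on a circle,
  extracellular regions (N-terminus, ECL1-3) sit above the membrane slab
  (z > 0), intracellular regions (ICL1-3, C-terminus) below.  Loop
  residues are spread evenly around the bundle axis, which keeps the toy
  exactly balanced: the loop-center midpoint coincides with the TM
  centroid, so axis-construction errors show up as nonzero
  ``tm_center_distance``.

A single integer seed drives all randomness through spawned substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import AA_ALPHABET, GAP, GroupedAlignment
from .structure import RegionConfig, StructureModel


@dataclass(frozen=True)
class SyntheticAlignmentSpec:
    """Study conditions for a planted-divergence two-group alignment."""

    n_a: int = 40
    n_b: int = 40
    length: int = 300
    n_planted: int = 15
    planted_sites: tuple[int, ...] | None = None   # drawn from the seed if None
    divergence: float = 0.9                        # 0 = exchangeable groups
    background_concentration: float = 0.5          # Dirichlet concentration
    gap_rate: float = 0.05
    majority_gap_sites: tuple[int, ...] = ()
    group_a_label: str = "ckr"
    group_b_label: str = "variant"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must lie in [0, 1]")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must lie in [0, 1)")
        if self.planted_sites is not None:
            bad = [c for c in self.planted_sites if not 0 <= c < self.length]
            if bad:
                raise ValueError(f"planted sites outside [0, {self.length}): {bad}")


#: number of low-frequency residues the planted divergence shifts mass onto
_N_TARGET_RESIDUES = 4


def generate_alignment(spec: SyntheticAlignmentSpec):
    """Draw a grouped alignment plus its planted-site truth table.

    Returns ``(aln, planted)`` where ``planted`` is the sorted tuple of
    divergent column indices.  The first group-A sequence is the designated
    reference and receives no injected gaps (the structure-bearing anchor
    must cover every detectable column; a planted site hidden behind a
    reference gap would be undetectable by construction, which is also why
    a planted site in ``majority_gap_sites`` is rejected).
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_sites, rng_comp, rng_letters, rng_gaps = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    if spec.planted_sites is None:
        planted = tuple(
            sorted(rng_sites.choice(spec.length, size=spec.n_planted, replace=False))
        )
    else:
        planted = tuple(sorted(set(spec.planted_sites)))
    overlap = set(planted) & set(spec.majority_gap_sites)
    if overlap:
        raise ValueError(
            f"planted sites {sorted(overlap)} are forced above the gap-skip "
            "threshold and would be undetectable by design"
        )

    n_total = spec.n_a + spec.n_b
    k = len(AA_ALPHABET)
    alpha = np.full(k, spec.background_concentration)
    planted_set = set(planted)

    letters = np.empty((n_total, spec.length), dtype=np.int8)
    for c in range(spec.length):
        shared = rng_comp.dirichlet(alpha)
        comp_b = shared
        if c in planted_set:
            # move mass onto the residues the shared composition barely uses
            target_idx = np.argsort(shared, kind="stable")[:_N_TARGET_RESIDUES]
            target = np.zeros(k)
            target[target_idx] = 1.0 / _N_TARGET_RESIDUES
            comp_b = (1.0 - spec.divergence) * shared + spec.divergence * target
        letters[: spec.n_a, c] = rng_letters.choice(k, size=spec.n_a, p=shared)
        letters[spec.n_a :, c] = rng_letters.choice(k, size=spec.n_b, p=comp_b)

    gapped = rng_gaps.random((n_total, spec.length)) < spec.gap_rate
    gapped[0, :] = False  # reference sequence stays ungapped
    k_majority = n_total // 2 + 1
    for c in spec.majority_gap_sites:
        rows = 1 + rng_gaps.choice(n_total - 1, size=k_majority, replace=False)
        gapped[rows, c] = True

    rows = []
    for i in range(n_total):
        chars = [AA_ALPHABET[letters[i, c]] if not gapped[i, c] else GAP
                 for c in range(spec.length)]
        rows.append("".join(chars))
    ids = [f"{spec.group_a_label}_{i+1}" for i in range(spec.n_a)] + [
        f"{spec.group_b_label}_{i+1}" for i in range(spec.n_b)
    ]
    group_of = {
        sid: (spec.group_a_label if i < spec.n_a else spec.group_b_label)
        for i, sid in enumerate(ids)
    }
    aln = GroupedAlignment(
        ids=tuple(ids), rows=tuple(rows), group_of=group_of, reference_id=ids[0]
    )
    return aln, planted


@dataclass(frozen=True)
class SyntheticStructureSpec:
    """Geometry of the toy seven-helix bundle."""

    n_term: int = 10
    c_term: int = 10
    per_tm: int = 22
    per_loop: int = 6
    radius: float = 12.0          # Angstrom, helix axes from the bundle axis
    rise: float = 1.5             # Angstrom of z per TM residue
    loop_offset: float = 2.0      # loops sit this far beyond the helix ends
    helix_radius: float = 2.3     # local C-alpha radius about each helix axis
    xy_jitter: float = 0.0        # optional Gaussian xy noise (symmetry-breaking)
    n_insert: int = 0             # residues of an excluded fused-insert blob
    seed: int = 0


# topology order: region label, side (+1 extracellular / -1 intracellular / 0 TM)
_TOPOLOGY = (
    ("N", +1), ("TM1", 0), ("ICL1", -1), ("TM2", 0), ("ECL1", +1),
    ("TM3", 0), ("ICL2", -1), ("TM4", 0), ("ECL2", +1), ("TM5", 0),
    ("ICL3", -1), ("TM6", 0), ("ECL3", +1), ("TM7", 0), ("C", -1),
)

_INSERT_OFFSET = 1000  # insert residues numbered from here, like a fusion construct


def generate_structure(spec: SyntheticStructureSpec):
    """Build the toy bundle; returns ``(StructureModel, RegionConfig)``.

    Region residue numbers run sequentially through the topology; the
    C-terminal range doubles as ``cterm_range`` (excluded from the
    intracellular center, mirroring the receptor convention), and the
    optional insert blob lands in ``excluded_ranges``.  Pocket residues
    default to the extracellular half of the TM bundle.
    """
    rng = np.random.default_rng(spec.seed)
    z_half = (spec.per_tm - 1) * spec.rise / 2.0
    loop_z = z_half + spec.loop_offset

    residues: dict[int, np.ndarray] = {}
    ranges: dict[str, tuple[int, int]] = {}
    resnum = 0
    tm_index = 0
    loop_phase = 0.0
    for label, side in _TOPOLOGY:
        if side == 0:
            theta = 2.0 * math.pi * tm_index / 7.0
            cx, cy = spec.radius * math.cos(theta), spec.radius * math.sin(theta)
            zs = np.linspace(z_half, -z_half, spec.per_tm)
            if tm_index % 2 == 1:
                zs = zs[::-1]  # alternate up/down through the membrane
            start = resnum + 1
            for j, z in enumerate(zs):
                resnum += 1
                # spiral phase offset by the bundle angle: the seven local
                # offsets cancel, keeping the TM centroid on the bundle axis
                phi = math.radians(100.0) * j + theta
                residues[resnum] = np.array(
                    [cx + spec.helix_radius * math.cos(phi),
                     cy + spec.helix_radius * math.sin(phi),
                     z]
                )
            ranges[label] = (start, resnum)
            tm_index += 1
        else:
            n_res = {"N": spec.n_term, "C": spec.c_term}.get(label, spec.per_loop)
            start = resnum + 1
            # evenly spaced around the full circle: the region's xy centroid
            # vanishes, so the loop-center midpoint matches the bundle center
            for j in range(n_res):
                resnum += 1
                phi = 2.0 * math.pi * j / n_res + loop_phase
                residues[resnum] = np.array(
                    [spec.radius * math.cos(phi),
                     spec.radius * math.sin(phi),
                     side * loop_z]
                )
            ranges[label] = (start, resnum)
            loop_phase += 0.5  # decorrelate successive regions
    if spec.xy_jitter > 0:
        for r in residues:
            residues[r] = residues[r] + np.array(
                [rng.normal(0, spec.xy_jitter), rng.normal(0, spec.xy_jitter), 0.0]
            )

    excluded: list[tuple[int, int]] = []
    if spec.n_insert > 0:
        start = _INSERT_OFFSET + 1
        for j in range(spec.n_insert):
            residues[start + j] = np.array(
                [spec.radius + 20.0 + rng.normal(0, 1.0),
                 rng.normal(0, 1.0),
                 -z_half + rng.normal(0, 1.0)]
            )
        excluded.append((start, start + spec.n_insert - 1))

    pocket = frozenset(
        r
        for label in (f"TM{i}" for i in range(1, 8))
        for r in range(ranges[label][0], ranges[label][1] + 1)
        if residues[r][2] > z_half / 2.0
    )
    cfg = RegionConfig(
        ranges=ranges,
        excluded_ranges=tuple(excluded),
        cterm_range=ranges["C"],
        pocket_residues=pocket,
    )
    return StructureModel(residues=dict(sorted(residues.items()))), cfg


@dataclass(frozen=True)
class RecoveryResult:
    precision: float | None   # None when nothing was selected
    recall: float


def evaluate_recovery(selected, planted) -> RecoveryResult:
    """Precision/recall of a selected column set against the planted truth."""
    sel = set(int(c) for c in selected)
    tru = set(int(c) for c in planted)
    if not tru:
        raise ValueError("empty planted-site truth table")
    hit = len(sel & tru)
    precision = hit / len(sel) if sel else None
    return RecoveryResult(precision=precision, recall=hit / len(tru))
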