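"""Receptor structure handling: regions, membrane axis, residue projection.

A 7TM receptor is reduced to its C-alpha trace plus a region label per
residue (N-terminus, TM1-7, ECL1-3, ICL1-3, C-terminus).  The
extracellular<->intracellular axis runs between two geometric centers: the
C-alphas of the extracellular loops plus the N-terminal region on one
side, and of the intracellular loops on the other (the C-terminal tail,
which extends into the cytosol, and any engineered insert such as a fused
lysozyme are excluded from the center computation).  Every residue's
C-alpha is then orthogonally projected onto the axis; the signed distance
from the axis midpoint (positive = extracellular) is the residue's
projection score, the quantity the spatial-bias t-tests compare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml
from Bio.PDB import PDBParser

TM_LABELS = tuple(f"TM{i}" for i in range(1, 8))
EXTRACELLULAR_LABELS = ("N", "ECL1", "ECL2", "ECL3")
INTRACELLULAR_LABELS = ("ICL1", "ICL2", "ICL3", "C")
ALL_LABELS = ("N",) + TM_LABELS + ("ECL1", "ECL2", "ECL3", "ICL1", "ICL2", "ICL3", "C")


class ChainNotFoundError(KeyError):
    """Requested chain id absent from the structure."""


class InsertionCodeError(ValueError):
    """Residue insertion codes are not supported in region arithmetic."""


class DegenerateAxisError(ValueError):
    """The two geometric centers coincide; no axis direction exists."""


@dataclass(frozen=True)
class RegionConfig:
    """Residue-number intervals defining receptor topology.

    ``ranges`` maps region label -> inclusive (start, end) interval;
    ``excluded_ranges`` are dropped entirely (e.g. a fused-lysozyme
    insert); ``cterm_range`` is removed from the intracellular center
    only (its residues are still projected); ``pocket_residues`` flags
    the ligand-binding cavity.
    """

    ranges: Mapping[str, tuple[int, int]]
    excluded_ranges: tuple[tuple[int, int], ...] = ()
    cterm_range: tuple[int, int] | None = None
    pocket_residues: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for label in self.ranges:
            if label not in ALL_LABELS:
                raise ValueError(f"unknown region label {label!r}")
        for label, (a, b) in self.ranges.items():
            if a > b:
                raise ValueError(f"region {label}: start {a} > end {b}")

    def is_excluded(self, resnum: int) -> bool:
        return any(a <= resnum <= b for a, b in self.excluded_ranges)

    def region_of(self, resnum: int) -> str | None:
        if self.is_excluded(resnum):
            return None
        for label, (a, b) in self.ranges.items():
            if a <= resnum <= b:
                return label
        return None

    def residues_in(self, labels: Iterable[str], model: "StructureModel") -> list[int]:
        """Residues of `model` lying in the given regions, exclusions removed."""
        wanted = set(labels)
        return [
            r
            for r in model.residues
            if not self.is_excluded(r) and self.region_of(r) in wanted
        ]

    def in_pocket(self, resnum: int) -> bool:
        return resnum in self.pocket_residues

    @classmethod
    def from_yaml(cls, path) -> "RegionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ranges = {k: (int(v[0]), int(v[1])) for k, v in raw["regions"].items()}
        excluded = tuple((int(a), int(b)) for a, b in raw.get("excluded_ranges", []))
        cterm = raw.get("cterm_range")
        if cterm is not None:
            cterm = (int(cterm[0]), int(cterm[1]))
        pocket = frozenset(int(r) for r in raw.get("pocket_residues", []))
        return cls(ranges=ranges, excluded_ranges=excluded, cterm_range=cterm,
                   pocket_residues=pocket)

    def to_yaml(self, path) -> None:
        payload = {
            "regions": {k: list(v) for k, v in self.ranges.items()},
            "excluded_ranges": [list(r) for r in self.excluded_ranges],
            "cterm_range": list(self.cterm_range) if self.cterm_range else None,
            "pocket_residues": sorted(self.pocket_residues),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass(frozen=True)
class StructureModel:
    """Ordered residue number -> C-alpha coordinate map for one chain."""

    residues: Mapping[int, np.ndarray]

    def coords(self, resnums: Iterable[int]) -> np.ndarray:
        return np.array([self.residues[r] for r in resnums], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body copy: x -> R x + t for every C-alpha."""
        return StructureModel(
            residues={
                r: rotation @ xyz + translation for r, xyz in self.residues.items()
            }
        )


def read_structure(path, chain: str = "A") -> StructureModel:
    """C-alpha trace of one chain from a PDB file.

    HETATM records and waters are ignored; for alternate locations the
    first altloc (alphabetically) is kept; insertion codes are rejected;
    residues without a C-alpha are skipped with a warning.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    model = structure[0]
    if chain not in model:
        raise ChainNotFoundError(f"chain {chain!r} not present in {path}")
    residues: dict[int, np.ndarray] = {}
    for res in model[chain]:
        hetflag, resnum, icode = res.id
        if hetflag != " ":
            continue
        if icode != " ":
            raise InsertionCodeError(
                f"residue {resnum}{icode.strip()}: insertion codes are not supported"
            )
        if "CA" not in res:
            warnings.warn(f"residue {resnum} has no C-alpha; skipped", stacklevel=2)
            continue
        atom = res["CA"]
        if atom.is_disordered():
            alt = sorted(atom.disordered_get_id_list())[0]
            atom = atom.disordered_get(alt)
        residues[resnum] = np.asarray(atom.coord, dtype=float)
    return StructureModel(residues=dict(sorted(residues.items())))


def write_ca_pdb(model: StructureModel, path, chain: str = "A") -> None:
    """Write the C-alpha trace as minimal ATOM records (GLY placeholders)."""
    with open(path, "w") as fh:
        serial = 1
        for resnum, (x, y, z) in model.residues.items():
            fh.write(
                f"ATOM  {serial:5d}  CA  GLY {chain}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
            serial += 1
        fh.write("END\n")


@dataclass(frozen=True)
class ProjectionAxis:
    """Extracellular<->intracellular axis through the loop centers."""

    center_extra: np.ndarray
    center_intra: np.ndarray

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.center_extra + self.center_intra)

    @property
    def unit_vector(self) -> np.ndarray:
        """Unit vector from the midpoint toward the extracellular center."""
        d = self.center_extra - self.center_intra
        norm = np.linalg.norm(d)
        if norm == 0:
            raise DegenerateAxisError("extracellular and intracellular centers coincide")
        return d / norm


@dataclass(frozen=True)
class ProjectionResult:
    """Signed axis positions (Angstrom) per residue, with a selected split."""

    score_of: Mapping[int, float]
    selected: frozenset[int] = field(default_factory=frozenset)

    def with_selected(self, residues: Iterable[int]) -> "ProjectionResult":
        sel = frozenset(residues) & set(self.score_of)
        return ProjectionResult(score_of=self.score_of, selected=sel)

    def selected_scores(self) -> np.ndarray:
        return np.array([self.score_of[r] for r in sorted(self.selected)])

    def remaining_scores(self) -> np.ndarray:
        rest = sorted(set(self.score_of) - self.selected)
        return np.array([self.score_of[r] for r in rest])


def compute_axis(model: StructureModel, cfg: RegionConfig) -> ProjectionAxis:
    """Geometric centers of the extracellular and intracellular loop sets.

    Extracellular: ECL1-3 + N-terminal region.  Intracellular: ICL1-3 (and
    any C-terminal residues outside ``cterm_range``); the cytosol-extending
    C-terminal tail and excluded inserts never contribute.
    """
    extra = cfg.residues_in(EXTRACELLULAR_LABELS, model)
    intra = cfg.residues_in(INTRACELLULAR_LABELS, model)
    if cfg.cterm_range is not None:
        a, b = cfg.cterm_range
        intra = [r for r in intra if not a <= r <= b]
    if not extra or not intra:
        raise ValueError("empty extracellular or intracellular region set")
    center_extra = model.coords(extra).mean(axis=0)
    center_intra = model.coords(intra).mean(axis=0)
    axis = ProjectionAxis(center_extra=center_extra, center_intra=center_intra)
    axis.unit_vector  # raises DegenerateAxisError on coincident centers
    return axis


def project_residues(
    model: StructureModel, axis: ProjectionAxis, cfg: RegionConfig
) -> ProjectionResult:
    """Signed axis score for every non-excluded residue.

    score(r) = unit_vector . (CA(r) - midpoint); positive lies on the
    extracellular side.  C-terminal residues are projected (they are only
    left out of the center computation).
    """
    u = axis.unit_vector
    mid = axis.midpoint
    scores = {
        r: float(u @ (xyz - mid))
        for r, xyz in model.residues.items()
        if not cfg.is_excluded(r)
    }
    return ProjectionResult(score_of=scores)


def tm_center_distance(model: StructureModel, axis: ProjectionAxis, cfg: RegionConfig) -> float:
    """Distance from the axis midpoint to the TM-helix C-alpha centroid.

    A small value means the loop-center midpoint sits near the geometric
    center of the membrane-spanning bundle.
    """
    tm = cfg.residues_in(TM_LABELS, model)
    if not tm:
        raise ValueError("no TM residues present")
    centroid = model.coords(tm).mean(axis=0)
    return float(np.linalg.norm(axis.midpoint - centroid))
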