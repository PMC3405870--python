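"""Aligned-sequence handling for two-group divergence comparisons.

A comparison starts from a multiple protein alignment (FASTA or Clustal)
plus a two-column table assigning each sequence to one of exactly two
functional groups (e.g. traditional chemokine receptors vs. one decoy- or
viral-receptor group).  One sequence — the one with a solved structure,
CXCR4 in the reference analysis — is designated as the reference, and its
ungapped positions anchor alignment columns to residue numbers.

Compositions are modelled over the 20 standard amino acids only; the
ambiguity code 'X' and the dot gap symbol are normalized to '-' on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from Bio import AlignIO

#: Amino-acid alphabet in NCBI substitution-matrix order.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
GAP = "-"


class AlignmentShapeError(ValueError):
    """Rows of the alignment do not all have the same length."""


class AlignmentParseError(ValueError):
    """A sequence contains a character outside the 20 letters + gap."""


class GroupTableError(ValueError):
    """Malformed or inconsistent group-assignment table."""


def _normalize_row(seq: str) -> str:
    return seq.upper().replace(".", GAP).replace("X", GAP)


@dataclass(frozen=True)
class GroupedAlignment:
    """An alignment with optional group labels and a reference sequence.

    Rows are equal-length strings over the 20 amino-acid letters plus '-'.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    group_of: Mapping[str, str] | None = None
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise GroupTableError(f"duplicate sequence ids: {dupes}")
        if not self.rows:
            raise AlignmentShapeError("empty alignment")
        L = len(self.rows[0])
        if L < 1:
            raise AlignmentShapeError("alignment has zero columns")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise AlignmentShapeError(
                    f"sequence {sid!r} has length {len(row)}, expected {L}"
                )
            for c, ch in enumerate(row):
                if ch != GAP and ch not in AA_INDEX:
                    raise AlignmentParseError(
                        f"sequence {sid!r}, column {c}: invalid residue {ch!r}"
                    )
        if self.group_of is not None:
            missing = [i for i in self.ids if i not in self.group_of]
            if missing:
                raise GroupTableError(f"sequences without a group label: {missing}")
        if self.reference_id is not None and self.reference_id not in self.ids:
            raise GroupTableError(
                f"reference id {self.reference_id!r} not in the alignment"
            )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Labels actually used by sequences in the alignment, sorted."""
        if self.group_of is None:
            return ()
        return tuple(sorted({self.group_of[i] for i in self.ids}))

    def rows_of_group(self, label: str) -> tuple[str, ...]:
        if self.group_of is None:
            raise GroupTableError("alignment has no group labels attached")
        return tuple(r for i, r in zip(self.ids, self.rows) if self.group_of[i] == label)

    def column(self, col: int) -> str:
        if not 0 <= col < self.length:
            raise IndexError(f"column {col} out of range [0, {self.length})")
        return "".join(r[col] for r in self.rows)

    def encoded(self) -> np.ndarray:
        """Integer matrix (n_sequences x L); gap encoded as -1."""
        lut = np.full(128, -1, dtype=np.int8)
        for a, i in AA_INDEX.items():
            lut[ord(a)] = i
        mat = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        return lut[mat].reshape(self.n_sequences, self.length)


def read_alignment(path, fmt: str = "fasta") -> GroupedAlignment:
    """Read an aligned FASTA or Clustal file (no group labels attached).

    Letters are uppercased; 'X' and '.' become gaps.  Ragged records and
    unknown residue letters raise with the offending sequence named.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format: {fmt!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        if "same length" in str(exc):
            raise AlignmentShapeError(str(exc)) from exc
        raise
    ids = tuple(rec.id for rec in msa)
    rows = tuple(_normalize_row(str(rec.seq)) for rec in msa)
    return GroupedAlignment(ids=ids, rows=rows)


def write_alignment(aln: GroupedAlignment, path, fmt: str = "fasta") -> None:
    """Write the alignment back out (round-trips exactly through read_alignment)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio.Align import MultipleSeqAlignment

    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(r), id=i, description="") for i, r in zip(aln.ids, aln.rows)]
    )
    AlignIO.write(msa, str(path), fmt)


def read_groups(path) -> dict[str, str]:
    """Read a two-column (id, group label) whitespace/tab-delimited table."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GroupTableError(
                    f"line {lineno}: expected two columns, got {len(parts)}"
                )
            sid, label = parts
            if sid in mapping:
                raise GroupTableError(f"line {lineno}: duplicate id {sid!r}")
            mapping[sid] = label
    return mapping


def attach_groups(
    aln: GroupedAlignment,
    group_of: Mapping[str, str],
    reference_id: str | None = None,
) -> GroupedAlignment:
    """Join group labels onto an alignment; exactly two labels must be used.

    Ids in the table but absent from the alignment are ignored (the table
    may cover a superset); alignment sequences without a label are an error.
    """
    missing = [i for i in aln.ids if i not in group_of]
    if missing:
        raise GroupTableError(f"no group label for sequences: {missing}")
    used = {group_of[i] for i in aln.ids}
    if len(used) != 2:
        raise GroupTableError(
            f"a comparison needs exactly two groups, found {sorted(used)}"
        )
    sub = {i: group_of[i] for i in aln.ids}
    return replace(aln, group_of=sub, reference_id=reference_id or aln.reference_id)


def column_gap_fraction(aln: GroupedAlignment, col: int) -> float:
    """Fraction of sequences (both groups pooled, unweighted) gapped at `col`."""
    letters = aln.column(col)
    return letters.count(GAP) / len(letters)


@dataclass(frozen=True)
class ReferenceColumnMap:
    """Alignment column -> reference residue number, for the structure anchor.

    The k-th non-gap character of the reference row maps to residue number
    k + pdb_offset (k counted from 1), so mapped numbers can be made to
    match the deposited structure's author numbering.
    """

    column_to_residue: Mapping[int, int]
    gapped_columns: frozenset[int] = field(default_factory=frozenset)

    def residue_of(self, col: int) -> int | None:
        return self.column_to_residue.get(col)


def map_reference_columns(aln: GroupedAlignment, pdb_offset: int = 0) -> ReferenceColumnMap:
    """Build the column -> reference residue-number map from the reference row."""
    if aln.reference_id is None:
        raise GroupTableError("alignment has no reference sequence designated")
    row = aln.rows[aln.ids.index(aln.reference_id)]
    mapping: dict[int, int] = {}
    gapped: set[int] = set()
    k = 0
    for col, ch in enumerate(row):
        if ch == GAP:
            gapped.add(col)
        else:
            k += 1
            mapping[col] = k + pdb_offset
    return ReferenceColumnMap(column_to_residue=mapping, gapped_columns=frozenset(gapped))
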