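"""Grantham Variation / Grantham Deviation scoring from an alignment.

Given a protein multiple sequence alignment, each position defines a
hyper-rectangle in the three-dimensional Grantham property space
(composition, polarity, volume) spanned by the residues observed there
across orthologs.

* **GV** (Grantham Variation) measures the spread of that rectangle:
  the Grantham-form length of its diagonal.  GV = 0 at an invariant
  position.
* **GD** (Grantham Deviation) measures how far a mutant residue falls
  outside the rectangle: the Grantham-form distance from the mutant's
  property point to the nearest face.  GD = 0 whenever the mutant lies
  within the ranges already tolerated at that position.

A (GV, GD) pair maps onto an ordered series of grades C0 (most likely
neutral) through C65 (most likely deleterious); grades C45, C55 and C65
are treated as deleterious calls.  The grade boundaries are loaded from
an editable JSON grid (``data/gvgd_grid.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .grantham import ALPHA, BETA, GAMMA, PROPERTIES, RHO
from .variants import AMINO_ACIDS, Call, ProteinVariant

__all__ = [
    "DELETERIOUS_GRADES",
    "GRADES",
    "GvgdGrid",
    "GvgdResult",
    "MsaColumn",
    "ProteinAlignment",
    "compute_gd",
    "compute_gv",
    "gvgd_call",
    "gvgd_class",
    "score_variant",
]

#: All grades, most-likely-neutral first.
GRADES = ("C0", "C15", "C25", "C35", "C45", "C55", "C65")

#: Grades treated as a deleterious call.
DELETERIOUS_GRADES = frozenset({"C45", "C55", "C65"})

_GAP_CHARS = set("-.")


class MsaColumn:
    """Residues observed at one alignment position, gaps removed."""

    def __init__(self, residues: Iterable[str]):
        kept = [r.upper() for r in residues if r not in _GAP_CHARS and r != " "]
        bad = [r for r in kept if r not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"nonstandard residues in column: {sorted(set(bad))}")
        if not kept:
            raise ValueError("alignment column is empty after gap removal")
        self.residues: tuple[str, ...] = tuple(kept)

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, aa: str) -> bool:
        return aa.upper() in self.residues

    def property_ranges(self) -> np.ndarray:
        """(2, 3) array: per-property min (row 0) and max (row 1)."""
        pts = np.array([PROPERTIES[r] for r in self.residues])
        return np.vstack([pts.min(axis=0), pts.max(axis=0)])


_WEIGHTS = np.array([ALPHA, BETA, GAMMA])


def compute_gv(column: MsaColumn) -> float:
    """Grantham Variation: spread of the column's property rectangle."""
    lo, hi = column.property_ranges()
    return RHO * float(np.sqrt(np.sum(_WEIGHTS * (hi - lo) ** 2)))


def compute_gd(column: MsaColumn, mutant: str) -> float:
    """Grantham Deviation of ``mutant`` from the column's tolerated ranges.

    Zero when every property of the mutant lies within the column's
    per-property range; otherwise the Grantham-form distance to the
    nearest boundary of the property hyper-rectangle.
    """
    mutant = mutant.upper()
    if mutant not in PROPERTIES:
        raise ValueError(f"nonstandard mutant residue: {mutant!r}")
    lo, hi = column.property_ranges()
    point = np.array(PROPERTIES[mutant])
    excess = np.maximum(lo - point, 0.0) + np.maximum(point - hi, 0.0)
    return RHO * float(np.sqrt(np.sum(_WEIGHTS * excess**2)))


@dataclass(frozen=True)
class GvgdGrid:
    """Editable grade grid: GD >= intercept + slope*GV, highest grade wins."""

    boundaries: tuple[tuple[str, float], ...]  # (grade, intercept), descending
    slope: float

    @classmethod
    def default(cls) -> "GvgdGrid":
        text = (
            resources.files("missensus").joinpath("data/gvgd_grid.json").read_text()
        )
        return cls.from_json(text)

    @classmethod
    def from_json(cls, text: str) -> "GvgdGrid":
        spec = json.loads(text)
        bounds = tuple(
            (b["grade"], float(b["intercept"])) for b in spec["boundaries"]
        )
        return cls(boundaries=bounds, slope=float(spec["slope"]))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "GvgdGrid":
        return cls.from_json(Path(path).read_text())

    def classify(self, gv: float, gd: float) -> str:
        if gv < 0 or gd < 0:
            raise ValueError(f"GV and GD must be non-negative, got ({gv}, {gd})")
        for grade, intercept in self.boundaries:
            # boundary inclusive; epsilon guards float noise in slope*gv
            if gd >= intercept + self.slope * gv - 1e-9:
                return grade
        return "C0"


def gvgd_class(gv: float, gd: float, grid: Optional[GvgdGrid] = None) -> str:
    """Map a (GV, GD) pair to a grade C0..C65."""
    return (grid or GvgdGrid.default()).classify(gv, gd)


def gvgd_call(grade: str) -> Call:
    """Binary verdict of a grade: C45/C55/C65 deleterious, rest neutral."""
    if grade not in GRADES:
        raise ValueError(f"unknown grade: {grade!r}")
    return Call.DELETERIOUS if grade in DELETERIOUS_GRADES else Call.NEUTRAL


@dataclass(frozen=True)
class GvgdResult:
    gv: float
    gd: float
    grade: str

    @property
    def call(self) -> Call:
        return gvgd_call(self.grade)


class ProteinAlignment:
    """Aligned FASTA with the reference (scored) sequence first.

    Variant positions are 1-based coordinates on the reference
    sequence's *ungapped* residues; they are mapped to alignment columns
    internally.
    """

    def __init__(self, sequences: Sequence[str], ids: Optional[Sequence[str]] = None):
        if not sequences:
            raise ValueError("alignment has no sequences")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in sequences]
        self.ids = list(ids) if ids is not None else [f"seq{i}" for i in range(len(sequences))]
        ref = self.sequences[0]
        # ungapped reference position (1-based) -> alignment column (0-based)
        self._ref_to_col = {}
        pos = 0
        for col, ch in enumerate(ref):
            if ch not in _GAP_CHARS:
                pos += 1
                self._ref_to_col[pos] = col

    @classmethod
    def from_fasta(cls, source: Union[str, Path, IO[str]]) -> "ProteinAlignment":
        records = list(SeqIO.parse(source, "fasta"))
        if not records:
            raise ValueError("no sequences in FASTA input")
        return cls([str(r.seq) for r in records], [r.id for r in records])

    @property
    def reference_length(self) -> int:
        return len(self._ref_to_col)

    def column(self, position: int) -> MsaColumn:
        """Alignment column at 1-based ungapped reference position."""
        try:
            col = self._ref_to_col[position]
        except KeyError:
            raise ValueError(
                f"position {position} outside reference sequence "
                f"(length {self.reference_length})"
            ) from None
        return MsaColumn(seq[col] for seq in self.sequences)

    def reference_residue(self, position: int) -> str:
        return self.sequences[0][self._ref_to_col[position]]


def score_variant(
    alignment: ProteinAlignment,
    variant: ProteinVariant,
    grid: Optional[GvgdGrid] = None,
    *,
    check_reference: bool = True,
) -> GvgdResult:
    """GV, GD and grade for one substitution against the alignment.

    With ``check_reference`` the reference residue at the variant's
    position must equal the variant's wild-type residue.
    """
    column = alignment.column(variant.position)
    if check_reference:
        ref = alignment.reference_residue(variant.position)
        if ref != variant.wt_aa:
            raise ValueError(
                f"reference residue {ref} at position {variant.position} "
                f"does not match variant wild-type {variant.wt_aa}"
            )
    gv = compute_gv(column)
    gd = compute_gd(column, variant.mut_aa)
    return GvgdResult(gv=gv, gd=gd, grade=gvgd_class(gv, gd, grid))
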