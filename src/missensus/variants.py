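"""Domain types for missense variants and variant-table I/O.

A variant is a single amino-acid substitution on a named protein
(e.g. BRCA1 Cys64Gly).  Records carry the raw output of each upstream
predictor, the harmonized binary call derived from it, an optional
five-tier clinical classification (1 benign ... 5 pathogenic, 3 = VUS),
an optional conservation grade (1-9), and optional folding free-energy
changes from the two stability channels.

Tables are plain TSV/CSV with required columns ``gene`` and ``variant``;
predictor columns are mapped by a configurable column map.  Empty cells
are missing values, never zero.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional, Union

import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

__all__ = [
    "AMINO_ACIDS",
    "Call",
    "DuplicateVariantError",
    "ProteinVariant",
    "Tool",
    "ToolPrediction",
    "VariantParseError",
    "VariantRecord",
    "VOTE_TOOLS",
    "parse_protein_variant",
    "read_variant_table",
    "write_results",
]

#: The 20 standard amino acids, one-letter codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_ONE_TO_THREE = dict(protein_letters_1to3)

_VARIANT_RE = re.compile(
    r"^(?:p\.)?\(?([A-Za-z]{3}|[A-Za-z])(\d+)([A-Za-z]{3}|[A-Za-z])\)?$"
)


class VariantParseError(ValueError):
    """A protein-change string could not be interpreted."""


class DuplicateVariantError(ValueError):
    """The same (gene, substitution) appeared more than once in a table."""

    def __init__(self, duplicates: list[tuple[str, str]]):
        self.duplicates = duplicates
        listing = ", ".join(f"{g}:{v}" for g, v in duplicates)
        super().__init__(f"duplicate (gene, variant) rows: {listing}")


class Tool(str, enum.Enum):
    """Upstream predictors whose outputs the pipeline consumes."""

    SIFT = "SIFT"
    POLYPHEN2 = "PolyPhen2"
    PHD_SNP = "PhD-SNP"
    SNPS_GO = "SNPs&GO"
    SNAP = "SNAP"
    FATHMM = "FATHMM"
    IMUTANT = "I-Mutant"
    PANTHER = "PANTHER"
    ALIGN_GVGD = "Align-GVGD"
    FOLDX = "FoldX"
    CONSURF = "ConSurf"


#: The seven predictors that take part in the rank-1..4 vote.
VOTE_TOOLS: tuple[Tool, ...] = (
    Tool.SIFT,
    Tool.PHD_SNP,
    Tool.POLYPHEN2,
    Tool.SNPS_GO,
    Tool.SNAP,
    Tool.FATHMM,
    Tool.IMUTANT,
)


class Call(str, enum.Enum):
    """Harmonized binary verdict of a single predictor."""

    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"


def _check_residue(code: str, what: str) -> str:
    one = code.upper() if len(code) == 1 else _THREE_TO_ONE.get(code.upper())
    if one is None or one not in AMINO_ACIDS:
        raise VariantParseError(f"unknown {what} residue code: {code!r}")
    return one


@dataclass(frozen=True, order=True)
class ProteinVariant:
    """One amino-acid substitution, 1-based protein coordinates."""

    gene: str
    wt_aa: str  # one-letter
    position: int
    mut_aa: str  # one-letter

    def __post_init__(self) -> None:
        if self.wt_aa not in AMINO_ACIDS:
            raise VariantParseError(f"unknown wild-type residue: {self.wt_aa!r}")
        if self.mut_aa not in AMINO_ACIDS:
            raise VariantParseError(f"unknown mutant residue: {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise VariantParseError(
                f"synonymous change {self.wt_aa}{self.position}{self.mut_aa}: "
                "wild-type and mutant residues are identical"
            )
        if self.position < 1:
            raise VariantParseError(f"non-positive position: {self.position}")

    @property
    def short(self) -> str:
        """One-letter form, e.g. ``C64G``."""
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def long(self) -> str:
        """Three-letter form, e.g. ``Cys64Gly`` (canonical output form)."""
        return (
            f"{_ONE_TO_THREE[self.wt_aa]}{self.position}{_ONE_TO_THREE[self.mut_aa]}"
        )

    def __str__(self) -> str:
        return f"{self.gene}:{self.long}"


def parse_protein_variant(text: str, gene: str) -> ProteinVariant:
    """Parse ``Cys39Ser``, ``C39S``, ``p.Cys39Ser`` or ``p.C39S``.

    All four spellings of the same substitution parse to the same
    :class:`ProteinVariant`.
    """
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        raise VariantParseError(f"cannot parse protein change: {text!r}")
    wt_code, pos_str, mut_code = m.groups()
    if len(wt_code) != len(mut_code):
        raise VariantParseError(
            f"mixed one-/three-letter residue codes in {text!r}"
        )
    wt = _check_residue(wt_code, "wild-type")
    mut = _check_residue(mut_code, "mutant")
    position = int(pos_str)
    if position < 1:
        raise VariantParseError(f"non-positive position in {text!r}")
    return ProteinVariant(gene=gene, wt_aa=wt, position=position, mut_aa=mut)


@dataclass(frozen=True)
class ToolPrediction:
    """One predictor's raw output plus its harmonized binary call."""

    tool: Tool
    raw: Union[float, str, None]
    call: Optional[Call]


@dataclass
class VariantRecord:
    """Assembled analysis row for one variant.

    ``predictions`` holds at most one :class:`ToolPrediction` per tool.
    ``rank`` and ``extremely_deleterious`` are populated by the consensus
    stage; ``truth`` carries the latent label of simulated cohorts and is
    absent for real data.
    """

    variant: ProteinVariant
    predictions: dict[Tool, ToolPrediction] = field(default_factory=dict)
    gold: Optional[int] = None  # five-tier clinical class 1..5
    consurf: Optional[int] = None  # conservation grade 1..9
    imutant_ddg: Optional[float] = None
    foldx_ddg: Optional[float] = None
    n_deleterious: Optional[int] = None
    rank: Optional[int] = None
    deleterious_consensus: Optional[bool] = None
    extremely_deleterious: Optional[bool] = None
    gv: Optional[float] = None
    gd: Optional[float] = None
    gvgd_grade: Optional[str] = None
    truth: Optional[str] = None  # latent 'pathogenic'/'benign' in simulations
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gold is not None and self.gold not in (1, 2, 3, 4, 5):
            raise ValueError(f"gold class must be 1..5, got {self.gold}")
        if self.consurf is not None and not 1 <= self.consurf <= 9:
            raise ValueError(f"conservation grade must be 1..9, got {self.consurf}")

    def call(self, tool: Tool) -> Optional[Call]:
        pred = self.predictions.get(tool)
        return None if pred is None else pred.call

    def set_prediction(self, pred: ToolPrediction) -> None:
        self.predictions[pred.tool] = pred


# ---------------------------------------------------------------------------
# Table I/O

#: Default mapping from table column name to tool (raw output columns).
DEFAULT_TOOL_COLUMNS: dict[str, Tool] = {
    "sift": Tool.SIFT,
    "polyphen2": Tool.POLYPHEN2,
    "phd_snp": Tool.PHD_SNP,
    "snps_go": Tool.SNPS_GO,
    "snap": Tool.SNAP,
    "fathmm": Tool.FATHMM,
    "panther": Tool.PANTHER,
}

#: call-only columns for tools whose raw channel lives elsewhere in the row
_EXTRA_CALL_COLUMNS = {
    "imutant": Tool.IMUTANT,
    "foldx": Tool.FOLDX,
    "align_gvgd": Tool.ALIGN_GVGD,
}


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def read_variant_table(
    source: Union[str, IO[str]],
    *,
    sep: str = "\t",
    tool_columns: Optional[Mapping[str, Tool]] = None,
) -> list[VariantRecord]:
    """Read a variant table into records.

    Required columns: ``gene`` and ``variant``.  Tool columns carry raw
    predictor output (harmonization happens downstream); ``iarc_class``
    (or ``gold``) the five-tier class; ``consurf`` the conservation
    grade; ``imutant_ddg`` and either ``foldx_ddg`` or the
    ``foldx_ddg_wt``/``foldx_ddg_mt`` pair the stability channels.
    Unknown columns are kept as opaque string annotations.  Empty cells
    become missing values.  Duplicate (gene, substitution) rows — after
    normalizing the protein-change spelling — raise
    :class:`DuplicateVariantError`.
    """
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = {"gene", "variant"} - set(df.columns)
    if missing_cols:
        raise ValueError(
            f"variant table lacks required column(s): {sorted(missing_cols)}"
        )
    colmap = dict(DEFAULT_TOOL_COLUMNS if tool_columns is None else tool_columns)

    records: list[VariantRecord] = []
    seen: dict[tuple[str, str], int] = {}
    duplicates: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        variant = parse_protein_variant(row["variant"], row["gene"])
        key = (variant.gene, variant.short)
        if key in seen:
            duplicates.append((variant.gene, variant.long))
        seen[key] = 1
        rec = VariantRecord(variant=variant)
        call_cells: dict[Tool, Call] = {}
        for col, value in row.items():
            if col in ("gene", "variant") or _is_missing(value):
                continue
            if col.endswith("_call") and col[: -len("_call")] in colmap:
                call_cells[colmap[col[: -len("_call")]]] = Call(value.strip().lower())
            elif col.endswith("_call") and col[: -len("_call")] in _EXTRA_CALL_COLUMNS:
                call_cells[_EXTRA_CALL_COLUMNS[col[: -len("_call")]]] = Call(
                    value.strip().lower()
                )
            elif col in colmap:
                tool = colmap[col]
                try:
                    raw: Union[str, float] = float(value)
                except ValueError:
                    raw = value.strip()
                rec.set_prediction(ToolPrediction(tool=tool, raw=raw, call=None))
            elif col in ("gold", "iarc_class"):
                rec.gold = int(float(value))
            elif col == "consurf":
                rec.consurf = int(float(value))
            elif col in ("imutant_ddg", "foldx_ddg"):
                setattr(rec, col, float(value))
            elif col in ("foldx_ddg_wt", "foldx_ddg_mt"):
                rec.annotations[col] = value
            elif col == "truth":
                rec.truth = value.strip()
            elif col == "n_deleterious":
                rec.n_deleterious = int(float(value))
            elif col == "rank":
                rec.rank = int(float(value))
            elif col in ("deleterious_consensus", "extremely_deleterious"):
                setattr(rec, col, value.strip().lower() in ("true", "1", "yes"))
            elif col in ("gv", "gd"):
                setattr(rec, col, float(value))
            elif col == "gvgd_grade":
                rec.gvgd_grade = value.strip()
            else:
                rec.annotations[col] = value
        # wt/mt free energies collapse to their difference
        wt = rec.annotations.pop("foldx_ddg_wt", None)
        mt = rec.annotations.pop("foldx_ddg_mt", None)
        if wt is not None and mt is not None and rec.foldx_ddg is None:
            rec.foldx_ddg = float(mt) - float(wt)
        for tool, call in call_cells.items():
            pred = rec.predictions.get(tool)
            raw = pred.raw if pred is not None else None
            if raw is None:
                if tool is Tool.IMUTANT:
                    raw = rec.imutant_ddg
                elif tool is Tool.FOLDX:
                    raw = rec.foldx_ddg
                elif tool is Tool.ALIGN_GVGD:
                    raw = rec.gvgd_grade
            rec.set_prediction(ToolPrediction(tool=tool, raw=raw, call=call))
        records.append(rec)
    if duplicates:
        raise DuplicateVariantError(duplicates)
    return records


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_results(
    records: Iterable[VariantRecord],
    sink: Union[str, IO[str]],
    *,
    sep: str = "\t",
    tool_columns: Optional[Mapping[str, Tool]] = None,
) -> pd.DataFrame:
    """Write records to a TSV/CSV table; missing fields are empty cells.

    Raw tool outputs and harmonized calls are both emitted
    (``<tool>`` and ``<tool>_call`` columns).  Returns the frame written.
    """
    colmap = dict(DEFAULT_TOOL_COLUMNS if tool_columns is None else tool_columns)
    tool_to_col = {t: c for c, t in colmap.items()}
    rows = []
    for rec in records:
        row: dict[str, str] = {
            "gene": rec.variant.gene,
            "variant": rec.variant.long,
        }
        for tool, col in tool_to_col.items():
            pred = rec.predictions.get(tool)
            row[col] = _fmt(pred.raw if pred else None)
            row[f"{col}_call"] = _fmt(pred.call.value if pred and pred.call else None)
        row["imutant_ddg"] = _fmt(rec.imutant_ddg)
        row["foldx_ddg"] = _fmt(rec.foldx_ddg)
        for col, tool in _EXTRA_CALL_COLUMNS.items():
            pred = rec.predictions.get(tool)
            row[f"{col}_call"] = _fmt(
                pred.call.value if pred and pred.call else None
            )
        row["consurf"] = _fmt(rec.consurf)
        row["iarc_class"] = _fmt(rec.gold)
        row["gv"] = _fmt(rec.gv)
        row["gd"] = _fmt(rec.gd)
        row["gvgd_grade"] = _fmt(rec.gvgd_grade)
        row["n_deleterious"] = _fmt(rec.n_deleterious)
        row["rank"] = _fmt(rec.rank)
        row["deleterious_consensus"] = _fmt(rec.deleterious_consensus)
        row["extremely_deleterious"] = _fmt(rec.extremely_deleterious)
        row["truth"] = _fmt(rec.truth)
        for k, v in rec.annotations.items():
            row[k] = _fmt(v)
        rows.append(row)
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=["gene", "variant"])
    df.to_csv(sink, sep=sep, index=False)
    return df
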