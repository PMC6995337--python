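"""Synthetic cohorts and alignments with the structure the pipeline assumes.

The cohort generator emulates the assembled per-variant table that the
analysis consumes: each variant carries a latent pathogenic/benign
label; every predictor's *native* raw output (score or label) is then
drawn so that its harmonized call is correct with the tool's configured
sensitivity (on pathogenic variants) or specificity (on benign ones),
conditionally independently across tools.  Stability channels are drawn
from label-specific components, conservation grades from label-specific
discrete distributions, and the five-tier gold class follows the latent
label (4/5 for pathogenic, 1/2 for benign) except for a configurable
fraction recorded as class 3 (VUS).

Default operating points are the BRCA1 column of the bundled published
benchmark, so simulated cohorts resemble that study's regime.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from typing import IO, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .variants import AMINO_ACIDS, Tool, ProteinVariant, ToolPrediction, VariantRecord

__all__ = [
    "CohortConfig",
    "ColumnSpec",
    "MsaConfig",
    "NormalComponent",
    "ToolOperatingPoint",
    "simulate_cohort",
    "simulate_msa",
    "write_fasta",
]

_AA_LIST = sorted(AMINO_ACIDS)


class ToolOperatingPoint(BaseModel):
    sensitivity: float = Field(ge=0.0, le=1.0)
    specificity: float = Field(ge=0.0, le=1.0)


class NormalComponent(BaseModel):
    mean: float
    sd: float = Field(gt=0.0)


class CohortConfig(BaseModel):
    """Parameters of a simulated variant cohort."""

    n_variants: int = Field(default=500, ge=1)
    prevalence: float = Field(default=0.2, ge=0.0, le=1.0)
    gene: str = "BRCA1"
    seed: int = 0
    #: (sensitivity, specificity) per predictor; defaults are the BRCA1
    #: operating points of the bundled published benchmark.
    tool_rates: dict[str, ToolOperatingPoint] = {
        "SIFT": ToolOperatingPoint(sensitivity=0.9545, specificity=0.4348),
        "PolyPhen2": ToolOperatingPoint(sensitivity=0.9091, specificity=0.3913),
        "PhD-SNP": ToolOperatingPoint(sensitivity=1.0, specificity=0.587),
        "SNPs&GO": ToolOperatingPoint(sensitivity=1.0, specificity=0.1739),
        "SNAP": ToolOperatingPoint(sensitivity=1.0, specificity=0.3152),
        "FATHMM": ToolOperatingPoint(sensitivity=0.3636, specificity=0.565),
        "I-Mutant": ToolOperatingPoint(sensitivity=0.6364, specificity=0.3261),
        "PANTHER": ToolOperatingPoint(sensitivity=0.9545, specificity=0.6848),
    }
    #: Fraction of PANTHER outputs missing (the tool often returns none).
    panther_missing_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    #: Fraction of gold classes overridden to 3 (VUS, excluded from metrics).
    class3_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    #: Force-field stability components (kcal/mol): high specificity /
    #: moderate sensitivity of the +3.0 cutoff.
    foldx_ddg: dict[str, NormalComponent] = {
        "pathogenic": NormalComponent(mean=3.5, sd=1.5),
        "benign": NormalComponent(mean=0.0, sd=1.0),
    }
    #: Magnitude components (kcal/mol) of the SVM stability channel; the
    #: sign is set by the drawn I-Mutant call so the sign rule recovers it.
    imutant_ddg_magnitude: dict[str, NormalComponent] = {
        "deleterious": NormalComponent(mean=1.0, sd=0.8),
        "neutral": NormalComponent(mean=0.3, sd=0.5),
    }
    #: Conservation-grade distributions over grades 1..9: pathogenic
    #: variants sit at conserved positions, benign ones spread low.
    conservation: dict[str, list[float]] = {
        "pathogenic": [0.01, 0.01, 0.02, 0.03, 0.05, 0.08, 0.15, 0.25, 0.40],
        "benign": [0.15, 0.15, 0.14, 0.12, 0.12, 0.10, 0.09, 0.07, 0.06],
    }

    @field_validator("conservation")
    @classmethod
    def _dists_sum_to_one(cls, v: dict[str, list[float]]) -> dict[str, list[float]]:
        for label, probs in v.items():
            if len(probs) != 9:
                raise ValueError(f"{label}: need 9 grade probabilities")
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{label}: probabilities must be >=0 and sum to 1")
        return v

    @model_validator(mode="after")
    def _known_tools(self) -> "CohortConfig":
        for name in self.tool_rates:
            Tool(name)  # raises on unknown tool names
        return self


def _draw_call_correct(rng: np.random.Generator, pathogenic: bool, point: ToolOperatingPoint) -> bool:
    """True -> tool calls deleterious."""
    if pathogenic:
        return rng.random() < point.sensitivity
    return rng.random() >= point.specificity


def _raw_output(rng: np.random.Generator, tool: Tool, deleterious: bool):
    """A native-scale raw output whose default harmonization equals the call."""
    if tool is Tool.SIFT:
        return float(rng.uniform(0.0, 0.0499)) if deleterious else float(rng.uniform(0.05, 1.0))
    if tool is Tool.POLYPHEN2:
        return "probably damaging" if deleterious else "benign"
    if tool in (Tool.PHD_SNP, Tool.SNPS_GO):
        return "Disease" if deleterious else "Neutral"
    if tool is Tool.SNAP:
        return "non-neutral" if deleterious else "neutral"
    if tool is Tool.FATHMM:
        return float(rng.uniform(-7.0, -1.5)) if deleterious else float(rng.uniform(-1.49, 5.0))
    if tool is Tool.PANTHER:
        return float(rng.uniform(-10.0, -3.01)) if deleterious else float(rng.uniform(-2.99, 0.0))
    raise ValueError(f"no native raw emission for {tool}")


def _random_variant(rng: np.random.Generator, gene: str, position: int) -> ProteinVariant:
    wt = _AA_LIST[rng.integers(20)]
    mut = _AA_LIST[rng.integers(20)]
    while mut == wt:
        mut = _AA_LIST[rng.integers(20)]
    return ProteinVariant(gene=gene, wt_aa=wt, position=position, mut_aa=mut)


def simulate_cohort(config: CohortConfig) -> list[VariantRecord]:
    """Draw a cohort of variant records with a latent truth column.

    Raw predictor outputs are emitted on each tool's native scale with
    harmonized calls left unset — the cohort exercises the same
    harmonization stage real tables go through.  The SVM stability
    channel's DDG is sign-consistent with its drawn call; positions are
    sequential so no duplicate (gene, variant) pairs arise.
    """
    rng = np.random.default_rng(config.seed)
    seq_tools = [
        Tool.SIFT, Tool.POLYPHEN2, Tool.PHD_SNP, Tool.SNPS_GO,
        Tool.SNAP, Tool.FATHMM, Tool.PANTHER,
    ]
    records: list[VariantRecord] = []
    for i in range(config.n_variants):
        pathogenic = rng.random() < config.prevalence
        label = "pathogenic" if pathogenic else "benign"
        rec = VariantRecord(
            variant=_random_variant(rng, config.gene, position=i + 1),
            truth=label,
        )
        for tool in seq_tools:
            point = config.tool_rates.get(tool.value)
            if point is None:
                continue
            deleterious = _draw_call_correct(rng, pathogenic, point)
            if tool is Tool.PANTHER and rng.random() < config.panther_missing_rate:
                continue  # tool returned nothing
            rec.set_prediction(
                ToolPrediction(tool=tool, raw=_raw_output(rng, tool, deleterious), call=None)
            )
        # SVM stability channel: call first, then a sign-consistent DDG
        im_point = config.tool_rates.get(Tool.IMUTANT.value)
        if im_point is not None:
            im_deleterious = _draw_call_correct(rng, pathogenic, im_point)
            comp = config.imutant_ddg_magnitude[
                "deleterious" if im_deleterious else "neutral"
            ]
            magnitude = abs(rng.normal(comp.mean, comp.sd)) + 1e-6
            rec.imutant_ddg = -magnitude if im_deleterious else magnitude
        # force-field channel: label-component mixture
        comp = config.foldx_ddg[label]
        rec.foldx_ddg = float(rng.normal(comp.mean, comp.sd))
        # conservation grade
        probs = config.conservation[label]
        rec.consurf = int(rng.choice(np.arange(1, 10), p=probs))
        # five-tier gold class
        if rng.random() < config.class3_fraction:
            rec.gold = 3
        elif pathogenic:
            rec.gold = int(rng.choice([4, 5]))
        else:
            rec.gold = int(rng.choice([1, 2]))
        records.append(rec)
    return records


class ColumnSpec(BaseModel):
    """One alignment column: residues allowed across orthologs + reference."""

    allowed: list[str] = Field(min_length=1)
    reference: str

    @field_validator("allowed")
    @classmethod
    def _standard_allowed(cls, v: list[str]) -> list[str]:
        bad = [a for a in v if a.upper() not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"nonstandard residues in allowed set: {bad}")
        return [a.upper() for a in v]

    @field_validator("reference")
    @classmethod
    def _standard_reference(cls, v: str) -> str:
        if v.upper() not in AMINO_ACIDS:
            raise ValueError(f"nonstandard reference residue: {v!r}")
        return v.upper()


class MsaConfig(BaseModel):
    n_sequences: int = Field(default=20, ge=1)
    columns: list[ColumnSpec] = Field(min_length=1)
    seed: int = 0


def simulate_msa(config: MsaConfig) -> list[tuple[str, str]]:
    """Draw an aligned set of (id, sequence) pairs, reference first.

    The reference sequence spells out the per-column reference residues;
    every other sequence draws each column independently from that
    column's allowed set.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    ref = "".join(spec.reference for spec in config.columns)
    sequences = [("reference", ref)]
    for i in range(config.n_sequences - 1):
        seq = "".join(
            spec.allowed[rng.integers(len(spec.allowed))] for spec in config.columns
        )
        sequences.append((f"ortholog{i + 1}", seq))
    return sequences


def write_fasta(
    sequences: Sequence[tuple[str, str]], sink: Union[str, IO[str]]
) -> None:
    """Write (id, sequence) pairs as FASTA."""
    lines = [f">{name}\n{seq}\n" for name, seq in sequences]
    if hasattr(sink, "write"):
        sink.write("".join(lines))
    else:
        with open(sink, "w") as fh:
            fh.write("".join(lines))
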