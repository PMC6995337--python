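"""End-to-end orchestration of the consensus analysis.

Stage order: ingest -> harmonize -> GV/GD -> stability -> rank ->
extreme flag -> benchmark -> conservation -> report.  Stages whose
inputs are absent (no alignment, no stability channel, no gold column)
are skipped and the report says so; the output is a pure function of
(inputs, config).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from . import __version__
from .consensus import (
    HarmonizationConfig,
    flag_extremely_deleterious,
    harmonize_call,
    rank_variant,
    summarize_distribution,
)
from .conservation import compare_conservation
from .gvgd import GvgdGrid, ProteinAlignment, score_variant
from .metrics import evaluate_all
from .stability import FOLDX_DEFAULT_CUTOFF, foldx_binary_call, imutant_binary_call
from .variants import (
    VOTE_TOOLS,
    Tool,
    ToolPrediction,
    VariantRecord,
    read_variant_table,
    write_results,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "annotate_records"]

logger = logging.getLogger(__name__)

_SEQ_TOOLS = (
    Tool.SIFT,
    Tool.POLYPHEN2,
    Tool.PHD_SNP,
    Tool.SNPS_GO,
    Tool.SNAP,
    Tool.FATHMM,
    Tool.PANTHER,
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, detail: str, record: Optional[VariantRecord] = None):
        self.stage = stage
        self.record = record
        where = f" at {record.variant}" if record is not None else ""
        super().__init__(f"stage {stage!r} failed{where}: {detail}")


class PipelineConfig(BaseModel):
    """Paths and thresholds for a pipeline run."""

    variant_table: str
    msa: Optional[str] = None
    harmonization: Optional[str] = None  # JSON path; default bundled config
    gvgd_grid: Optional[str] = None  # JSON path; default bundled grid
    output_dir: str = "."
    sep: str = "\t"
    imutant_mode: str = Field(default="sign", pattern="^(sign|band)$")
    foldx_cutoff: float = FOLDX_DEFAULT_CUTOFF
    check_reference: bool = True

    def config_hash(self) -> str:
        # where outputs land does not change what is computed
        payload = self.model_dump(exclude={"output_dir"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _harmonize_stage(
    records: Sequence[VariantRecord],
    config: HarmonizationConfig,
    imutant_mode: str,
    foldx_cutoff: float,
) -> None:
    for rec in records:
        try:
            for tool in _SEQ_TOOLS:
                pred = rec.predictions.get(tool)
                if pred is not None and pred.call is None:
                    rec.set_prediction(
                        ToolPrediction(
                            tool=tool,
                            raw=pred.raw,
                            call=harmonize_call(tool, pred.raw, config),
                        )
                    )
            if rec.imutant_ddg is not None:
                rec.set_prediction(
                    ToolPrediction(
                        tool=Tool.IMUTANT,
                        raw=rec.imutant_ddg,
                        call=imutant_binary_call(rec.imutant_ddg, imutant_mode),
                    )
                )
            if rec.foldx_ddg is not None:
                rec.set_prediction(
                    ToolPrediction(
                        tool=Tool.FOLDX,
                        raw=rec.foldx_ddg,
                        call=foldx_binary_call(rec.foldx_ddg, cutoff=foldx_cutoff),
                    )
                )
        except ValueError as err:
            raise PipelineError("harmonize", str(err), rec) from err


def _gvgd_stage(
    records: Sequence[VariantRecord],
    alignment: ProteinAlignment,
    grid: GvgdGrid,
    check_reference: bool,
) -> None:
    for rec in records:
        try:
            result = score_variant(
                alignment, rec.variant, grid, check_reference=check_reference
            )
        except ValueError as err:
            raise PipelineError("gvgd", str(err), rec) from err
        rec.gv, rec.gd, rec.gvgd_grade = result.gv, result.gd, result.grade
        rec.set_prediction(
            ToolPrediction(tool=Tool.ALIGN_GVGD, raw=result.grade, call=result.call)
        )


def _rank_stage(records: Sequence[VariantRecord]) -> None:
    for rec in records:
        calls = {t: rec.call(t) for t in VOTE_TOOLS}
        result = rank_variant(calls)
        rec.n_deleterious = result.n_deleterious
        rec.rank = result.rank
        rec.deleterious_consensus = result.deleterious_consensus
        rec.extremely_deleterious = flag_extremely_deleterious(calls, rec.gvgd_grade)


def annotate_records(
    records: Sequence[VariantRecord],
    *,
    harmonization: Optional[HarmonizationConfig] = None,
    alignment: Optional[ProteinAlignment] = None,
    grid: Optional[GvgdGrid] = None,
    imutant_mode: str = "sign",
    foldx_cutoff: float = FOLDX_DEFAULT_CUTOFF,
    check_reference: bool = True,
) -> None:
    """Harmonize, score and rank records in place (no file I/O)."""
    _harmonize_stage(
        records, harmonization or HarmonizationConfig.default(), imutant_mode, foldx_cutoff
    )
    if alignment is not None:
        _gvgd_stage(records, alignment, grid or GvgdGrid.default(), check_reference)
    _rank_stage(records)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write the annotated table and a JSON report.

    Returns the report dict.  The report bundles the per-tool
    deleterious/neutral distribution, the gold-standard benchmark
    (when a gold column is present), the conservation comparison of
    consensus-deleterious vs consensus-neutral variants (when grades
    are present), and run provenance (version, config hash).
    """
    try:
        records = read_variant_table(config.variant_table, sep=config.sep)
    except (OSError, ValueError) as err:
        raise PipelineError("ingest", str(err)) from err

    harmonization = (
        HarmonizationConfig.from_file(config.harmonization)
        if config.harmonization
        else HarmonizationConfig.default()
    )
    grid = GvgdGrid.from_file(config.gvgd_grid) if config.gvgd_grid else GvgdGrid.default()
    alignment = ProteinAlignment.from_fasta(config.msa) if config.msa else None

    annotate_records(
        records,
        harmonization=harmonization,
        alignment=alignment,
        grid=grid,
        imutant_mode=config.imutant_mode,
        foldx_cutoff=config.foldx_cutoff,
        check_reference=config.check_reference,
    )

    report: dict = {
        "missensus_version": __version__,
        "config_hash": config.config_hash(),
        "n_records": len(records),
        "imutant_mode": config.imutant_mode,
        "foldx_cutoff": config.foldx_cutoff,
        "n_extremely_deleterious": sum(
            1 for r in records if r.extremely_deleterious
        ),
        "distribution": json.loads(
            summarize_distribution(records).to_json(orient="index")
        ),
    }

    if any(r.gold is not None for r in records):
        metrics = evaluate_all(records)
        report["benchmark"] = metrics.to_dict()
    else:
        logger.info("no gold column: benchmark stage skipped")

    del_grades = [
        r.consurf for r in records if r.deleterious_consensus and r.consurf is not None
    ]
    neu_grades = [
        r.consurf
        for r in records
        if r.deleterious_consensus is False and r.consurf is not None
    ]
    if del_grades and neu_grades:
        report["conservation"] = compare_conservation(del_grades, neu_grades).to_dict()
    else:
        logger.info("conservation stage skipped: a group has no grades")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(records, str(outdir / "annotated.tsv"), sep=config.sep)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
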