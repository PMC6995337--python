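"""Confusion-matrix benchmarking against a five-tier gold standard.

The gold standard is the IARC-style five-tier clinical classification:
classes 4-5 (likely pathogenic / pathogenic) are positives, classes 1-2
(benign / likely benign) negatives, and class 3 (VUS) is excluded from
evaluation.  Any binary predictor column — a single tool or the vote
consensus — is scored by sensitivity, specificity and the Matthews
correlation coefficient

    MCC = (Tp*Tn - Fp*Fn) / sqrt((Tp+Fp)(Tp+Fn)(Tn+Fp)(Tn+Fn)),

which equals the Pearson correlation of the two binary indicator
vectors.  Metrics with a zero denominator are signalled as undefined,
never silently reported as 0 or 1.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .consensus import rank_variant
from .variants import VOTE_TOOLS, Call, Tool, VariantRecord

__all__ = [
    "ConfusionMatrix",
    "GoldLabel",
    "MetricsReport",
    "UndefinedMetricError",
    "binarize_gold",
    "confusion",
    "evaluate_all",
    "mcc",
    "reference_benchmark",
    "sensitivity",
    "specificity",
]


def reference_benchmark() -> dict:
    """Bundled published benchmark of eight predictors on BRCA1/BRCA2.

    Per gene and tool: the confusion counts against the binarized
    five-tier gold standard together with the metric values as printed
    in the source table (strings, preserving printed precision), plus
    per-gene deleterious-call counts over the full retrieved cohorts.
    """
    text = (
        resources.files("missensus")
        .joinpath("data/reference_benchmark.json")
        .read_text()
    )
    return json.loads(text)


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; names the offending marginal."""


class GoldLabel(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"


def binarize_gold(gold: int) -> GoldLabel:
    """Five-tier class to truth label: 4/5 positive, 1/2 negative, 3 excluded."""
    if gold in (4, 5):
        return GoldLabel.POSITIVE
    if gold in (1, 2):
        return GoldLabel.NEGATIVE
    if gold == 3:
        return GoldLabel.EXCLUDED
    raise ValueError(f"gold class must be in 1..5, got {gold!r}")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    pred: Sequence[Optional[Call]], gold: Sequence[GoldLabel]
) -> ConfusionMatrix:
    """Tabulate aligned prediction/truth pairs.

    Pairs with a missing prediction or an excluded truth label are
    dropped; at least one evaluable pair is required.
    """
    if len(pred) != len(gold):
        raise ValueError(f"length mismatch: {len(pred)} predictions, {len(gold)} labels")
    tp = tn = fp = fn = 0
    for p, g in zip(pred, gold):
        if p is None or g is GoldLabel.EXCLUDED:
            continue
        if g is GoldLabel.POSITIVE:
            if p is Call.DELETERIOUS:
                tp += 1
            else:
                fn += 1
        else:
            if p is Call.DELETERIOUS:
                fp += 1
            else:
                tn += 1
    if tp + tn + fp + fn == 0:
        raise ValueError("no evaluable prediction/truth pairs")
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def sensitivity(cm: ConfusionMatrix) -> float:
    """Tp / (Tp + Fn), as a percentage."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: Tp + Fn = 0")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """Tn / (Tn + Fp), as a percentage."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: Tn + Fp = 0")
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient, in [-1, 1]."""
    marginals = {
        "Tp+Fp": cm.tp + cm.fp,
        "Tp+Fn": cm.tp + cm.fn,
        "Tn+Fp": cm.tn + cm.fp,
        "Tn+Fn": cm.tn + cm.fn,
    }
    zero = [name for name, value in marginals.items() if value == 0]
    if zero:
        raise UndefinedMetricError(f"MCC undefined: zero marginal(s) {zero}")
    denom = math.sqrt(math.prod(float(v) for v in marginals.values()))
    return (cm.tp * cm.tn - cm.fp * cm.fn) / denom


@dataclass
class MetricsReport:
    """Per-classifier metrics table plus the underlying counts."""

    table: pd.DataFrame  # index: classifier; columns: tp..mcc, n_evaluable, n_dropped
    matrices: dict[str, ConfusionMatrix]

    def to_dict(self) -> dict:
        return {
            name: {
                **{k: int(v) for k, v in row.items() if k in ("tp", "tn", "fp", "fn", "n_evaluable", "n_dropped")},
                **{
                    k: (None if pd.isna(row[k]) else float(row[k]))
                    for k in ("sensitivity_pct", "specificity_pct", "mcc")
                },
            }
            for name, row in self.table.iterrows()
        }


def _record_gold(rec: VariantRecord) -> Optional[GoldLabel]:
    return None if rec.gold is None else binarize_gold(rec.gold)


def evaluate_all(
    records: Sequence[VariantRecord],
    tools: Optional[Sequence[Tool]] = None,
    *,
    include_consensus: bool = True,
) -> MetricsReport:
    """Benchmark each tool's calls (and the vote consensus) against gold.

    Per classifier, pairs lacking either a call or a usable gold label
    are dropped and counted in ``n_dropped``.  Metrics whose
    denominator is zero are reported as NaN in the table (the scalar
    functions raise instead).
    """
    if tools is None:
        tools = list(VOTE_TOOLS) + [Tool.PANTHER]
    golds = [_record_gold(rec) for rec in records]
    if all(g is None for g in golds):
        raise ValueError("no record has a gold class")
    gold_labels = [GoldLabel.EXCLUDED if g is None else g for g in golds]

    classifiers: dict[str, list[Optional[Call]]] = {
        tool.value: [rec.call(tool) for rec in records] for tool in tools
    }
    if include_consensus:
        classifiers["consensus"] = [
            Call.DELETERIOUS
            if rank_variant(
                {t: rec.call(t) for t in VOTE_TOOLS}
            ).deleterious_consensus
            else Call.NEUTRAL
            for rec in records
        ]

    rows = []
    matrices: dict[str, ConfusionMatrix] = {}
    for name, preds in classifiers.items():
        try:
            cm = confusion(preds, gold_labels)
        except ValueError:
            cm = ConfusionMatrix(0, 0, 0, 0)  # tool produced no evaluable pair
        matrices[name] = cm
        row: dict[str, object] = {
            "classifier": name,
            "tp": cm.tp,
            "tn": cm.tn,
            "fp": cm.fp,
            "fn": cm.fn,
            "n_evaluable": cm.total,
            "n_dropped": len(records) - cm.total,
        }
        for key, fn in (
            ("sensitivity_pct", sensitivity),
            ("specificity_pct", specificity),
            ("mcc", mcc),
        ):
            try:
                row[key] = fn(cm)
            except UndefinedMetricError:
                row[key] = float("nan")
        rows.append(row)
    return MetricsReport(
        table=pd.DataFrame(rows).set_index("classifier"), matrices=matrices
    )
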