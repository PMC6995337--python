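"""Harmonization of tool outputs and the vote-rank consensus.

Seven predictors vote: SIFT, PhD-SNP, PolyPhen2, SNPs&GO, SNAP, FATHMM
and the SVM stability channel (I-Mutant).  The number of deleterious
votes n maps onto four ranks — n in {0,1}: rank 1, {2,3}: rank 2,
{4,5}: rank 3, {6,7}: rank 4 — and ranks 3-4 constitute the deleterious
consensus.  A variant is *extremely deleterious* when all seven voters
call it deleterious **and** its GV/GD grade is in the deleterious set
{C45, C55, C65}.

PANTHER is harmonized and summarized alongside the voters but never
votes (it frequently returns no score).  Missing votes count as
non-deleterious; the ``n_missing`` field lets callers filter on
completeness instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .gvgd import DELETERIOUS_GRADES, GRADES
from .variants import VOTE_TOOLS, Call, Tool, VariantRecord

__all__ = [
    "HarmonizationConfig",
    "HarmonizationError",
    "RankResult",
    "flag_extremely_deleterious",
    "harmonize_call",
    "rank_variant",
    "summarize_distribution",
]

logger = logging.getLogger(__name__)


class HarmonizationError(ValueError):
    """A raw tool output could not be mapped to a binary call."""


@dataclass(frozen=True)
class _ToolRule:
    op: Optional[str] = None
    cutoff: Optional[float] = None
    deleterious_labels: frozenset[str] = frozenset()
    neutral_labels: frozenset[str] = frozenset()


_OPS = {
    "lt": lambda x, c: x < c,
    "le": lambda x, c: x <= c,
    "gt": lambda x, c: x > c,
    "ge": lambda x, c: x >= c,
}


class HarmonizationConfig:
    """Per-tool rules mapping native scores/labels to binary calls."""

    def __init__(self, rules: Mapping[Tool, _ToolRule]):
        self.rules = dict(rules)

    @classmethod
    def default(cls) -> "HarmonizationConfig":
        text = (
            resources.files("missensus")
            .joinpath("data/harmonization.json")
            .read_text()
        )
        return cls.from_json(text)

    @classmethod
    def from_json(cls, text: str) -> "HarmonizationConfig":
        spec = json.loads(text)
        rules = {}
        for name, rule in spec["tools"].items():
            rules[Tool(name)] = _ToolRule(
                op=rule.get("op"),
                cutoff=rule.get("cutoff"),
                deleterious_labels=frozenset(
                    s.lower() for s in rule.get("deleterious_labels", [])
                ),
                neutral_labels=frozenset(
                    s.lower() for s in rule.get("neutral_labels", [])
                ),
            )
        return cls(rules)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "HarmonizationConfig":
        return cls.from_json(Path(path).read_text())


def harmonize_call(
    tool: Tool,
    raw: Union[float, str, None],
    config: Optional[HarmonizationConfig] = None,
) -> Optional[Call]:
    """Map one tool's native output to deleterious/neutral.

    ``None`` (or NaN) raw output yields a missing call.  Unrecognized
    labels or tools without a configured rule raise
    :class:`HarmonizationError` naming the tool and the value.
    """
    if raw is None:
        return None
    config = config or HarmonizationConfig.default()
    rule = config.rules.get(tool)
    if rule is None:
        raise HarmonizationError(f"no harmonization rule for tool {tool.value}")
    if isinstance(raw, (int, float)):
        if raw != raw:  # NaN
            return None
        if rule.op is None or rule.cutoff is None:
            raise HarmonizationError(
                f"{tool.value}: numeric output {raw!r} but rule has no cutoff"
            )
        return (
            Call.DELETERIOUS if _OPS[rule.op](float(raw), rule.cutoff) else Call.NEUTRAL
        )
    label = str(raw).strip().lower()
    if label == "":
        return None
    if label in rule.deleterious_labels:
        return Call.DELETERIOUS
    if label in rule.neutral_labels:
        return Call.NEUTRAL
    # labels that are themselves numbers (e.g. "0.03" read from text)
    try:
        return harmonize_call(tool, float(label), config)
    except (ValueError, HarmonizationError) as err:
        if isinstance(err, HarmonizationError):
            raise
        raise HarmonizationError(
            f"{tool.value}: unrecognized output {raw!r}"
        ) from None


@dataclass(frozen=True)
class RankResult:
    """Vote aggregate over the seven consensus predictors."""

    n_deleterious: int
    n_missing: int
    rank: int
    deleterious_consensus: bool

    def __post_init__(self) -> None:
        assert 0 <= self.n_deleterious <= 7 and 1 <= self.rank <= 4


def rank_variant(calls: Mapping[Tool, Optional[Call]]) -> RankResult:
    """Aggregate the seven vote tools' calls into a rank.

    Missing calls count as non-deleterious votes and are tallied in
    ``n_missing``.  Calls from non-vote tools raise ``ValueError``.
    """
    extra = set(calls) - set(VOTE_TOOLS)
    if extra:
        names = sorted(t.value for t in extra)
        raise ValueError(f"non-vote tool(s) in vote set: {names}")
    n_del = sum(1 for t in VOTE_TOOLS if calls.get(t) is Call.DELETERIOUS)
    n_missing = sum(1 for t in VOTE_TOOLS if calls.get(t) is None)
    # {0,1}->1, {2,3}->2, {4,5}->3, {6,7}->4
    rank = n_del // 2 + 1
    return RankResult(
        n_deleterious=n_del,
        n_missing=n_missing,
        rank=rank,
        deleterious_consensus=rank >= 3,
    )


def flag_extremely_deleterious(
    calls: Mapping[Tool, Optional[Call]], gvgd_grade: Optional[str]
) -> bool:
    """All seven voters deleterious and GV/GD grade in {C45, C55, C65}.

    Any missing vote or missing/neutral grade yields False (with the
    reason logged), never an error: the flag is a conjunction over all
    eight predictors.
    """
    if gvgd_grade is None:
        logger.debug("extreme flag false: GV/GD grade missing")
        return False
    if gvgd_grade not in GRADES:
        raise ValueError(f"unknown GV/GD grade: {gvgd_grade!r}")
    missing = [t.value for t in VOTE_TOOLS if calls.get(t) is None]
    if missing:
        logger.debug("extreme flag false: missing call(s) from %s", missing)
        return False
    if any(calls[t] is not Call.DELETERIOUS for t in VOTE_TOOLS):
        return False
    return gvgd_grade in DELETERIOUS_GRADES


def summarize_distribution(
    records: Sequence[VariantRecord],
    tools: Optional[Sequence[Tool]] = None,
) -> pd.DataFrame:
    """Per-tool deleterious/neutral/missing counts and percentages.

    Percentages are of non-missing calls, NaN when a tool returned
    nothing; counts always satisfy n_deleterious + n_neutral +
    n_missing = len(records).
    """
    if tools is None:
        tools = list(VOTE_TOOLS) + [Tool.PANTHER]
    rows = []
    for tool in tools:
        calls = [rec.call(tool) for rec in records]
        n_del = sum(1 for c in calls if c is Call.DELETERIOUS)
        n_neu = sum(1 for c in calls if c is Call.NEUTRAL)
        n_mis = sum(1 for c in calls if c is None)
        n_obs = n_del + n_neu
        rows.append(
            {
                "tool": tool.value,
                "n_deleterious": n_del,
                "n_neutral": n_neu,
                "n_missing": n_mis,
                "pct_deleterious": 100.0 * n_del / n_obs if n_obs else float("nan"),
                "pct_neutral": 100.0 * n_neu / n_obs if n_obs else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("tool")
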