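"""Threshold rules for protein-stability predictions.

Two stability channels feed the pipeline, both expressed as a folding
free-energy change in kcal/mol:

* the sequence/SVM channel (I-Mutant style), banded into a large
  decrease (< -0.5), neutral (-0.5..0.5 inclusive) and a large increase
  (> 0.5); and
* the force-field channel (FoldX style), where DDG = DG(mutant) -
  DG(wild-type) and a change above a configurable cutoff (default
  +3.0 kcal/mol) is treated as highly destabilizing and flagged
  pathogenic.

The SVM channel exposes two binary modes: ``sign`` (deleterious iff
DDG < 0, i.e. any predicted destabilization) and ``band`` (deleterious
only on a large decrease).
"""

from __future__ import annotations

import enum
import math

from .variants import Call

__all__ = [
    "FOLDX_DEFAULT_CUTOFF",
    "FoldxCategory",
    "ImutantBand",
    "classify_foldx",
    "classify_imutant",
    "foldx_binary_call",
    "imutant_binary_call",
]

FOLDX_DEFAULT_CUTOFF = 3.0  # kcal/mol


class ImutantBand(str, enum.Enum):
    LARGE_DECREASE = "large_decrease"
    NEUTRAL = "neutral"
    LARGE_INCREASE = "large_increase"


class FoldxCategory(str, enum.Enum):
    STABILIZING = "stabilizing"
    # DDG exactly 0 is outside both published half-lines; kept explicit.
    NEUTRAL_ZERO = "neutral_zero"
    DESTABILIZING = "destabilizing"
    HIGHLY_DESTABILIZING = "highly_destabilizing"


def _require_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")
    return value


def classify_imutant(ddg: float) -> ImutantBand:
    """Band a predicted stability change; +-0.5 is inclusive into neutral."""
    ddg = _require_finite(ddg, "ddg")
    if ddg < -0.5:
        return ImutantBand.LARGE_DECREASE
    if ddg > 0.5:
        return ImutantBand.LARGE_INCREASE
    return ImutantBand.NEUTRAL


def imutant_binary_call(ddg: float, mode: str = "sign") -> Call:
    """Binary verdict from the SVM stability channel.

    ``sign``: deleterious iff ddg < 0 (any predicted loss of stability).
    ``band``: deleterious iff the band is a large decrease (< -0.5).
    """
    ddg = _require_finite(ddg, "ddg")
    if mode == "sign":
        return Call.DELETERIOUS if ddg < 0 else Call.NEUTRAL
    if mode == "band":
        return (
            Call.DELETERIOUS
            if classify_imutant(ddg) is ImutantBand.LARGE_DECREASE
            else Call.NEUTRAL
        )
    raise ValueError(f"unknown I-Mutant binary mode: {mode!r}")


def classify_foldx(
    ddg_wt: float | None = None,
    ddg_mt: float | None = None,
    *,
    ddg: float | None = None,
    cutoff: float = FOLDX_DEFAULT_CUTOFF,
) -> FoldxCategory:
    """Categorize a force-field stability change.

    Either pass the wild-type and mutant free energies (DDG is their
    difference, mutant minus wild-type) or DDG directly.  DDG < 0 is
    stabilizing, 0 < DDG <= cutoff destabilizing, DDG > cutoff highly
    destabilizing; DDG == 0 is an explicit neutral-zero category.
    """
    if ddg is None:
        if ddg_wt is None or ddg_mt is None:
            raise ValueError("pass either (ddg_wt, ddg_mt) or ddg=")
        ddg = _require_finite(ddg_mt, "ddg_mt") - _require_finite(ddg_wt, "ddg_wt")
    else:
        ddg = _require_finite(ddg, "ddg")
    cutoff = _require_finite(cutoff, "cutoff")
    if ddg < 0:
        return FoldxCategory.STABILIZING
    if ddg == 0:
        return FoldxCategory.NEUTRAL_ZERO
    if ddg > cutoff:
        return FoldxCategory.HIGHLY_DESTABILIZING
    return FoldxCategory.DESTABILIZING


def foldx_binary_call(
    ddg: float, *, cutoff: float = FOLDX_DEFAULT_CUTOFF
) -> Call:
    """Deleterious iff the change exceeds the highly-destabilizing cutoff."""
    category = classify_foldx(ddg=ddg, cutoff=cutoff)
    return (
        Call.DELETERIOUS
        if category is FoldxCategory.HIGHLY_DESTABILIZING
        else Call.NEUTRAL
    )
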