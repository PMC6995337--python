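"""Evolutionary-conservation grades and the deleterious-vs-neutral comparison.

Conservation grades are ordinal 1-9 (1 rapidly evolving / variable,
5 average, 9 slowly evolving / conserved).  Because the scale is
ordinal with heavy ties, groups are compared with a rank-based
two-sample test (Mann-Whitney U, two-sided, normal approximation with
tie correction); the effect is summarized by the common-language effect
size P(random deleterious grade > random neutral grade), counting ties
as half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConservationComparison",
    "bin_grade",
    "compare_conservation",
]


def bin_grade(grade: int) -> str:
    """Report bin of a grade: 1-3 variable, 4-6 average, 7-9 conserved."""
    if not isinstance(grade, (int, np.integer)) or not 1 <= grade <= 9:
        raise ValueError(f"conservation grade must be an integer 1..9, got {grade!r}")
    if grade <= 3:
        return "variable"
    if grade <= 6:
        return "average"
    return "conserved"


@dataclass(frozen=True)
class ConservationComparison:
    n_deleterious: int
    n_neutral: int
    median_deleterious: float
    median_neutral: float
    u_statistic: float
    effect_size: float  # P(deleterious grade > neutral grade) + 0.5*P(tie)
    p_value: float
    direction: str  # deleterious_more_conserved / neutral_more_conserved / none
    test: str = "mann-whitney-u (two-sided, tie-corrected normal approximation)"

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "n_deleterious": self.n_deleterious,
            "n_neutral": self.n_neutral,
            "median_deleterious": self.median_deleterious,
            "median_neutral": self.median_neutral,
            "u_statistic": self.u_statistic,
            "effect_size": self.effect_size,
            "p_value": self.p_value,
            "direction": self.direction,
        }


def compare_conservation(
    deleterious_grades: Sequence[int], neutral_grades: Sequence[int]
) -> ConservationComparison:
    """Rank-based comparison of the two groups' grade distributions.

    Antisymmetric in its arguments: swapping the groups flips the
    direction, maps the effect size e to 1 - e and leaves the (two-
    sided) p-value unchanged.
    """
    for name, grades in (
        ("deleterious", deleterious_grades),
        ("neutral", neutral_grades),
    ):
        if len(grades) == 0:
            raise ValueError(f"{name} grade list is empty")
        for g in grades:
            bin_grade(int(g))  # validates 1..9
    x = np.asarray(deleterious_grades, dtype=float)
    y = np.asarray(neutral_grades, dtype=float)
    if np.all(np.concatenate([x, y]) == x[0]):
        # every grade identical: exchangeable by construction
        u1, p = len(x) * len(y) / 2.0, 1.0
    else:
        u1, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = min(float(p), 1.0)
    effect = float(u1) / (len(x) * len(y))
    if effect > 0.5:
        direction = "deleterious_more_conserved"
    elif effect < 0.5:
        direction = "neutral_more_conserved"
    else:
        direction = "none"
    return ConservationComparison(
        n_deleterious=len(x),
        n_neutral=len(y),
        median_deleterious=float(np.median(x)),
        median_neutral=float(np.median(y)),
        u_statistic=float(u1),
        effect_size=effect,
        p_value=float(p),
        direction=direction,
    )
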