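"""Grantham physicochemical distance between amino acids.

The distance combines three residue properties — composition ``c``
(atomic weight ratio of non-carbon side-chain atoms), polarity ``p``
and molecular volume ``v`` — in the quadratic form

    D(a, b) = rho * sqrt(alpha*(c_a-c_b)^2 + beta*(p_a-p_b)^2 + gamma*(v_a-v_b)^2)

with the original 1974 constants alpha = 1.833, beta = 0.1018,
gamma = 0.000399 and rho = 50.723, chosen so the mean distance over all
190 residue pairs is 100.  Rounding D to the nearest integer reproduces
the published 20x20 matrix.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

__all__ = [
    "ALPHA",
    "BETA",
    "GAMMA",
    "RHO",
    "PROPERTIES",
    "grantham_distance",
    "published_matrix",
]

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399
RHO = 50.723

#: (composition, polarity, volume) per residue, one-letter codes.
PROPERTIES: dict[str, tuple[float, float, float]] = {
    "A": (0.0, 8.1, 31.0),
    "C": (2.75, 5.5, 55.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "F": (0.0, 5.2, 132.0),
    "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0),
    "I": (0.0, 5.2, 111.0),
    "K": (0.33, 11.3, 119.0),
    "L": (0.0, 4.9, 111.0),
    "M": (0.0, 5.7, 105.0),
    "N": (1.33, 11.6, 56.0),
    "P": (0.39, 8.0, 32.5),
    "Q": (0.89, 10.5, 85.0),
    "R": (0.65, 10.5, 124.0),
    "S": (1.42, 9.2, 32.0),
    "T": (0.71, 8.6, 61.0),
    "V": (0.0, 5.9, 84.0),
    "W": (0.13, 5.4, 170.0),
    "Y": (0.2, 6.2, 136.0),
}


def _properties(aa: str) -> tuple[float, float, float]:
    try:
        return PROPERTIES[aa.upper()]
    except KeyError:
        raise ValueError(f"nonstandard residue: {aa!r}") from None


def grantham_distance(a: str, b: str) -> float:
    """Grantham distance between two residues (one-letter codes).

    Symmetric, zero iff ``a == b``; matches the published integer matrix
    to rounding.
    """
    ca, pa, va = _properties(a)
    cb, pb, vb = _properties(b)
    return RHO * float(
        np.sqrt(
            ALPHA * (ca - cb) ** 2 + BETA * (pa - pb) ** 2 + GAMMA * (va - vb) ** 2
        )
    )


def published_matrix() -> dict[tuple[str, str], int]:
    """The bundled 20x20 integer distance matrix, keyed both ways.

    Loaded from package data (``data/grantham_matrix.tsv``); the table
    is the rounded quadratic form over the bundled property constants
    and agrees with the widely reproduced published matrix.
    """
    text = (
        resources.files("missensus").joinpath("data/grantham_matrix.tsv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    out: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        cells = line.split("\t")
        row_aa = cells[0]
        for col_aa, cell in zip(header, cells[1:]):
            if cell != "":
                value = int(cell)
                out[(row_aa, col_aa)] = value
                out[(col_aa, row_aa)] = value
    return out
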