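import pytest

from missensus import CohortConfig, simulate_cohort
from missensus.pipeline import annotate_records


@pytest.fixture(scope="session")
def small_cohort():
    """200 simulated variants, harmonized and ranked (no alignment stage)."""
    records = simulate_cohort(CohortConfig(n_variants=200, seed=7))
    annotate_records(records)
    return records


def printed_decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def matches_printed(value: float, printed: str) -> bool:
    """Agreement at printed precision, allowing round-to-nearest or
    truncation toward zero (source tables use both)."""
    import math

    d = printed_decimals(printed)
    target = round(float(printed) * 10**d)
    scaled = value * 10**d
    return target in (round(scaled), math.trunc(scaled))
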