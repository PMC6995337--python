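"""Harmonization, the 128-vector vote oracle, and the extreme flag."""

import itertools

import pytest

from missensus import (
    Call,
    HarmonizationConfig,
    Tool,
    VOTE_TOOLS,
    flag_extremely_deleterious,
    harmonize_call,
    rank_variant,
    summarize_distribution,
)
from missensus.consensus import HarmonizationError
from missensus.gvgd import GRADES
from missensus.simulate import CohortConfig, simulate_cohort
from missensus.pipeline import annotate_records

D, N = Call.DELETERIOUS, Call.NEUTRAL

# the rank bins as published: votes -> rank
RANK_BINS = {0: 1, 1: 1, 2: 2, 3: 2, 4: 3, 5: 3, 6: 4, 7: 4}


def vector_calls(bits):
    return {tool: (D if b else N) for tool, b in zip(VOTE_TOOLS, bits)}


class TestHarmonize:
    @pytest.mark.parametrize(
        "tool,raw,call",
        [
            (Tool.SIFT, 0.01, D),
            (Tool.SIFT, 0.05, N),  # cutoff is strict less-than
            (Tool.SIFT, "0.2", N),  # numeric strings accepted
            (Tool.POLYPHEN2, "benign", N),
            (Tool.POLYPHEN2, "Probably Damaging", D),
            (Tool.SNAP, "non-neutral", D),
            (Tool.SNAP, "Neutral", N),
            (Tool.PHD_SNP, "Disease", D),
            (Tool.SNPS_GO, "Neutral", N),
            (Tool.FATHMM, -3.2, D),
            (Tool.FATHMM, 1.0, N),
            (Tool.PANTHER, -6.0, D),
        ],
    )
    def test_default_mappings(self, tool, raw, call):
        assert harmonize_call(tool, raw) is call

    def test_missing_raw_gives_missing_call(self):
        assert harmonize_call(Tool.SIFT, None) is None
        assert harmonize_call(Tool.SNAP, "") is None
        assert harmonize_call(Tool.SIFT, float("nan")) is None

    def test_unrecognized_label_names_tool_and_value(self):
        with pytest.raises(HarmonizationError, match="SNAP.*wobbly"):
            harmonize_call(Tool.SNAP, "wobbly")

    def test_tool_without_rule_rejected(self):
        with pytest.raises(HarmonizationError, match="ConSurf"):
            harmonize_call(Tool.CONSURF, 5)

    def test_config_is_editable(self):
        config = HarmonizationConfig.from_json(
            '{"tools": {"SIFT": {"op": "lt", "cutoff": 0.2}}}'
        )
        assert harmonize_call(Tool.SIFT, 0.1, config) is D


class TestRank:
    def test_agrees_with_bruteforce_over_all_128_vectors(self):
        for bits in itertools.product([0, 1], repeat=7):
            result = rank_variant(vector_calls(bits))
            assert result.n_deleterious == sum(bits)
            assert result.rank == RANK_BINS[sum(bits)]
            assert result.deleterious_consensus == (result.rank >= 3)

    @pytest.mark.parametrize(
        "n_del,rank,consensus",
        [(7, 4, True), (6, 4, True), (5, 3, True), (4, 3, True),
         (3, 2, False), (2, 2, False), (1, 1, False), (0, 1, False)],
    )
    def test_published_bins(self, n_del, rank, consensus):
        bits = [1] * n_del + [0] * (7 - n_del)
        result = rank_variant(vector_calls(bits))
        assert (result.rank, result.deleterious_consensus) == (rank, consensus)

    def test_missing_votes_count_as_neutral_and_are_tallied(self):
        calls = vector_calls([1] * 7)
        calls[Tool.FATHMM] = None
        result = rank_variant(calls)
        assert result.n_deleterious == 6 and result.n_missing == 1
        assert result.rank == 4

    def test_monotone_in_single_flips(self):
        for bits in itertools.product([0, 1], repeat=7):
            base = rank_variant(vector_calls(bits)).rank
            for i, b in enumerate(bits):
                if not b:
                    flipped = list(bits)
                    flipped[i] = 1
                    assert rank_variant(vector_calls(flipped)).rank >= base

    def test_non_vote_tool_rejected(self):
        calls = vector_calls([1] * 7)
        calls[Tool.PANTHER] = D
        with pytest.raises(ValueError, match="PANTHER"):
            rank_variant(calls)


class TestExtremeFlag:
    def test_all_grade_and_vote_combinations_imply_rank4(self):
        """extreme => all 7 votes deleterious and deleterious grade; over
        all 128 x 7 combinations the flag implies rank 4."""
        for bits in itertools.product([0, 1], repeat=7):
            calls = vector_calls(bits)
            for grade in GRADES:
                flag = flag_extremely_deleterious(calls, grade)
                expected = all(bits) and grade in ("C45", "C55", "C65")
                assert flag == expected
                if flag:
                    assert rank_variant(calls).rank == 4

    def test_missing_vote_or_grade_gives_false(self):
        calls = vector_calls([1] * 7)
        assert flag_extremely_deleterious(calls, None) is False
        calls[Tool.SNAP] = None
        assert flag_extremely_deleterious(calls, "C65") is False

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError):
            flag_extremely_deleterious(vector_calls([1] * 7), "C70")


class TestDistribution:
    def test_published_percentage_reproduced(self):
        """A cohort with 337 of 520 deleterious calls for a tool reports
        64.8% deleterious."""
        records = simulate_cohort(CohortConfig(n_variants=520, seed=3))
        annotate_records(records)
        for i, rec in enumerate(records):
            call = D if i < 337 else N
            pred = rec.predictions[Tool.SIFT]
            rec.predictions[Tool.SIFT] = type(pred)(
                tool=Tool.SIFT, raw=pred.raw, call=call
            )
        summary = summarize_distribution(records)
        assert summary.loc["SIFT", "n_deleterious"] == 337
        assert round(summary.loc["SIFT", "pct_deleterious"], 1) == 64.8

    def test_counts_conserve_per_tool(self, small_cohort):
        summary = summarize_distribution(small_cohort)
        for _, row in summary.iterrows():
            assert (
                row["n_deleterious"] + row["n_neutral"] + row["n_missing"]
                == len(small_cohort)
            )

    def test_percentages_sum_to_100(self, small_cohort):
        summary = summarize_distribution(small_cohort)
        observed = summary[summary["n_missing"] < len(small_cohort)]
        assert (
            (observed["pct_deleterious"] + observed["pct_neutral"]) - 100.0
        ).abs().max() < 1e-9

    def test_all_missing_tool_has_undefined_pct(self, small_cohort):
        import math

        # no stage ever sets a ConSurf prediction: everything is missing
        summary = summarize_distribution(small_cohort, tools=[Tool.CONSURF])
        assert summary.loc["ConSurf", "n_missing"] == len(small_cohort)
        assert math.isnan(summary.loc["ConSurf", "pct_deleterious"])

    def test_empty_record_list_gives_empty_summary(self):
        summary = summarize_distribution([])
        assert (summary["n_deleterious"] == 0).all()
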