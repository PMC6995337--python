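"""The synthetic-cohort and alignment generators."""

import io

import numpy as np
import pytest
from pydantic import ValidationError

from missensus import (
    Call,
    CohortConfig,
    MsaConfig,
    ProteinAlignment,
    VOTE_TOOLS,
    compute_gd,
    compute_gv,
    evaluate_all,
    simulate_cohort,
    simulate_msa,
    write_results,
)
from missensus.pipeline import annotate_records
from missensus.simulate import ColumnSpec, ToolOperatingPoint, write_fasta


class TestDeterminism:
    def test_same_seed_byte_identical_table(self):
        cfg = CohortConfig(n_variants=80, seed=123)
        out = []
        for _ in range(2):
            records = simulate_cohort(cfg)
            buf = io.StringIO()
            write_results(records, buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_different_seeds_differ(self):
        a = simulate_cohort(CohortConfig(n_variants=50, seed=1))
        b = simulate_cohort(CohortConfig(n_variants=50, seed=2))
        assert [r.truth for r in a] != [r.truth for r in b]

    def test_same_seed_byte_identical_fasta(self):
        cfg = MsaConfig(
            n_sequences=10,
            seed=9,
            columns=[ColumnSpec(allowed=["A", "V", "L"], reference="A")] * 12,
        )
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_fasta(simulate_msa(cfg), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]


class TestForcedOutcomes:
    def test_all_pathogenic_perfect_tools_gives_rank4(self):
        cfg = CohortConfig(
            n_variants=40,
            prevalence=1.0,
            seed=5,
            tool_rates={
                name: ToolOperatingPoint(sensitivity=1.0, specificity=1.0)
                for name in CohortConfig().tool_rates
            },
        )
        records = simulate_cohort(cfg)
        annotate_records(records)
        assert all(r.rank == 4 and r.n_deleterious == 7 for r in records)
        assert all(r.call(t) is Call.DELETERIOUS for r in records for t in VOTE_TOOLS)

    def test_all_benign_perfect_tools_gives_rank1(self):
        cfg = CohortConfig(
            n_variants=40,
            prevalence=0.0,
            seed=5,
            tool_rates={
                name: ToolOperatingPoint(sensitivity=1.0, specificity=1.0)
                for name in CohortConfig().tool_rates
            },
        )
        records = simulate_cohort(cfg)
        annotate_records(records)
        assert all(r.rank == 1 and r.n_deleterious == 0 for r in records)


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_tool_operating_points_recovered_at_n5000(self, seed):
        """Empirical per-tool sensitivity/specificity on a simulated cohort
        fall within 3 binomial SDs of the configured operating points."""
        cfg = CohortConfig(n_variants=5000, seed=seed, class3_fraction=0.0)
        records = simulate_cohort(cfg)
        annotate_records(records)
        report = evaluate_all(records)
        n_pos = sum(1 for r in records if r.truth == "pathogenic")
        n_neg = len(records) - n_pos
        for name, point in cfg.tool_rates.items():
            row = report.table.loc[name]
            for metric, p, n in (
                ("sensitivity_pct", point.sensitivity, n_pos),
                ("specificity_pct", point.specificity, n_neg),
            ):
                if name == "PANTHER":
                    n = row["tp" if metric == "sensitivity_pct" else "tn"] + row[
                        "fn" if metric == "sensitivity_pct" else "fp"
                    ]
                sd = np.sqrt(p * (1 - p) / n) if 0 < p < 1 else 0.0
                tol = max(3 * 100 * sd, 1e-9)
                assert abs(row[metric] - 100 * p) <= tol, (name, metric)

    def test_consensus_beats_worst_tool_when_all_informative(self):
        """With conditionally independent voters all better than chance,
        the consensus sensitivity exceeds the worst single tool's."""
        cfg = CohortConfig(
            n_variants=4000,
            seed=4,
            class3_fraction=0.0,
            tool_rates={
                name: ToolOperatingPoint(sensitivity=0.8, specificity=0.8)
                for name in CohortConfig().tool_rates
            },
        )
        records = simulate_cohort(cfg)
        annotate_records(records)
        table = evaluate_all(records).table
        vote_rows = table.loc[[t.value for t in VOTE_TOOLS]]
        assert (
            table.loc["consensus", "sensitivity_pct"]
            > vote_rows["sensitivity_pct"].min()
        )
        assert (
            table.loc["consensus", "specificity_pct"]
            > vote_rows["specificity_pct"].min()
        )

    def test_class3_records_change_no_metric(self):
        """VUS (class 3) records are excluded by gold binarization, so
        appending them is metric-neutral."""
        base = simulate_cohort(CohortConfig(n_variants=800, seed=6, class3_fraction=0.0))
        annotate_records(base)
        before = evaluate_all(base).table
        extra = simulate_cohort(CohortConfig(n_variants=200, seed=60))
        annotate_records(extra)
        for i, rec in enumerate(extra):
            rec.gold = 3
            rec.variant = type(rec.variant)(
                gene=rec.variant.gene,
                wt_aa=rec.variant.wt_aa,
                position=1000 + i,
                mut_aa=rec.variant.mut_aa,
            )
        after = evaluate_all(base + extra).table
        assert after.drop(columns="n_dropped").equals(
            before.drop(columns="n_dropped")
        )


class TestMsa:
    def test_invariant_column_gives_gv_zero_downstream(self):
        cfg = MsaConfig(
            n_sequences=8,
            seed=1,
            columns=[ColumnSpec(allowed=["C"], reference="C")] * 5,
        )
        buf = io.StringIO()
        write_fasta(simulate_msa(cfg), buf)
        buf.seek(0)
        aln = ProteinAlignment.from_fasta(buf)
        assert compute_gv(aln.column(3)) == 0.0

    def test_out_of_range_mutant_has_positive_gd(self):
        # G lies outside the A-V property ranges on all three axes
        cfg = MsaConfig(
            n_sequences=30,
            seed=2,
            columns=[ColumnSpec(allowed=["A", "V"], reference="A")],
        )
        sequences = simulate_msa(cfg)
        aln = ProteinAlignment([s for _, s in sequences], [n for n, _ in sequences])
        assert compute_gd(aln.column(1), "G") > 0.0

    def test_reference_emitted_first(self):
        cfg = MsaConfig(
            n_sequences=4,
            seed=3,
            columns=[
                ColumnSpec(allowed=["L", "I", "V"], reference="W"),
                ColumnSpec(allowed=["K"], reference="K"),
            ],
        )
        sequences = simulate_msa(cfg)
        assert sequences[0] == ("reference", "WK")
        assert all(seq[0] in "LIV" and seq[1] == "K" for _, seq in sequences[1:])


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(prevalence=1.5)
        with pytest.raises(ValidationError):
            CohortConfig(
                tool_rates={"SIFT": {"sensitivity": 2.0, "specificity": 0.5}}
            )

    def test_conservation_distribution_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            CohortConfig(conservation={"pathogenic": [0.5] * 9, "benign": [1 / 9] * 9})

    def test_unknown_tool_name_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(tool_rates={"NotATool": {"sensitivity": 1, "specificity": 1}})

    def test_empty_allowed_set_rejected(self):
        with pytest.raises(ValidationError):
            ColumnSpec(allowed=[], reference="A")
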