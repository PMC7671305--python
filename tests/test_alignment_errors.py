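"""Tests for error counting, profile aggregation and substitution matrices."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrprofile.alignment_errors import (
    ErrorCounts,
    aggregate_profile,
    count_errors,
    longest_perfect_run,
    profiles_to_tsv,
    substitution_matrix,
)
from lrprofile.io_formats import EditColumn, EditScript, expand_edit_script

from conftest import make_alignment, match_script, script_from_ops


class TestCountErrors:
    def test_perfect_alignment(self):
        c = count_errors(match_script(10))
        assert (c.n_match, c.n_sub, c.n_ins, c.n_del, c.n_ambiguous, c.n_columns) == (
            10, 0, 0, 0, 0, 10,
        )

    def test_mixed_indels_fixture(self):
        # manual expansion oracle: "3M1I2M1D4M" / "5^A4" -> (9,0,1,1,0,11)
        es = expand_edit_script(make_alignment("3M1I2M1D4M", "ACGTAGCTTA", md="5^A4"))
        c = count_errors(es)
        assert (c.n_match, c.n_sub, c.n_ins, c.n_del, c.n_ambiguous, c.n_columns) == (
            9, 0, 1, 1, 0, 11,
        )

    def test_substitution_fixture(self):
        # manual expansion oracle: "10M" / "4A5" -> (9,1,0,0,0,10)
        es = expand_edit_script(make_alignment("10M", "ACGTGCGTAC", md="4A5"))
        c = count_errors(es)
        assert (c.n_match, c.n_sub, c.n_ins, c.n_del, c.n_ambiguous, c.n_columns) == (
            9, 1, 0, 0, 0, 10,
        )

    def test_n_bases_ambiguous_not_errors(self):
        cols = [
            EditColumn("match", 1, 1, "A", "A"),
            EditColumn("sub", 2, 2, "N", "G"),
            EditColumn("match", 3, 3, "C", "N"),
        ]
        es = EditScript(cols, read_span=3, ref_span=3, read_length=3)
        c = count_errors(es)
        assert c.n_match == 1 and c.n_sub == 0 and c.n_ambiguous == 2


class TestLongestPerfectRun:
    def test_all_match(self):
        assert longest_perfect_run(match_script(10)) == 10

    def test_substitution_splits_runs(self):
        # runs of 4 and 5, maximum 5
        es = expand_edit_script(make_alignment("10M", "ACGTGCGTAC", md="4A5"))
        assert longest_perfect_run(es) == 5

    def test_insertion_splits_runs(self):
        # runs of 3 and 7
        es = expand_edit_script(make_alignment("3M1I7M", "ACGTACGTACG", md="10"))
        assert longest_perfect_run(es) == 7

    def test_ambiguous_breaks_run(self):
        cols = (
            [EditColumn("match", i + 1, i + 1, "A", "A") for i in range(4)]
            + [EditColumn("match", 5, 5, "N", "N")]
            + [EditColumn("match", i + 6, i + 6, "A", "A") for i in range(2)]
        )
        es = EditScript(cols, read_span=7, ref_span=7, read_length=7)
        assert longest_perfect_run(es) == 4


class TestAggregateProfile:
    def test_pooled_count_arithmetic(self):
        # oracle: pooled counts (10+8 match, 1 sub, 1 ins over 20 columns)
        s1 = match_script(10)
        s2 = script_from_ops("MMMMSMMMIM")
        prof = aggregate_profile([s1, s2], n_reads_total=2)
        assert prof.sub_pct == pytest.approx(5.0)
        assert prof.ins_pct == pytest.approx(5.0)
        assert prof.del_pct == pytest.approx(0.0)
        assert prof.total_pct == pytest.approx(10.0)

    def test_single_perfect_alignment(self):
        prof = aggregate_profile([match_script(100)], n_reads_total=1)
        assert prof.total_pct == 0
        assert prof.longest_perfect_match == 100
        assert prof.longest_alignment == 100
        assert prof.aligned_pct == 100.0

    def test_empty_profile_warns(self, caplog):
        prof = aggregate_profile([], n_reads_total=5)
        assert prof.sub_pct is None and prof.total_pct is None
        assert prof.n_reads_aligned == 0

    def test_stretch_of_longest_alignment(self):
        # ref_span 12 vs read_span 10 -> +20%
        s = script_from_ops("MMMMMMMMMMDD")
        prof = aggregate_profile([s], n_reads_total=1)
        assert prof.longest_alignment == 12
        assert prof.max_stretch_pct == pytest.approx(20.0)

    def test_pooled_rate_equals_bruteforce_concatenation(self):
        # brute-force oracle: concatenate all columns into one list and count
        scripts = [
            script_from_ops("MMSMIMD"),
            script_from_ops("MMMM"),
            script_from_ops("SSIDM"),
        ]
        all_cols = [c for s in scripts for c in s.columns]
        n_sub = sum(1 for c in all_cols if c.op == "sub")
        n_ins = sum(1 for c in all_cols if c.op == "ins")
        n_del = sum(1 for c in all_cols if c.op == "del")
        prof = aggregate_profile(scripts, n_reads_total=3)
        assert prof.sub_pct == pytest.approx(100 * n_sub / len(all_cols))
        assert prof.ins_pct == pytest.approx(100 * n_ins / len(all_cols))
        assert prof.del_pct == pytest.approx(100 * n_del / len(all_cols))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.text(alphabet="MSID", min_size=1, max_size=30), min_size=1, max_size=8))
    def test_rate_identity_property(self, op_strings):
        scripts = []
        for ops in op_strings:
            if not any(ch in "MSD" for ch in ops):
                ops += "M"
            scripts.append(script_from_ops(ops))
        prof = aggregate_profile(scripts, n_reads_total=len(scripts))
        assert prof.total_pct == pytest.approx(prof.sub_pct + prof.ins_pct + prof.del_pct)
        assert prof.longest_perfect_match <= prof.longest_alignment or prof.longest_alignment == 0

    def test_monotonicity_zero_error_alignment(self):
        base = [script_from_ops("MMSMIMD")]
        before = aggregate_profile(base, n_reads_total=1)
        after = aggregate_profile(base + [match_script(50)], n_reads_total=2)
        assert after.sub_pct <= before.sub_pct
        assert after.ins_pct <= before.ins_pct
        assert after.del_pct <= before.del_pct
        assert after.total_pct <= before.total_pct


class TestSubstitutionMatrix:
    def test_single_sub_rate(self):
        # one A->G sub among 10 aligned A columns -> rate 0.1
        cols = [EditColumn("match", i + 1, i + 1, "A", "A") for i in range(9)]
        cols.append(EditColumn("sub", 10, 10, "A", "G"))
        es = EditScript(cols, read_span=10, ref_span=10, read_length=10)
        m = substitution_matrix([es])
        assert m.rates[0, 2] == pytest.approx(0.1)  # A->G
        assert m.counts[0, 0] == 9

    def test_zero_substitutions(self):
        m = substitution_matrix([match_script(20)])
        assert np.all(m.rates == 0)
        assert m.transition_rate == 0
        assert m.transition_share is None

    def test_transition_vs_transversion_classification(self):
        cols = [
            EditColumn("sub", 1, 1, "A", "G"),   # transition
            EditColumn("sub", 2, 2, "C", "T"),   # transition
            EditColumn("sub", 3, 3, "A", "C"),   # transversion
            EditColumn("match", 4, 4, "G", "G"),
        ]
        es = EditScript(cols, read_span=4, ref_span=4, read_length=4)
        m = substitution_matrix([es])
        assert m.transition_rate == pytest.approx(2 / 4)
        assert m.transversion_rate == pytest.approx(1 / 4)
        assert m.transition_share == pytest.approx(2 / 3)

    def test_row_sums_equal_ref_base_columns(self):
        es = script_from_ops("MMSMMS")  # ref bases all A in the builder
        m = substitution_matrix([es])
        assert m.counts.sum(axis=1)[0] == 6  # all columns have ref A
        assert m.counts[0].sum() == 6


def test_profiles_tsv_layout():
    prof = aggregate_profile([match_script(10)], n_reads_total=1)
    text = profiles_to_tsv([("raw", prof)])
    header, row = text.strip().split("\n")
    assert header.split("\t") == [
        "dataset", "n_reads", "aligned_pct", "sub_pct", "ins_pct", "del_pct",
        "total_pct", "longest_perfect_match_bp", "longest_alignment_bp",
        "max_stretch_pct",
    ]
    assert row.split("\t")[0] == "raw"
    assert row.split("\t")[3] == "0.00"
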