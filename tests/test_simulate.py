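"""Tests for the truth-emitting read simulator."""

from __future__ import annotations

import io

import numpy as np
import pytest

from lrprofile.alignment_errors import ErrorCounts, count_errors
from lrprofile.io_formats import expand_edit_script, parse_alignments, revcomp
from lrprofile.simulate import (
    FivePrimeNoise,
    HomopolymerModel,
    ReadLengthModel,
    SimulationConfig,
    generate_genome,
    ont_like,
    pacbio_like,
    simulate_read,
    simulate_readset,
    write_readset,
)


class TestGenerateGenome:
    def test_gc_zero_is_at_only(self):
        g = generate_genome(500, gc=0.0, seed=1)
        assert set(g.sequence) <= {"A", "T"}

    def test_gc_fraction_binomial_bound(self):
        # binomial 3 sigma at n=1e6 is ~0.0015
        g = generate_genome(10**6, gc=0.5, seed=2)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / len(g)
        assert abs(gc - 0.5) < 0.002

    def test_deterministic(self):
        assert generate_genome(1000, seed=3).sequence == generate_genome(1000, seed=3).sequence

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            generate_genome(0)
        with pytest.raises(ValueError):
            generate_genome(10, gc=1.5)


class TestConfigValidation:
    def test_rates_must_sum_below_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_sub=0.5, p_ins=0.3, p_del=0.3)

    def test_pathological_deletion_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_del=1.0)

    def test_multiplier_guard(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                p_sub=0.2, p_ins=0.1, p_del=0.1,
                five_prime=FivePrimeNoise(n5=100, multiplier=3.0),
            )

    def test_sub_pref_must_be_row_stochastic(self):
        bad = np.full((4, 4), 0.5)
        np.fill_diagonal(bad, 0.0)
        with pytest.raises(ValueError):
            SimulationConfig(p_sub=0.1, sub_pref=bad)

    def test_presets_validate(self):
        ont_like()
        pacbio_like()


class TestSimulateRead:
    def test_error_free_read_is_reference_copy(self):
        g = generate_genome(2000, seed=4)
        rng = np.random.default_rng(0)
        sr = simulate_read(g, 100, 500, "+", SimulationConfig(), rng)
        assert sr.read.sequence == g.sequence[100:600]
        assert sr.truth_alignment.cigar == [("M", 500)]
        assert sr.truth_alignment.md == "500"
        c = sr.truth_counts
        assert (c.n_match, c.n_sub, c.n_ins, c.n_del) == (500, 0, 0, 0)

    def test_error_free_reverse_strand(self):
        g = generate_genome(2000, seed=4)
        rng = np.random.default_rng(0)
        sr = simulate_read(g, 100, 500, "-", SimulationConfig(), rng)
        assert sr.read.sequence == revcomp(g.sequence[100:600])
        assert sr.truth_alignment.seq == g.sequence[100:600]
        # read positions run 5'->3' of the original read: stored left-to-right
        # they descend
        positions = [c.read_pos for c in sr.truth_columns.columns]
        assert positions[0] == 500 and positions[-1] == 1

    def test_truth_roundtrip_md_and_ref_routes(self):
        g = generate_genome(5000, seed=5)
        cfg = ont_like(seed=6)
        rng = np.random.default_rng(7)
        for start, span, strand in [(0, 800, "+"), (4500, 900, "-"), (123, 1000, "-")]:
            sr = simulate_read(g, start, span, strand, cfg, rng)
            es_md = expand_edit_script(sr.truth_alignment)
            assert es_md.columns == sr.truth_columns.columns
            aln = sr.truth_alignment
            aln_no_md = type(aln)(**{**aln.__dict__, "md": None})
            es_ref = expand_edit_script(aln_no_md, g)
            assert es_ref.columns == sr.truth_columns.columns
            assert count_errors(es_md) == sr.truth_counts

    def test_wraparound_read_on_circular_genome(self):
        g = generate_genome(1000, seed=8)
        rng = np.random.default_rng(9)
        sr = simulate_read(g, 900, 300, "+", SimulationConfig(), rng)
        assert sr.read.sequence == g.sequence[900:] + g.sequence[:200]
        es = expand_edit_script(sr.truth_alignment, g)
        assert es.columns == sr.truth_columns.columns
        assert es.columns[-1].ref_pos == 200

    def test_wraparound_rejected_on_linear_genome(self):
        g = generate_genome(1000, seed=8, circular=False)
        with pytest.raises(ValueError):
            simulate_read(g, 900, 300, "+", SimulationConfig(), np.random.default_rng(0))

    def test_configured_rate_recovery_moderate_scale(self):
        # Monte-Carlo oracle: pooled truth rates near configured per-column
        # rates; 3 binomial sigma at ~500 kbp is ~0.09 pp for rates ~4%
        g = generate_genome(100_000, seed=10)
        cfg = ont_like(seed=11)
        pooled = ErrorCounts()
        for sr in simulate_readset(g, 5.0, cfg):
            pooled += sr.truth_counts
        n = pooled.n_columns
        for observed, configured in [
            (pooled.n_sub / n, cfg.p_sub),
            (pooled.n_ins / n, cfg.p_ins),
            (pooled.n_del / n, cfg.p_del),
        ]:
            sigma = (configured * (1 - configured) / n) ** 0.5
            assert abs(observed - configured) < 4 * sigma + 1e-4

    def test_substitution_preference_applied(self):
        g = generate_genome(100_000, seed=12)
        cfg = ont_like(seed=13)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        n_total = 0
        n_transition = 0
        for sr in simulate_readset(g, 3.0, cfg):
            for c in sr.truth_columns.columns:
                if c.op == "sub":
                    n_total += 1
                    n_transition += (c.ref_base, c.read_base) in transitions
        share = n_transition / n_total
        assert abs(share - 0.7) < 0.03

    def test_homopolymer_expansion_bias(self):
        g = generate_genome(50_000, gc=0.2, seed=14)
        hp = HomopolymerModel(enabled=True, min_run=4, p_expand=0.5, p_contract=0.0)
        cfg = SimulationConfig(homopolymer=hp, seed=15)
        n_ins = 0
        n_reads = 0
        for sr in simulate_readset(g, 2.0, cfg):
            n_ins += sr.truth_counts.n_ins
            assert sr.truth_counts.n_sub == 0 and sr.truth_counts.n_del == 0
            n_reads += 1
            # every insertion extends a run of the same base
            for c in sr.truth_columns.columns:
                if c.op == "ins":
                    assert c.read_base in "ACGT"
        assert n_ins > 0

    def test_five_prime_noise_concentrates_errors(self):
        g = generate_genome(50_000, seed=16)
        cfg = SimulationConfig(
            p_sub=0.02,
            five_prime=FivePrimeNoise(n5=500, multiplier=4.0),
            read_length=ReadLengthModel(mu=8.0, sigma=0.1, min_len=2000, max_len=5000),
            seed=17,
        )
        head = tail = 0
        head_cols = tail_cols = 0
        for sr in simulate_readset(g, 3.0, cfg):
            for c in sr.truth_columns.columns:
                if c.read_pos is None:
                    continue
                if c.read_pos <= 500:
                    head_cols += 1
                    head += c.op == "sub"
                elif c.read_pos > 1000:
                    tail_cols += 1
                    tail += c.op == "sub"
        ratio = (head / head_cols) / (tail / tail_cols)
        assert 3.2 < ratio < 4.8


class TestSimulateReadset:
    def test_coverage_threshold_bound(self):
        g = generate_genome(100_000, seed=18)
        cfg = SimulationConfig(
            read_length=ReadLengthModel(mu=7.6, sigma=0.3, min_len=500, max_len=10_000),
            seed=19,
        )
        total = sum(len(sr.read) for sr in simulate_readset(g, 10.0, cfg))
        assert 10.0 * len(g) <= total < 10.0 * len(g) + 10_000

    def test_strand_fractions(self):
        g = generate_genome(20_000, seed=20)
        cfg = SimulationConfig(
            read_length=ReadLengthModel(mu=4.0, sigma=0.2, min_len=20, max_len=200),
            seed=21,
        )
        strands = [sr.strand for sr in simulate_readset(g, 30.0, cfg)]
        frac = strands.count("+") / len(strands)
        assert len(strands) > 5000
        assert abs(frac - 0.5) < 0.02

    def test_byte_identical_outputs_for_same_seed(self):
        g = generate_genome(20_000, seed=22)
        cfg = ont_like(seed=23)
        outs = []
        for _ in range(2):
            fq, sm, tsv = io.StringIO(), io.StringIO(), io.StringIO()
            write_readset(simulate_readset(g, 2.0, cfg), g, cfg, fq, sm, tsv)
            outs.append((fq.getvalue(), sm.getvalue(), tsv.getvalue()))
        assert outs[0] == outs[1]

    def test_truth_sam_parses_and_matches(self, tmp_path):
        g = generate_genome(30_000, seed=24)
        cfg = pacbio_like(seed=25)
        reads = list(simulate_readset(g, 1.0, cfg))
        sam = tmp_path / "truth.sam"
        fq = tmp_path / "reads.fastq"
        write_readset(reads, g, cfg, str(fq), str(sam))
        parsed = list(parse_alignments(sam))
        assert len(parsed) == len(reads)
        for aln, sr in zip(parsed, reads):
            assert aln.read_name == sr.read.name
            assert expand_edit_script(aln).columns == sr.truth_columns.columns
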