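"""Simulator: determinism, ground truth, closed-loop behaviour with the classifier."""

import math

import numpy as np
import pytest

from strandcheck import (
    OrientationCall,
    SimSpec,
    build_index,
    classify_pairs,
    make_transcriptome,
    mix_samples,
    revcomp,
    run_on_pairs,
    simulate_gdna_pairs,
    simulate_pairs,
    simulate_to_files,
    tally,
)
from strandcheck.simulate import parse_truth_name


class TestMakeTranscriptome:
    def test_fixed_seed_reproduces_sequences(self):
        a = make_transcriptome(1, (100, 100), seed=3)
        b = make_transcriptome(1, (100, 100), seed=3)
        assert a[0].sequence == b[0].sequence

    def test_ids_are_unique_and_zero_padded(self):
        txs = make_transcriptome(10, (50, 60), seed=1)
        assert [t.id for t in txs] == [f"tx{i:04d}" for i in range(1, 11)]

    def test_gc_content_near_half(self):
        """Uniform bases: total GC is Binomial(N, 0.5), so mean in [0.48, 0.52]."""
        txs = make_transcriptome(1000, (500, 3000), seed=7)
        gc = sum(t.sequence.count("G") + t.sequence.count("C") for t in txs)
        total = sum(len(t.sequence) for t in txs)
        assert 0.48 <= gc / total <= 0.52

    def test_lengths_respect_range(self):
        txs = make_transcriptome(50, (200, 300), seed=2)
        assert all(200 <= len(t.sequence) <= 300 for t in txs)


class TestSimulatePairs:
    def test_same_seed_gives_byte_identical_fastq(self, toy_transcriptome, tmp_path):
        spec = SimSpec(n_pairs=500, strandedness_p=0.8, seed=11)
        paths = [
            (tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq")
            for tag in ("a", "b")
        ]
        for p1, p2 in paths:
            simulate_to_files(toy_transcriptome, spec, p1, p2)
        assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
        assert paths[0][1].read_bytes() == paths[1][1].read_bytes()

    def test_truth_orientation_matches_substring_oracle(self, toy_transcriptome):
        """At error 0 the named orientation must agree with exact-substring search."""
        by_id = {t.id: t.sequence for t in toy_transcriptome}
        spec = SimSpec(n_pairs=300, strandedness_p=0.7, seed=5)
        pairs, truth = simulate_pairs(toy_transcriptome, spec)
        for pair, rec in zip(pairs, truth):
            src = by_id[rec.transcript_id]
            assert parse_truth_name(pair.name) == (
                rec.transcript_id,
                rec.orientation,
                rec.start,
            )
            if rec.orientation == "FR":
                assert pair.seq1 in src and revcomp(pair.seq2) in src
            else:
                assert revcomp(pair.seq1) in src and pair.seq2 in src

    def test_pure_fr_library_yields_zero_rf_calls(self, toy_transcriptome, toy_index):
        spec = SimSpec(n_pairs=2000, strandedness_p=1.0, layout="FR", seed=21)
        pairs, _ = simulate_pairs(toy_transcriptome, spec)
        counts = tally(classify_pairs(pairs, toy_index))
        assert counts.n_rf == 0
        assert counts.n_fr + counts.n_failed + counts.n_unmapped == counts.n_total

    def test_pure_rf_library_yields_zero_fr_calls(self, toy_transcriptome, toy_index):
        spec = SimSpec(n_pairs=2000, strandedness_p=1.0, layout="RF", seed=22)
        pairs, _ = simulate_pairs(toy_transcriptome, spec)
        counts = tally(classify_pairs(pairs, toy_index))
        assert counts.n_fr == 0

    def test_unstranded_fr_count_binomially_concentrated(self, toy_transcriptome):
        spec = SimSpec(n_pairs=20_000, strandedness_p=0.5, seed=23)
        _, truth = simulate_pairs(toy_transcriptome, spec)
        n_fr = sum(1 for t in truth if t.orientation == "FR")
        n = len(truth)
        assert abs(n_fr - n / 2) <= 4 * math.sqrt(n * 0.25)

    def test_substitution_errors_change_bases_at_requested_rate(self, toy_transcriptome):
        clean = SimSpec(n_pairs=200, strandedness_p=1.0, seed=31, error_rate=0.0)
        noisy = SimSpec(n_pairs=200, strandedness_p=1.0, seed=31, error_rate=0.02)
        pairs_c, _ = simulate_pairs(toy_transcriptome, clean)
        pairs_n, _ = simulate_pairs(toy_transcriptome, noisy)
        diffs = sum(
            a != b
            for pc, pn in zip(pairs_c, pairs_n)
            for a, b in zip(pc.seq1 + pc.seq2, pn.seq1 + pn.seq2)
        )
        total = sum(len(p.seq1) + len(p.seq2) for p in pairs_c)
        assert 0.01 < diffs / total < 0.03

    def test_strandedness_below_half_rejected(self, toy_transcriptome):
        with pytest.raises(ValueError, match="layout"):
            SimSpec(n_pairs=10, strandedness_p=0.4)

    def test_every_transcript_too_short_is_an_error(self):
        short = make_transcriptome(3, (40, 50), seed=1)
        with pytest.raises(ValueError, match="read_len"):
            simulate_pairs(short, SimSpec(n_pairs=10, read_len=100))


@pytest.fixture(scope="module")
def pools(toy_transcriptome):
    stranded, _ = simulate_pairs(
        toy_transcriptome, SimSpec(n_pairs=3000, strandedness_p=1.0, seed=41)
    )
    unstranded, _ = simulate_pairs(
        toy_transcriptome, SimSpec(n_pairs=3000, strandedness_p=0.5, seed=42)
    )
    return stranded, unstranded


class TestMixSamples:

    def test_ratio_one_draws_only_from_pool_a(self, pools):
        a, b = pools
        mixed = mix_samples(a, b, ratio=1.0, total_pairs=100, seed=1)
        names_a = {p.name for p in a}
        assert all(p.name in names_a for p in mixed)

    def test_half_ratio_splits_exactly(self, pools):
        a, b = pools
        mixed = mix_samples(a, b, ratio=0.5, total_pairs=2000, seed=2)
        names_a = {p.name for p in a}
        n_from_a = sum(1 for p in mixed if p.name in names_a)
        assert len(mixed) == 2000
        assert n_from_a == 1000

    def test_insufficient_pool_reports_deficit(self, pools):
        a, b = pools
        with pytest.raises(ValueError, match="short"):
            mix_samples(a, b, ratio=1.0, total_pairs=10_000, seed=3)

    def test_mixing_law_recovered_by_pipeline(self, pools, toy_index):
        """Percent stranded of an r-mix follows 100*(r + (1-r)/2)."""
        a, b = pools
        for ratio in (0.6, 1.0):
            mixed = mix_samples(a, b, ratio=ratio, total_pairs=2000, seed=4)
            report = run_on_pairs(mixed, toy_index)
            expected = 100 * (ratio + (1 - ratio) / 2)
            sigma_pp = 100 * math.sqrt(0.25 / 2000)
            assert abs(report.percent_stranded - expected) <= 4 * sigma_pp


class TestGdnaControl:
    def test_truth_is_a_fair_coin_per_pair(self):
        pairs, truth, features = simulate_gdna_pairs(
            n_pairs=5000, region_len=100_000, seed=51
        )
        assert all(f.genome_strand == "+" for f in features)
        n_fr = sum(1 for t in truth if t.orientation == "FR")
        assert abs(n_fr - 2500) <= 4 * math.sqrt(5000 * 0.25)

    def test_fixed_seed_reproducible(self):
        a = simulate_gdna_pairs(n_pairs=100, region_len=50_000, seed=6)
        b = simulate_gdna_pairs(n_pairs=100, region_len=50_000, seed=6)
        assert a[0] == b[0]

    def test_pipeline_sees_no_strand_bias(self):
        pairs, _, features = simulate_gdna_pairs(
            n_pairs=5000, region_len=200_000, seed=52
        )
        idx = build_index(features)
        report = run_on_pairs(pairs, idx)
        sigma = math.sqrt(0.25 / (report.counts.n_fr + report.counts.n_rf))
        assert abs(report.stranded_proportion - 0.5) <= 3 * sigma
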