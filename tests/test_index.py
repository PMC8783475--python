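"""K-mer index construction and strand-aware read assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandcheck import (
    AssignmentStatus,
    KmerIndex,
    Orientation,
    Transcript,
    assign_read,
    build_index,
    revcomp,
)
from strandcheck.index import IndexLoadError, assign_reads

dna = st.text(alphabet="ACGT", min_size=31, max_size=120)


class TestBuildIndex:
    def test_enumerates_exactly_the_sense_kmers(self):
        idx = build_index([Transcript(id="tx", sequence="ACGTACGT")], k=5)
        assert set(idx.table) == {"ACGTA", "CGTAC", "GTACG", "TACGT"}
        assert all(idx.table[kmer] == {"tx"} for kmer in idx.table)

    def test_reverse_complement_kmers_not_stored(self):
        idx = build_index([Transcript(id="tx", sequence="AAAAACCCCCGG")], k=11)
        assert "AAAAACCCCCG" in idx.table
        assert revcomp("AAAAACCCCCG") not in idx.table

    def test_transcript_shorter_than_k_contributes_nothing(self, caplog):
        with caplog.at_level("WARNING", logger="strandcheck"):
            idx = build_index(
                [
                    Transcript(id="long", sequence="A" * 40),
                    Transcript(id="short", sequence="ACGT"),
                ],
                k=31,
            )
        assert idx.n_kmers == 1  # poly-A has a single distinct 31-mer
        assert any("shorter than k" in r.message for r in caplog.records)

    def test_shared_kmer_maps_to_both_ids(self):
        shared = "ACGTTGCAAGCTGACGTTGCAAGCTGACGTA"
        t1 = Transcript(id="a", sequence=shared + "GGGGG")
        t2 = Transcript(id="b", sequence="TTTTT" + shared)
        idx = build_index([t1, t2], k=31)
        assert idx.table[shared] == {"a", "b"}

    def test_kmers_containing_n_are_skipped(self):
        idx = build_index([Transcript(id="t", sequence="ACGTN" + "A" * 31)], k=31)
        assert all("N" not in kmer for kmer in idx.table)

    def test_no_transcript_reaching_k_is_an_error(self):
        with pytest.raises(ValueError, match="k=31"):
            build_index([Transcript(id="t", sequence="ACGT")], k=31)

    @pytest.mark.parametrize("k", [10, 30, 1, 65])
    def test_even_or_out_of_range_k_rejected(self, k):
        with pytest.raises(ValueError):
            build_index([Transcript(id="t", sequence="A" * 100)], k=k)


class TestAssignRead:
    def test_exact_sense_substring(self, toy_transcriptome, toy_index):
        tx = toy_transcriptome[0]
        read = tx.sequence[100:150]
        a = assign_read(read, toy_index, min_vote_frac=0.25)
        assert a.status is AssignmentStatus.ASSIGNED
        assert a.orientation is Orientation.SENSE
        assert a.transcripts == {tx.id}
        assert a.votes_sense == 20  # 50 - 31 + 1

    def test_reverse_complement_is_antisense(self, toy_transcriptome, toy_index):
        tx = toy_transcriptome[0]
        read = revcomp(tx.sequence[100:150])
        a = assign_read(read, toy_index, min_vote_frac=0.25)
        assert a.status is AssignmentStatus.ASSIGNED
        assert a.orientation is Orientation.ANTISENSE
        assert a.transcripts == {tx.id}
        assert a.votes_antisense == 20

    def test_all_n_read_is_unmapped(self, toy_index):
        a = assign_read("N" * 50, toy_index)
        assert a.status is AssignmentStatus.UNMAPPED
        assert a.votes_sense == a.votes_antisense == 0

    def test_read_shorter_than_k_is_unmapped_not_an_error(self, toy_index):
        a = assign_read("ACGT", toy_index)
        assert a.status is AssignmentStatus.UNMAPPED

    def test_read_on_shared_sequence_reports_both_transcripts(self):
        shared = "ACGTTGCAAGCTGACGTTGCAAGCTGACGTAACGTGACTG" * 2
        txs = [
            Transcript(id="a", sequence=shared + "G" * 20),
            Transcript(id="b", sequence="T" * 20 + shared),
        ]
        idx = build_index(txs, k=31)
        a = assign_read(shared[:50], idx)
        assert a.status is AssignmentStatus.ASSIGNED
        assert a.transcripts == {"a", "b"}

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(dna)
    def test_orientation_antisymmetry(self, toy_index, seq):
        """assign_read(revcomp(s)) swaps SENSE/ANTISENSE and the vote counts."""
        a = assign_read(seq, toy_index)
        b = assign_read(revcomp(seq), toy_index)
        assert a.votes_sense == b.votes_antisense
        assert a.votes_antisense == b.votes_sense
        assert a.status == b.status
        if a.status is AssignmentStatus.ASSIGNED:
            assert a.orientation != b.orientation
            assert a.transcripts == b.transcripts

    def test_lowering_vote_threshold_never_unmaps(self, toy_transcriptome, toy_index):
        rng = np.random.default_rng(5)
        tx = toy_transcriptome[2]
        for _ in range(20):
            start = int(rng.integers(0, len(tx.sequence) - 60))
            read = list(tx.sequence[start : start + 60])
            for pos in rng.integers(0, 60, size=6):  # heavy corruption
                read[int(pos)] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            strict = assign_read(read, toy_index, min_vote_frac=0.6)
            lax = assign_read(read, toy_index, min_vote_frac=0.1)
            if strict.status is AssignmentStatus.ASSIGNED:
                assert lax.status is not AssignmentStatus.UNMAPPED


def brute_force_assign(read, transcripts):
    """Exact-substring oracle: scan every transcript on both strands."""
    sense = {t.id for t in transcripts if read in t.sequence}
    anti = {t.id for t in transcripts if revcomp(read) in t.sequence}
    return sense, anti


class TestOracleEquivalence:
    def test_agrees_with_substring_oracle_on_error_free_reads(
        self, toy_transcriptome, toy_index
    ):
        """On exact substrings the k-mer vote must reproduce brute force."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            tx = toy_transcriptome[int(rng.integers(len(toy_transcriptome)))]
            start = int(rng.integers(0, len(tx.sequence) - 75))
            read = tx.sequence[start : start + 75]
            if rng.random() < 0.5:
                read = revcomp(read)
            sense, anti = brute_force_assign(read, toy_transcriptome)
            assert (sense and not anti) or (anti and not sense)
            a = assign_read(read, toy_index)
            assert a.status is AssignmentStatus.ASSIGNED
            if sense:
                assert a.orientation is Orientation.SENSE
                assert a.transcripts == sense
            else:
                assert a.orientation is Orientation.ANTISENSE
                assert a.transcripts == anti

    def test_random_reads_do_not_map(self, toy_index):
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            read = "".join(bases[rng.integers(0, 4, size=80)])
            a = assign_read(read, toy_index)
            assert a.status is AssignmentStatus.UNMAPPED


class TestBatchPath:
    def test_batch_matches_scalar_on_mixed_reads(self, toy_transcriptome, toy_index):
        rng = np.random.default_rng(3)
        reads = []
        for _ in range(300):
            tx = toy_transcriptome[int(rng.integers(len(toy_transcriptome)))]
            start = int(rng.integers(0, len(tx.sequence) - 80))
            read = tx.sequence[start : start + 80]
            roll = rng.random()
            if roll < 0.3:
                read = revcomp(read)
            elif roll < 0.5:  # corrupt the tail, leaving some clean k-mers
                read = read[:60] + "".join(
                    "ACGT"[int(b)] for b in rng.integers(0, 4, size=20)
                )
            reads.append(read)
        reads.append("N" * 60)
        reads.append("ACG")  # shorter than k
        batch = assign_reads(reads, toy_index)
        for i, read in enumerate(reads):
            scalar = assign_read(read, toy_index)
            status = {0: AssignmentStatus.UNMAPPED, 1: AssignmentStatus.ASSIGNED, 2: AssignmentStatus.AMBIGUOUS_STRAND}[int(batch.status[i])]
            assert status is scalar.status, f"read {i}"
            assert int(batch.votes_sense[i]) == scalar.votes_sense
            assert int(batch.votes_antisense[i]) == scalar.votes_antisense
            if status is AssignmentStatus.ASSIGNED and batch.tx_single[i] >= 0:
                assert scalar.transcripts == {
                    toy_index.transcript_ids[int(batch.tx_single[i])]
                }


class TestPersistence:
    def test_save_load_round_trip_preserves_assignments(
        self, toy_transcriptome, toy_index, tmp_path
    ):
        path = tmp_path / "toy.idx"
        toy_index.save(path)
        loaded = KmerIndex.load(path)
        assert loaded.k == toy_index.k
        tx = toy_transcriptome[1]
        read = tx.sequence[50:110]
        assert assign_read(read, loaded) == assign_read(read, toy_index)

    def test_corrupt_artifact_raises_load_error(self, tmp_path):
        path = tmp_path / "bad.idx"
        path.write_bytes(b"this is not an index")
        with pytest.raises(IndexLoadError, match="rebuild"):
            KmerIndex.load(path)

    def test_wrong_version_raises_load_error(self, toy_index, tmp_path):
        import numpy as _np

        path = tmp_path / "old.idx"
        with open(path, "wb") as fh:
            _np.savez(fh, format_version=_np.array("strandcheck-index-0"))
        with pytest.raises(IndexLoadError, match="format"):
            KmerIndex.load(path)
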