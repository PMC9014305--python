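import numpy as np
import pytest

from circfind import (
    AnalysisConfig,
    Genome,
    GenomeRecord,
    SequenceRead,
    build_index,
    detect_sample,
    find_circular_junctions,
    reverse_complement,
)
from circfind.detect import hits_to_frame

from _oracles import naive_locate_forward, oracle_find_junctions, rc
from conftest import random_sequence


def junction_read(genome_seq, start, end, first_arm, read_len=51):
    """Read crossing the circle closure: locus 3' arm followed by 5' arm."""
    locus = genome_seq[start - 1 : end]
    return locus[len(locus) - first_arm :] + locus[: read_len - first_arm]


class TestSequenceIndex:
    def test_locate_matches_naive_scan_on_small_example(self):
        g = Genome((GenomeRecord("chr", "ACGTACGT"),))
        idx = build_index(g, seed_len=4)
        hits = idx.locate("ACGT")
        assert ("chr", 1, 4, "+") in hits and ("chr", 5, 8, "+") in hits
        # ACGT is its own reverse complement, so minus placements mirror plus
        assert ("chr", 1, 4, "-") in hits and ("chr", 5, 8, "-") in hits
        assert len(hits) == 4

    def test_query_longer_than_genome(self):
        g = Genome((GenomeRecord("chr", "ACGT"),))
        assert build_index(g, seed_len=2).locate("ACGTACGT") == []

    def test_query_with_n_never_matches(self):
        g = Genome((GenomeRecord("chr", "ACGTNACGT"),))
        idx = build_index(g, seed_len=4)
        assert idx.locate("GTNA") == []

    @pytest.mark.parametrize("case", range(25))
    def test_locate_equals_naive_scan_on_random_genomes(self, case):
        rng = np.random.default_rng(1000 + case)
        seqs = [("c%d" % i, random_sequence(rng, int(rng.integers(30, 400))))
                for i in range(int(rng.integers(1, 3)))]
        g = Genome(tuple(GenomeRecord(n, s) for n, s in seqs))
        idx = build_index(g, seed_len=5)
        for _ in range(20):
            qlen = int(rng.integers(3, 12))
            if rng.integers(0, 2):
                src = seqs[int(rng.integers(0, len(seqs)))][1]
                start = int(rng.integers(0, max(1, len(src) - qlen)))
                query = src[start : start + qlen]
            else:
                query = random_sequence(rng, qlen)
            got = sorted(
                (c, s, st) for c, s, _, st in idx.locate(query)
            )
            want = sorted(
                [(seqs[ci][0], i + 1, "+") for ci, i in naive_locate_forward(seqs, query)]
                + [(seqs[ci][0], i + 1, "-") for ci, i in naive_locate_forward(seqs, rc(query))]
            )
            assert got == want


class TestFindCircularJunctions:
    def test_planted_junction_recovered_uniquely(self, planted, cfg):
        genome, index, (start, end) = planted
        read = SequenceRead("r", junction_read(genome.records[0].sequence, start, end, 20))
        hits = find_circular_junctions(read, index, cfg)
        assert len(hits) == 1
        h = hits[0]
        assert h.junction == (start, end)
        assert h.strand == "+"
        assert h.upstream_segment == (end - 19, end)
        assert h.downstream_segment == (start, start + 30)

    def test_contiguous_read_is_linear(self, planted, cfg):
        genome, index, (start, _) = planted
        seq = genome.records[0].sequence[start - 1 : start + 50]
        assert find_circular_junctions(SequenceRead("r", seq), index, cfg) == []

    def test_short_read_precondition(self, planted, cfg):
        _, index, _ = planted
        read = SequenceRead("r", "A" * 39)
        assert find_circular_junctions(read, index, cfg) == []

    def test_minus_strand_junction_reported_in_forward_frame(self, planted, cfg):
        genome, index, (start, end) = planted
        read_seq = junction_read(genome.records[0].sequence, start, end, 24)
        hits = find_circular_junctions(
            SequenceRead("r", reverse_complement(read_seq)), index, cfg
        )
        assert [(h.strand, h.junction) for h in hits] == [("-", (start, end))]

    @pytest.mark.parametrize("first_arm", range(15, 26))
    def test_arm_length_floor(self, planted, cfg, first_arm):
        """Junction reads are found iff both arms reach min_segment_len."""
        genome, index, (start, end) = planted
        read = SequenceRead(
            "r", junction_read(genome.records[0].sequence, start, end, first_arm)
        )
        hits = find_circular_junctions(read, index, cfg)
        if cfg.min_segment_len <= first_arm <= 51 - cfg.min_segment_len:
            assert [h.junction for h in hits] == [(start, end)]
        else:
            assert hits == []

    def test_every_hit_satisfies_the_inverse_order_invariants(self, planted, cfg):
        genome, index, (start, end) = planted
        seq = genome.records[0].sequence
        for arm in range(20, 32):
            for read_seq in (junction_read(seq, start, end, arm),
                             reverse_complement(junction_read(seq, start, end, arm))):
                for h in find_circular_junctions(SequenceRead("r", read_seq), index, cfg):
                    a1, b1 = h.upstream_segment
                    a2, b2 = h.downstream_segment
                    assert b1 - a1 + 1 >= cfg.min_segment_len
                    assert b2 - a2 + 1 >= cfg.min_segment_len
                    assert a1 > b2
                    assert h.junction == (a2, b1)

    def test_strand_symmetry_under_read_reverse_complement(self, cfg):
        rng = np.random.default_rng(7)
        for _ in range(30):
            seq = random_sequence(rng, 3000)
            genome = Genome((GenomeRecord("c", seq),))
            index = build_index(genome, seed_len=20)
            s = int(rng.integers(1, 2800))
            e = s + int(rng.integers(55, 90))
            read_seq = junction_read(seq, s, e, int(rng.integers(20, 32)))
            fwd = find_circular_junctions(SequenceRead("r", read_seq), index, cfg)
            rev = find_circular_junctions(
                SequenceRead("r", reverse_complement(read_seq)), index, cfg
            )
            assert sorted(h.junction for h in fwd) == sorted(h.junction for h in rev)
            assert sorted(h.strand for h in fwd) == sorted(
                {"+": "-", "-": "+"}[h.strand] for h in rev
            )


class TestDetectSample:
    def test_simulated_mixture_counts(self, planted, cfg):
        genome, index, (start, end) = planted
        seq = genome.records[0].sequence
        reads = []
        for i in range(10):
            reads.append(
                SequenceRead(f"j{i}", junction_read(seq, start, end, 20 + i))
            )
        for i in range(90):
            p = 100 + 37 * i
            reads.append(SequenceRead(f"l{i}", seq[p : p + 51]))
        hits, summary = detect_sample(reads, index, cfg)
        assert summary == {"total_reads": 100, "reads_with_hits": 10}
        assert all(h.junction == (start, end) for h in hits)

    def test_empty_stream(self, planted, cfg):
        _, index, _ = planted
        hits, summary = detect_sample([], index, cfg)
        assert hits == [] and summary == {"total_reads": 0, "reads_with_hits": 0}

    def test_duplicated_stream_doubles_hits(self, planted, cfg):
        genome, index, (start, end) = planted
        reads = [
            SequenceRead("a", junction_read(genome.records[0].sequence, start, end, 22))
        ]
        hits1, _ = detect_sample(reads, index, cfg)
        hits2, _ = detect_sample(reads * 2, index, cfg)
        assert len(hits2) == 2 * len(hits1)

    def test_hits_frame_columns(self, planted, cfg):
        genome, index, (start, end) = planted
        reads = [
            SequenceRead("a", junction_read(genome.records[0].sequence, start, end, 22))
        ]
        hits, _ = detect_sample(reads, index, cfg)
        df = hits_to_frame(hits)
        assert list(df.columns) == [
            "read_id", "chrom", "strand", "circ_start", "circ_end", "split_pos",
        ]
        assert df.loc[0, "circ_start"] == start


class TestOracleAgreement:
    def test_repeat_induced_ambiguity_matches_oracle(self, cfg):
        """Both-parts-multi-placed splits are dropped identically."""
        rng = np.random.default_rng(99)
        core = random_sequence(rng, 400)
        seg = core[50:90]
        # duplicate a 40-mer so one read part becomes multi-placed
        seq = core + seg + random_sequence(rng, 200)
        seqs = [("c", seq)]
        genome = Genome((GenomeRecord("c", seq),))
        index = build_index(genome, seed_len=20)
        read_seq = junction_read(seq, 30, 120, 25)
        got = sorted(
            (h.chrom, h.strand, *h.junction)
            for h in find_circular_junctions(SequenceRead("r", read_seq), index, cfg)
        )
        want = sorted(oracle_find_junctions(seqs, read_seq, cfg.min_segment_len))
        assert got == want
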