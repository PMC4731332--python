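import random

import pytest
from hypothesis import given, strategies as st

from permacirc.formats import SeqRecord, revcomp
from permacirc.read_processing import (
    GenomeIndex,
    align_read,
    coverage_profiles,
    length_filter,
    quality_trim,
    trim_adapter,
)

from .oracles import max_sum_substring, smith_waterman_gotoh


def _phred_read(rid, seq, quals):
    return SeqRecord(rid, seq, list(quals))


class TestQualityTrim:
    def test_uniform_high_quality_unchanged(self):
        r = _phred_read("r", "ACGTACGT", [40] * 8)
        assert quality_trim(r).seq == "ACGTACGT"

    def test_uniform_low_quality_empties(self):
        r = _phred_read("r", "ACGTACGT", [2] * 8)  # p ~ 0.63 > 0.05
        assert quality_trim(r).seq == ""

    def test_requires_qualities(self):
        with pytest.raises(ValueError):
            quality_trim(SeqRecord("r", "ACGT"))

    def test_ambiguity_filter_after_trimming(self):
        r = _phred_read("r", "ANNNA", [40] * 5)
        assert quality_trim(r).seq == ""  # 3 N kept > 2 allowed
        r2 = _phred_read("r", "ANNA", [40] * 4)
        assert quality_trim(r2).seq == "ANNA"

    def test_matches_exhaustive_max_sum_oracle(self):
        rnd = random.Random(123)
        for _ in range(300):
            n = rnd.randint(1, 30)
            quals = [rnd.randint(0, 41) for _ in range(n)]
            seq = "".join(rnd.choice("ACGT") for _ in range(n))
            got = quality_trim(_phred_read("r", seq, quals), max_ambiguities=n)
            gains = [0.05 - 10 ** (-q / 10) for q in quals]
            best_sum, i, j = max_sum_substring(gains)
            if best_sum <= 0:
                assert got.seq == ""
            else:
                assert (got.seq, got.qual) == (seq[i:j], quals[i:j])


class TestAdapterTrim:
    ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # small RNA 3' adapter

    def test_full_adapter_removed(self):
        insert = "ACGTACGTACGT"
        r = SeqRecord("r", insert + self.ADAPTER)
        assert trim_adapter(r, self.ADAPTER).seq == insert

    def test_no_adapter_unchanged(self):
        r = SeqRecord("r", "ACGTACGTACGTACGTACGT")
        assert trim_adapter(r, self.ADAPTER).seq == r.seq

    def test_one_mismatch_in_long_overlap_removed(self):
        insert = "CCCCCCCCCC"
        partial = self.ADAPTER[:20]
        mutated = partial[:7] + ("A" if partial[7] != "A" else "C") + partial[8:]
        r = SeqRecord("r", insert + mutated)
        # enumerate all suffix overlaps by hand: longest admissible wins
        assert trim_adapter(r, self.ADAPTER).seq == insert

    def test_short_terminal_overlap(self):
        insert = "ACGTACGTAC"
        r = SeqRecord("r", insert + self.ADAPTER[:3])
        assert trim_adapter(r, self.ADAPTER).seq == insert


class TestLengthFilter:
    def test_cutoff_semantics(self):
        reads = [SeqRecord(f"r{n}", "A" * n) for n in (14, 15, 16)]
        kept = length_filter(reads, 15)
        assert [len(r) for r in kept] == [15, 16]

    def test_empty_input(self):
        assert length_filter([], 15) == []

    @given(
        lengths=st.lists(st.integers(0, 40), max_size=30),
        min_len=st.integers(0, 45),
    )
    def test_subsequence_and_monotone(self, lengths, min_len):
        reads = [SeqRecord(f"r{i}", "A" * n) for i, n in enumerate(lengths)]
        kept = length_filter(reads, min_len)
        assert all(len(r) >= min_len for r in kept)
        ids = [r.id for r in reads]
        assert [r.id for r in kept] == [i for i in ids if i in {r.id for r in kept}]
        stricter = length_filter(reads, min_len + 5)
        assert {r.id for r in stricter} <= {r.id for r in kept}


def _random_genome(rnd, n):
    return "".join(rnd.choice("ACGT") for _ in range(n))


def _read_from_genome(rnd, genome, min_len=30, max_len=60, max_mut=3):
    """Substring with substitutions kept away from a protected 12-mer."""
    n = rnd.randint(min_len, min(max_len, len(genome)))
    start = rnd.randint(0, len(genome) - n)
    seq = list(genome[start : start + n])
    prot = rnd.randint(0, n - 12)
    positions = [i for i in range(n) if not prot <= i < prot + 12]
    for i in rnd.sample(positions, rnd.randint(0, max_mut)):
        seq[i] = rnd.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(seq)


class TestAlignRead:
    def test_exact_unique_match(self):
        rnd = random.Random(0)
        genome = SeqRecord("g", _random_genome(rnd, 300))
        read = SeqRecord("r", genome.seq[100:130])
        (aln,) = align_read(read, genome)
        assert (aln.ref_start, aln.ref_end, aln.strand) == (100, 130, "+")
        assert aln.score == 30 and aln.clip5 == 0 and aln.clip3 == 0

    def test_reverse_strand(self):
        rnd = random.Random(1)
        genome = SeqRecord("g", _random_genome(rnd, 300))
        read = SeqRecord("r", revcomp(genome.seq[50:85]))
        (aln,) = align_read(read, genome)
        assert (aln.ref_start, aln.ref_end, aln.strand) == (50, 85, "-")

    def test_split_read_is_half_aligned_with_soft_clip(self):
        rnd = random.Random(2)
        g = list(_random_genome(rnd, 400))
        # prevent chance 1-nt extension of either half across the split point
        while g[55] == g[300]:
            g[55] = rnd.choice("ACGT")
        while g[299] == g[54]:
            g[299] = rnd.choice("ACGT")
        genome = SeqRecord("g", "".join(g))
        read = SeqRecord("r", genome.seq[40:55] + genome.seq[300:315])
        alns = align_read(read, genome)
        assert alns  # both halves score 15; co-optimal placements allowed
        for aln in alns:
            assert aln.read_aln_end - aln.read_aln_start == 15
            assert {aln.clip5, aln.clip3} == {0, 15}

    def test_clips_partition_read_with_aligned_interval(self):
        rnd = random.Random(3)
        genome = SeqRecord("g", _random_genome(rnd, 500))
        for _ in range(20):
            read = SeqRecord("r", _read_from_genome(rnd, genome.seq))
            for aln in align_read(read, genome):
                assert aln.clip5 + (aln.read_aln_end - aln.read_aln_start) + aln.clip3 == len(
                    read.seq
                )

    def test_no_seed_returns_empty(self):
        genome = SeqRecord("g", "ACGT" * 30)
        assert align_read(SeqRecord("r", "T" * 20), genome) == []

    def test_score_equals_full_smith_waterman(self):
        # the windowed seed-and-extend score must equal exhaustive local
        # affine-gap DP on reads derived from the genome
        rnd = random.Random(99)
        for _ in range(30):
            genome = SeqRecord("g", _random_genome(rnd, rnd.randint(100, 500)))
            read = SeqRecord("r", _read_from_genome(rnd, genome.seq))
            alns = align_read(read, genome)
            expected = max(
                smith_waterman_gotoh(genome.seq, read.seq),
                smith_waterman_gotoh(genome.seq, revcomp(read.seq)),
            )
            assert alns and alns[0].score == expected


class TestCoverage:
    def test_single_plus_alignment(self, default_locus):
        genome, _, _ = default_locus
        from permacirc.read_processing import AlignmentRecord

        aln = AlignmentRecord("r", genome.id, 10, 20, "+", 0, 10, 10, 10.0)
        prof = coverage_profiles([aln], genome)
        assert prof.depth["+"][10:20].sum() == 10 and prof.depth["+"].sum() == 10
        assert prof.starts5["+"][10] == 1 and prof.starts5["+"].sum() == 1

    def test_minus_strand_five_prime_end(self, default_locus):
        genome, _, _ = default_locus
        from permacirc.read_processing import AlignmentRecord

        aln = AlignmentRecord("r", genome.id, 10, 20, "-", 0, 10, 10, 10.0)
        prof = coverage_profiles([aln], genome)
        assert prof.starts5["-"][19] == 1

    def test_depth_conservation_identity(self, default_run):
        prof = coverage_profiles(default_run["alignments"], default_run["genome"])
        total = prof.total_depth().sum()
        aligned = sum(a.ref_end - a.ref_start for a in default_run["alignments"])
        assert total == aligned
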