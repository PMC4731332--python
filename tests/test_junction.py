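import numpy as np
import pytest

from permacirc.formats import SeqRecord
from permacirc.junction import (
    BHBMotif,
    CircularJunction,
    call_tss,
    circle_length,
    detect_circular_junctions,
    enumerate_bhb_configs,
    find_bhb,
    find_tata,
    predict_cleavage,
    validate_junction_vs_bhb,
)
from permacirc.read_processing import GenomeIndex, align_read
from permacirc.synthetic import LocusParams, ReadSimParams, build_locus, simulate_reads

from .conftest import run_junction_pipeline


class TestJunctionDetection:
    def test_synthetic_error_free_recovers_truth_exactly(self):
        for seed in range(5):
            res = run_junction_pipeline(seed=seed)
            truth = res["truth"]
            assert len(res["junctions"]) == 1
            j = res["junctions"][0]
            assert (j.acceptor, j.donor) == (truth.circle_start, truth.circle_end)
            assert circle_length(j) == truth.circle_len

    def test_precursor_only_reads_yield_no_junction(self):
        genome, truth, _ = build_locus(LocusParams(seed=2))
        reads = simulate_reads(
            genome, truth, ReadSimParams(n_precursor=120, n_circular=0, seed=3)
        )
        index = GenomeIndex(genome)
        alns = [a for r in reads for a in align_read(r, index)]
        assert detect_circular_junctions(alns, reads, genome) == []

    def test_min_support_threshold_semantics(self):
        genome, truth, _ = build_locus(LocusParams(seed=4))
        # construct a single junction-spanning read by hand
        A, D = truth.circle_start, truth.circle_end
        read = SeqRecord("jr", genome.seq[D - 40 : D] + genome.seq[A : A + 20])
        alns = align_read(read, genome)
        assert detect_circular_junctions(alns, [read], genome, min_support=2) == []
        (j,) = detect_circular_junctions(alns, [read], genome, min_support=1)
        assert (j.acceptor, j.donor, j.support) == (A, D, 1)

    def test_supporting_reads_all_imply_identical_coordinates(self):
        for err in (0.0, 0.01):
            res = run_junction_pipeline(seed=6, err=err)
            for j in res["junctions"]:
                assert j.support >= 2
                assert j.support == len(j.read_ids)


class TestCircleLength:
    def test_arithmetic(self):
        assert circle_length(CircularJunction("s", 100, 409, "+", 3)) == 309
        assert circle_length(CircularJunction("s", 0, 1, "+", 1)) == 1

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            CircularJunction("s", 10, 10, "+", 1)


class TestTSSCall:
    def test_synthetic_leader_recovered(self, default_run):
        truth, tss = default_run["truth"], default_run["tss"]
        assert tss is not None and tss.leader_len == truth.leader_len
        assert tss.tss == truth.tss

    def test_leader_arithmetic(self):
        starts = np.zeros(200, dtype=int)
        starts[100] = 20
        j = CircularJunction("s", 123, 200, "+", 5)
        call = call_tss(starts, j)
        assert call.tss == 100 and call.leader_len == 23

    def test_tied_peaks_no_call(self):
        starts = np.zeros(200, dtype=int)
        starts[100] = starts[110] = 10
        j = CircularJunction("s", 123, 200, "+", 5)
        assert call_tss(starts, j) is None

    def test_dispersed_starts_below_min_frac_no_call(self):
        starts = np.zeros(200, dtype=int)
        starts[100:120] = 1
        starts[100] = 2
        j = CircularJunction("s", 123, 199, "+", 5)
        assert call_tss(starts, j) is None

    def test_empty_window_no_call(self):
        starts = np.zeros(200, dtype=int)
        j = CircularJunction("s", 123, 199, "+", 5)
        assert call_tss(starts, j) is None


class TestFindTata:
    def test_planted_offset_recovered(self, default_run):
        truth = default_run["truth"]
        hit, offset = default_run["tata"]
        assert offset == truth.tata_offset == 26
        assert (hit.start, hit.end) == truth.tata_interval

    def test_absent_pattern_no_call(self):
        genome = SeqRecord("g", "ACGC" * 40)
        assert find_tata(genome, tss=100) is None

    def test_nearest_match_wins(self):
        seq = "C" * 40 + "TTAATA" + "CCCC" + "TTAATA" + "CC"
        genome = SeqRecord("g", seq + "C" * 20)
        tss = len(seq)
        hit, offset = find_tata(genome, tss)
        assert offset == 2 and hit.start == 50


class TestFindBHB:
    def test_top_ranked_equals_truth_geometry(self):
        for seed in range(8):
            genome, truth, _ = build_locus(LocusParams(seed=seed))
            j = CircularJunction(genome.id, truth.circle_start, truth.circle_end, "+", 5)
            motifs = find_bhb(genome, j)
            assert motifs
            top = motifs[0]
            tb = truth.bhb
            assert (top.bulge1, top.bulge2) == (tb.bulge1, tb.bulge2)
            assert (top.outer1, top.central, top.outer2) == (tb.outer1, tb.central, tb.outer2)

    def test_three_bp_central_helix_rejected(self):
        # probe construct: break one central pair of a planted BHB and the
        # junction-consistent configuration disappears
        genome, truth, _ = build_locus(LocusParams(seed=3))
        A, D = truth.circle_start, truth.circle_end
        j = CircularJunction(genome.id, A, D, "+", 5)
        assert any(validate_junction_vs_bhb(j, m) for m in find_bhb(genome, j))
        (c1s, _), _ = truth.bhb.central
        seq = list(genome.seq)
        base = seq[c1s]
        partner = {"A": "T", "T": "A", "G": "C", "C": "G"}[base]
        seq[c1s] = partner  # pick a base that cannot pair its partner
        from permacirc.structure import can_pair

        for alt in "ACGT":
            if not can_pair(alt, seq[truth.bhb.central[1][0] + 3]) :
                seq[c1s] = alt
                break
        probe = SeqRecord(genome.id, "".join(seq))
        assert not any(validate_junction_vs_bhb(j, m) for m in find_bhb(probe, j))

    def test_strand_swap_symmetry(self):
        genome, truth, _ = build_locus(LocusParams(seed=5))
        A, D, flank = truth.circle_start, truth.circle_end, 18
        s1 = genome.seq[A - flank : A + flank]
        s2 = genome.seq[D - flank : D + flank]
        direct = enumerate_bhb_configs(s1, s2)
        swapped = enumerate_bhb_configs(s2, s1)
        mirrored = sorted((c.c2, c.i1, c.b, c.a) for c in swapped)
        assert sorted((c.i1, c.c2, c.a, c.b) for c in direct) == mirrored
        assert sorted(c.score for c in direct) == sorted(c.score for c in swapped)

    def test_bulge_and_central_geometry_enforced(self):
        genome, truth, _ = build_locus(LocusParams(seed=0))
        j = CircularJunction(genome.id, truth.circle_start, truth.circle_end, "+", 5)
        for m in find_bhb(genome, j):
            assert m.central[0][1] - m.central[0][0] == 4
            assert m.bulge1[1] - m.bulge1[0] == 3
            assert m.bulge2[1] - m.bulge2[0] == 3
            assert m.outer1[0][1] - m.outer1[0][0] >= 2
            assert m.outer2[0][1] - m.outer2[0][0] >= 2

    def test_motif_invariants_validated_at_construction(self):
        with pytest.raises(ValueError, match="central"):
            BHBMotif("s", (0, 12), (20, 32), ((0, 2), (30, 32)), ((5, 8), (25, 28)),
                     ((8, 10), (22, 24)), (2, 5), (22, 25), 4, 24, 7)


class TestPredictCleavage:
    def test_cut_offset_arithmetic(self, default_locus):
        _, truth, _ = default_locus
        bhb = truth.bhb
        c1, c2 = predict_cleavage(bhb, cut_offset=2)
        assert c1 == bhb.bulge1[0] + 2 and c2 == bhb.bulge2[0] + 2
        d1, d2 = predict_cleavage(bhb, cut_offset=1)
        assert (c1 - d1, c2 - d2) == (1, 1)

    def test_shared_convention_round_trip(self, default_locus):
        _, truth, _ = default_locus
        assert predict_cleavage(truth.bhb, truth.cut_offset) == (
            truth.circle_start,
            truth.circle_end,
        )

    def test_invalid_offset_rejected(self, default_locus):
        _, truth, _ = default_locus
        with pytest.raises(ValueError):
            predict_cleavage(truth.bhb, cut_offset=3)


class TestValidation:
    def test_truth_bhb_validates_called_junction(self, default_run):
        truth = default_run["truth"]
        j = default_run["junctions"][0]
        assert validate_junction_vs_bhb(j, truth.bhb) is True

    def test_shifted_bhb_fails(self, default_run):
        truth = default_run["truth"]
        j = default_run["junctions"][0]
        import dataclasses

        shifted = dataclasses.replace(
            truth.bhb,
            bulge1=(truth.bhb.bulge1[0] + 1, truth.bhb.bulge1[1] + 1),
            cleavage1=truth.bhb.cleavage1 + 1,
        )
        assert validate_junction_vs_bhb(j, shifted) is False

    def test_missing_bhb_is_false(self, default_run):
        assert validate_junction_vs_bhb(default_run["junctions"][0], None) is False
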