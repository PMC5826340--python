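"""V/J alignment, CDR-H3 extraction, D identification, junction profiling."""

import random

import pytest

from finrep.assign import (
    AMBIGUOUS,
    ScoringScheme,
    align_segment,
    annotate_reads,
    extract_cdrh3,
    identify_d,
    junction_profile,
    sw_score,
)
from finrep.germline import GeneSegment, GermlineSet
from finrep.simulate import SimulationConfig, simulate_repertoire

from conftest import brute_force_sw

LOW = ScoringScheme(min_score=10)


def dseg(sid, seq):
    return GeneSegment(id=sid, segment_class="D", sequence=seq)


class TestAlignSegment:
    def test_verbatim_read_gives_full_span_zero_mismatches(
        self, small_germline
    ):
        v = small_germline.v_segments[3]
        hit = align_segment(v.sequence, small_germline.v_segments)
        assert hit is not None
        assert hit.segment_id == v.id
        assert hit.read_span == (0, len(v.sequence))
        assert hit.germline_span == (0, len(v.sequence))
        assert hit.mismatches == 0 and hit.gaps == 0
        assert hit.score == 2 * len(v.sequence)

    def test_tied_candidates_resolve_to_smallest_id(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGT"
        twins = [
            GeneSegment(id="V1.2", segment_class="V", sequence=seq),
            GeneSegment(id="V1.1", segment_class="V", sequence=seq),
        ]
        hit = align_segment(seq, twins, LOW)
        assert hit is not None and hit.segment_id == "V1.1"

    def test_no_candidate_reaches_min_score(self, small_germline):
        hit = align_segment("ACGT" * 5, small_germline.v_segments,
                            ScoringScheme(min_score=200))
        assert hit is None

    def test_matches_brute_force_smith_waterman_oracle(self):
        """Winner score equals an independent full-matrix DP on every read."""
        rng = random.Random(17)
        candidates = [
            GeneSegment(
                id=f"V1.{i+1}", segment_class="V",
                sequence="".join(rng.choice("ACGT") for _ in range(50)),
            )
            for i in range(8)
        ]
        for _ in range(50):
            if rng.random() < 0.5:
                read = "".join(rng.choice("ACGT") for _ in range(60))
            else:  # mutated fragment of a random candidate
                base = rng.choice(candidates).sequence
                read = "".join(
                    c if rng.random() > 0.15 else rng.choice("ACGT")
                    for c in base[rng.randrange(10):]
                )
                if len(read) < 12:
                    read += "ACGTACGTACGT"
            oracle = {c.id: brute_force_sw(read, c.sequence)
                      for c in candidates}
            best = max(oracle.values())
            hit = align_segment(read, candidates, ScoringScheme(min_score=0),
                                min_score=0)
            assert hit is not None
            assert hit.score == best
            assert oracle[hit.segment_id] == best

    def test_numba_kernel_equals_pairwise_aligner_scores(self):
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="local", match_score=2, mismatch_score=-3,
            open_gap_score=-5, extend_gap_score=-2,
        )
        rng = random.Random(23)
        scheme = ScoringScheme()
        for _ in range(100):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 90)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 90)))
            assert sw_score(a, b, scheme) == aligner.score(a, b)

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            align_segment("ACGT", [])


class TestExtractCdrh3:
    def test_toy_junction_extracted_between_anchors(self, toy_vj_germline):
        gs = toy_vj_germline
        read = "ATGAAATGC" + "GCAAGAGAC" + "TGGGGCCAAGGC"
        v_hit = align_segment(read, gs.v_segments, LOW)
        j_hit = align_segment(read, gs.j_segments, LOW)
        rec = extract_cdrh3(read, v_hit, j_hit, gs)
        assert not isinstance(rec, str)
        assert rec.nt == "GCAAGAGAC"
        assert rec.aa == "ARD"
        assert rec.aa_length == 3
        assert rec.productive

    def test_frame_violation_marks_unproductive(self, toy_vj_germline):
        gs = toy_vj_germline
        read = "ATGAAATGC" + "GGCAAGAGAC" + "TGGGGCCAAGGC"  # 10-nt junction
        v_hit = align_segment(read, gs.v_segments, LOW)
        j_hit = align_segment(read, gs.j_segments, LOW)
        rec = extract_cdrh3(read, v_hit, j_hit, gs)
        assert not isinstance(rec, str)
        assert len(rec.nt) == 10
        assert not rec.productive
        assert rec.aa == ""

    def test_include_anchors_mode_adds_both_motifs(self, toy_vj_germline):
        gs = toy_vj_germline
        read = "ATGAAATGC" + "GCAAGAGAC" + "TGGGGCCAAGGC"
        v_hit = align_segment(read, gs.v_segments, LOW)
        j_hit = align_segment(read, gs.j_segments, LOW)
        rec = extract_cdrh3(read, v_hit, j_hit, gs, include_anchors=True)
        assert not isinstance(rec, str)
        assert rec.nt == "TGC" + "GCAAGAGAC" + "TGG"
        assert rec.aa == "CARDW"

    def test_anchor_trimmed_out_of_alignment_fails(self, toy_vj_germline):
        gs = toy_vj_germline
        # read lacks the V entirely; V alignment covers only junk
        read = "TTTTTTTTTTTT" + "TGGGGCCAAGGC"
        j_hit = align_segment(read, gs.j_segments, LOW)
        v_hit = align_segment("ATGAAA" + read, gs.v_segments,
                              ScoringScheme(min_score=8))
        if v_hit is not None:  # partial V alignment misses the anchor
            out = extract_cdrh3("ATGAAA" + read, v_hit, j_hit, gs)
            assert out == "anchor-not-mapped"


class TestIdentifyD:
    DSET = [dseg("Dm1", "GGTTC"), dseg("Dm2", "TTTTT")]

    def test_unique_longest_match_wins(self):
        m = identify_d("AAGGTTCC", self.DSET)
        assert m is not None
        assert m.segment_id == "Dm1"
        assert m.length == 5
        assert (m.d5_del, m.d3_del) == (0, 0)

    def test_short_remnant_is_ambiguous(self):
        assert identify_d("AGT", [dseg("Dm1", "AGTCC")]) is None

    def test_equal_longest_matches_are_ambiguous(self):
        dset = [dseg("Dm1", "GGTTCA"), dseg("Dm3", "AGGTTC")]
        # interior contains GGTTC (5 nt) from both candidates
        assert identify_d("AAGGTTCAA", dset, min_match=4) is None

    def test_trimmed_match_reports_germline_offsets(self):
        m = identify_d("CCGTTAAACC", [dseg("Dm1", "TTGTTAAATT")])
        assert m is not None
        assert m.length == 6  # GTTAAA
        assert m.d5_del == 2 and m.d3_del == 2

    def test_empty_interior_is_ambiguous(self):
        assert identify_d("", self.DSET) is None


class TestJunctionProfile:
    def test_ambiguous_d_reports_vj_insert_span(self, toy_vj_germline):
        gs = toy_vj_germline
        read = "ATGAAATGC" + "CCCCCCCCCCCCCCCCCCCCC" + "TGGGGCCAAGGC"
        v_hit = align_segment(read, gs.v_segments, LOW)
        j_hit = align_segment(read, gs.j_segments, LOW)
        assert v_hit.read_span[1] == 9 and j_hit.read_span[0] == 30
        profile = junction_profile(v_hit, j_hit, None, 9, gs)
        assert profile.vj_ins == 21
        assert profile.v3_del == 0 and profile.j5_del == 0
        assert profile.vd_ins is None

    def test_zero_trimming_zero_insertion_all_fields_zero(
        self, toy_vj_germline
    ):
        gs = toy_vj_germline
        read = "ATGAAATGC" + "GCAAGAGA" + "TGGGGCCAAGGC"  # exact D between
        v_hit = align_segment(read, gs.v_segments, LOW)
        j_hit = align_segment(read, gs.j_segments, LOW)
        d = identify_d("GCAAGAGA", gs.d_segments)
        profile = junction_profile(v_hit, j_hit, d, 9, gs)
        assert (profile.v3_del, profile.j5_del) == (0, 0)
        assert (profile.d5_del, profile.d3_del) == (0, 0)
        assert (profile.vd_ins, profile.dj_ins) == (0, 0)
        assert not profile.clipped


class TestSimulatorRoundTrip:
    def test_noise_free_reads_recover_truth_exactly(
        self, paired_germlines, noise_free_repertoire
    ):
        """100% V/J/CDR-H3 recovery; D and junctions exact where D >= 4 nt."""
        from finrep.preprocess import ReadPair, merge_pairs
        from finrep.simulate import DEFAULT_C_STUBS

        pairs, truths = noise_free_repertoire
        primer_len = 20
        reads = []
        for (rid, m1, q1, m2, q2), t in zip(pairs, truths):
            merged = merge_pairs(
                ReadPair(rid, m1, [ord(c) - 33 for c in q1], m2,
                         [ord(c) - 33 for c in q2]),
                min_assembled_len=0,
            )
            core = merged.sequence[
                primer_len: len(merged.sequence)
                - len(DEFAULT_C_STUBS[t.isotype])
            ]
            reads.append((rid, core, t.isotype))
        df = annotate_reads(reads, paired_germlines)
        by_id = {t.read_id: t for t in truths}
        for row in df.itertuples():
            t = by_id[row.read_id]
            assert row.failure_reason == ""
            assert row.v_id == t.v_id
            assert row.j_id == t.j_id
            assert row.cdr3_nt == t.cdr3_nt
            assert row.v3_del == t.v3_del and row.j5_del == t.j5_del
            if t.d_remnant_len >= 4:
                assert row.d_id == t.d_id
                assert row.d5_del == t.d5_del and row.d3_del == t.d3_del
                assert row.vd_ins == t.vd_ins and row.dj_ins == t.dj_ins
            else:
                assert row.d_id == AMBIGUOUS

    def test_assignment_rate_does_not_improve_with_noise(
        self, paired_germlines
    ):
        rates = []
        for error_rate in (0.0, 0.05):
            config = SimulationConfig(
                seed=31, n_reads=60, isotype_mix=1.0, error_rate=error_rate,
                require_unambiguous_junctions=False,
            )
            pairs, truths = simulate_repertoire(paired_germlines, config)
            from finrep.preprocess import ReadPair, merge_pairs

            reads = []
            for (rid, m1, q1, m2, q2), t in zip(pairs, truths):
                merged = merge_pairs(
                    ReadPair(rid, m1, [ord(c) - 33 for c in q1], m2,
                             [ord(c) - 33 for c in q2]),
                    min_assembled_len=0,
                )
                reads.append((rid, merged.sequence[20:], t.isotype))
            df = annotate_reads(reads, paired_germlines)
            ok = sum(
                row.v_id == by.v_id and row.j_id == by.j_id
                for row, by in zip(df.itertuples(), truths)
            )
            rates.append(ok / len(truths))
        assert rates[0] == 1.0
        assert rates[1] <= rates[0]
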