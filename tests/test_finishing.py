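"""Chimera handling, orientation, consensus grouping and scaffolding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_seq, simulate_perfect_pairs
from vgwalk.assembly import Contig
from vgwalk.core import DnaSequence, revcomp
from vgwalk.finishing import (GapRecord, PairCoverageProfile, Scaffold,
                              detect_chimeric_contigs, group_and_consensus,
                              order_and_join, orient_contigs,
                              perfect_pair_coverage, split_contig)


class TestScaffoldType:
    def test_render_and_length(self, rng):
        a, b = random_seq(rng, 300), random_seq(rng, 200)
        s = Scaffold("s", [Contig("a", a), GapRecord(500), Contig("b", b)])
        assert s.sequence() == a + "N" * 500 + b
        assert len(s) == 1000
        assert s.total_contig_length() == 500

    def test_alternation_enforced(self, rng):
        with pytest.raises(ValueError):
            Scaffold("s", [GapRecord(500), Contig("a", random_seq(rng, 50))])
        with pytest.raises(ValueError):
            Scaffold("s", [Contig("a", random_seq(rng, 50)),
                           Contig("b", random_seq(rng, 50))])

    @given(st.lists(st.integers(150, 400), min_size=1, max_size=5),
           st.integers(0, 2 ** 31))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_part_structure(self, lens, seed):
        rng = np.random.default_rng(seed)
        parts = []
        for i, n in enumerate(lens):
            if parts:
                parts.append(GapRecord(500))
            parts.append(Contig(f"c{i}", random_seq(rng, n)))
        s = Scaffold("s", parts)
        back = Scaffold.from_sequence("s", s.sequence(), min_gap=100)
        assert [len(c.bases) for c in back.contigs()] == lens
        assert len(back.contigs()) == len(s.contigs())
        assert back.sequence() == s.sequence()


class TestChimeraDetection:
    def test_duplicated_exon_flagged(self, rng):
        exon = random_seq(rng, 150)
        transcript = DnaSequence("t", random_seq(rng, 100) + exon
                                 + random_seq(rng, 100))
        chimera = Contig("c", random_seq(rng, 80) + exon
                         + random_seq(rng, 300) + exon + random_seq(rng, 80))
        assert detect_chimeric_contigs(transcript, [chimera]) == [chimera]

    def test_multi_exon_contig_not_flagged(self, rng):
        e1, e2 = random_seq(rng, 150), random_seq(rng, 150)
        transcript = DnaSequence("t", e1 + e2)
        normal = Contig("c", e1 + random_seq(rng, 400) + e2)
        assert detect_chimeric_contigs(transcript, [normal]) == []

    def test_single_hsp_not_flagged(self, rng):
        exon = random_seq(rng, 150)
        transcript = DnaSequence("t", exon)
        contig = Contig("c", random_seq(rng, 50) + exon + random_seq(rng, 50))
        assert detect_chimeric_contigs(transcript, [contig]) == []


class TestPerfectPairCoverage:
    def test_own_pairs_cover_everything(self, rng):
        seq = random_seq(rng, 1200)
        contig = Contig("c", seq)
        pairs = simulate_perfect_pairs(rng, seq, coverage=30)
        profile = perfect_pair_coverage(contig, pairs, insert_range=(100, 400))
        interior = profile.coverage[100:-100]
        assert (interior > 0).all()
        assert profile.spanned[100:-100].all()

    def test_one_mismatch_contributes_nothing(self, rng):
        seq = random_seq(rng, 600)
        contig = Contig("c", seq)
        pairs = simulate_perfect_pairs(rng, seq, coverage=2)
        m1 = pairs[0].mate1.bases
        corrupted = ("A" if m1[50] != "A" else "C")
        bad = pairs[0].__class__(
            "bad",
            DnaSequence("bad", m1[:50] + corrupted + m1[51:]),
            pairs[0].mate2)
        profile = perfect_pair_coverage(contig, [bad],
                                        insert_range=(100, 400))
        assert profile.coverage.sum() == 0

    def test_junction_uncovered(self, rng):
        locus_a, locus_b = random_seq(rng, 600), random_seq(rng, 600)
        chimera = Contig("c", locus_a + locus_b)
        pairs = (simulate_perfect_pairs(rng, locus_a, coverage=30, prefix="a")
                 + simulate_perfect_pairs(rng, locus_b, coverage=30,
                                          prefix="b"))
        profile = perfect_pair_coverage(chimera, pairs,
                                        insert_range=(100, 400))
        junction = slice(595, 605)
        assert (profile.coverage[junction] == 0).any() or \
            not profile.spanned[junction].all()


class TestSplitContig:
    def _profile(self, contig, zero_runs):
        n = len(contig.bases)
        cov = np.full(n, 5, dtype=np.int32)
        spanned = np.ones(n, dtype=bool)
        for s, e in zero_runs:
            cov[s:e] = 0
            spanned[s:e] = False
        return PairCoverageProfile(contig.contig_id, cov, spanned)

    def test_internal_zero_run_splits(self, rng):
        contig = Contig("c", random_seq(rng, 1000))
        parts = split_contig(contig, self._profile(contig, [(400, 450)]))
        assert [p.bases for p in parts] == [contig.bases[:400],
                                            contig.bases[450:]]

    def test_terminal_zero_run_kept(self, rng):
        contig = Contig("c", random_seq(rng, 1000))
        parts = split_contig(contig, self._profile(contig, [(970, 1000)]))
        assert len(parts) == 1 and parts[0].bases == contig.bases

    def test_uniform_coverage_unchanged(self, rng):
        contig = Contig("c", random_seq(rng, 500))
        parts = split_contig(contig, self._profile(contig, []))
        assert parts == [contig]

    def test_never_grows(self, rng):
        contig = Contig("c", random_seq(rng, 800))
        parts = split_contig(contig, self._profile(contig,
                                                   [(100, 140), (600, 660)]))
        assert sum(len(p.bases) for p in parts) <= len(contig.bases)
        assert len(parts) == 3


class TestOrientation:
    def test_minus_contig_flipped(self, rng):
        transcript = DnaSequence("t", random_seq(rng, 300))
        contig = Contig("c", revcomp(random_seq(rng, 50) + transcript.bases
                                     + random_seq(rng, 50)))
        out = orient_contigs(transcript, [contig])
        assert transcript.bases in out[0].bases
        assert not out[0].orientation_flagged

    def test_plus_contig_unchanged(self, rng):
        transcript = DnaSequence("t", random_seq(rng, 300))
        contig = Contig("c", transcript.bases + random_seq(rng, 50))
        out = orient_contigs(transcript, [contig])
        assert out[0].bases == contig.bases

    def test_mixed_strand_flagged(self, rng):
        e1, e2 = random_seq(rng, 120), random_seq(rng, 120)
        transcript = DnaSequence("t", e1 + e2)
        contig = Contig("c", e1 + e2 + random_seq(rng, 60) + revcomp(e2[:80]))
        out = orient_contigs(transcript, [contig])
        assert out[0].orientation_flagged

    def test_no_hsp_passthrough_flagged(self, rng):
        transcript = DnaSequence("t", random_seq(rng, 300))
        contig = Contig("c", random_seq(rng, 200))
        out = orient_contigs(transcript, [contig])
        assert out[0].bases == contig.bases
        assert out[0].orientation_flagged


class TestGroupConsensus:
    def test_one_substitution_collapses(self, rng):
        base = random_seq(rng, 600)
        variant = base[:300] + ("A" if base[300] != "A" else "C") + base[301:]
        out = group_and_consensus([Contig("a", base), Contig("b", variant)])
        assert len(out) == 1
        assert out[0].bases == base  # ties go to the longest/first member

    def test_majority_wins_with_three(self, rng):
        base = random_seq(rng, 600)
        variant = base[:300] + ("A" if base[300] != "A" else "C") + base[301:]
        out = group_and_consensus([Contig("a", variant), Contig("b", base),
                                   Contig("c", base)])
        assert len(out) == 1
        assert out[0].bases == base

    def test_unrelated_contigs_unchanged(self, rng):
        a, b = Contig("a", random_seq(rng, 400)), Contig("b", random_seq(rng, 400))
        out = group_and_consensus([a, b])
        assert {c.bases for c in out} == {a.bases, b.bases}


class TestOrderAndJoin:
    def test_end_overlap_fuses_without_gap(self, rng):
        e1, e2 = random_seq(rng, 150), random_seq(rng, 150)
        intron = random_seq(rng, 300)
        transcript = DnaSequence("t", e1 + e2)
        a = Contig("a", e1 + intron[:175])
        b = Contig("b", intron[125:] + e2)  # 50-base perfect end overlap
        scaffold = order_and_join(transcript, [a, b])
        assert len(scaffold.contigs()) == 1
        assert scaffold.sequence() == e1 + intron + e2
        assert not any(isinstance(p, GapRecord) for p in scaffold.parts)

    def test_no_overlap_gets_500n_gap(self, rng):
        e1, e2 = random_seq(rng, 150), random_seq(rng, 150)
        transcript = DnaSequence("t", e1 + e2)
        a, b = Contig("a", e1), Contig("b", e2)
        scaffold = order_and_join(transcript, [a, b])
        assert scaffold.sequence() == e1 + "N" * 500 + e2

    def test_single_contig_no_gaps(self, rng):
        exon = random_seq(rng, 200)
        scaffold = order_and_join(DnaSequence("t", exon),
                                  [Contig("a", exon)])
        assert scaffold.sequence() == exon

    def test_order_follows_transcript(self, rng):
        exons = [random_seq(rng, 150) for _ in range(3)]
        transcript = DnaSequence("t", "".join(exons))
        contigs = [Contig("c2", exons[2]), Contig("c0", exons[0]),
                   Contig("c1", exons[1])]
        scaffold = order_and_join(transcript, contigs)
        assert [c.bases for c in scaffold.contigs()] == exons

    def test_unmappable_contig_dropped(self, rng):
        exon = random_seq(rng, 200)
        scaffold = order_and_join(DnaSequence("t", exon),
                                  [Contig("a", exon),
                                   Contig("junk", random_seq(rng, 200))])
        assert [c.bases for c in scaffold.contigs()] == [exon]
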