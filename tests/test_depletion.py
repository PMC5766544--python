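"""Median k-mer coverage depletion against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_lower_median, random_seq
from vgwalk.core import DnaSequence, ReadPair, canonical_kmer, revcomp
from vgwalk.depletion import (DepletionConfig, build_kmer_table,
                              filter_read_pairs, median_kmer_coverage,
                              read_kmer_counts)
from vgwalk.simulate import (RepeatFamily, SimConfig, extract_transcripts,
                             simulate_genome, simulate_reads)


def pair_of(m1: str, m2: str, pid: str = "p0") -> ReadPair:
    return ReadPair(pid, DnaSequence(pid, m1), DnaSequence(pid, m2))


class TestBuildKmerTable:
    def test_homopolymer_counts(self):
        # 40 - 31 + 1 = 10 occurrences per mate
        table = build_kmer_table([pair_of("A" * 40, "C" * 40)], k=31)
        assert table.get("A" * 31) == 10
        assert table.get("C" * 31) == 10
        assert len(table) == 2

    def test_strand_symmetric_counts_double(self, rng):
        seq = random_seq(rng, 60)
        table = build_kmer_table([pair_of(seq, revcomp(seq))], k=31)
        counts = [c for _, c in table.items()]
        assert counts and all(c % 2 == 0 for c in counts)

    def test_canonical_equals_revcomp_lookup(self, rng):
        seq = random_seq(rng, 50)
        table = build_kmer_table([pair_of(seq, "T" * 40)], k=31)
        kmer = seq[:31]
        assert table.get(kmer) == table.get(revcomp(kmer))

    def test_n_windows_skipped(self):
        table = build_kmer_table([pair_of("ACGTN" + "A" * 33, "C" * 35)], k=31)
        for kmer, _ in table.items():
            assert "N" not in kmer
        # only windows fully right of the N: positions 5..7 of mate1
        assert sum(c for k, c in table.items() if set(k) <= {"A"}) == 3

    def test_reads_shorter_than_k_empty_table(self):
        table = build_kmer_table([pair_of("ACGT", "ACGT")], k=31)
        assert len(table) == 0
        assert table.get("A" * 31) == 0


class TestMedianCoverage:
    def test_constant_multiset(self):
        table = build_kmer_table([pair_of("A" * 37, "A" * 37)], k=31)
        # every A-kmer has count 14; median is 14
        assert median_kmer_coverage(DnaSequence("r", "A" * 37), table) == 14

    def test_lower_median_1_1_9(self):
        # counts {AAA:9, AAC:1, ACG:1}; read AAACG has multiset {9,1,1}
        reads = [pair_of("AAACG", "T" * 3)]
        reads += [pair_of("AAA", "T" * 3, pid=f"x{i}") for i in range(8)]
        table = build_kmer_table(reads, k=3)
        med = median_kmer_coverage(DnaSequence("r", "AAACG"), table)
        assert med == oracle_lower_median([9, 1, 1]) == 1

    def test_short_read_uncounted(self):
        table = build_kmer_table([pair_of("A" * 40, "A" * 40)], k=31)
        assert median_kmer_coverage(DnaSequence("r", "A" * 30), table) is None

    @given(st.integers(0, 2 ** 31))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = 7
        reads = [random_seq(rng, int(rng.integers(10, 40))) for _ in range(8)]
        pairs = [pair_of(r, revcomp(r), pid=f"p{i}")
                 for i, r in enumerate(reads)]
        table = build_kmer_table(pairs, k=k)
        probe = reads[0]
        counts = [table.get(probe[i : i + k])
                  for i in range(len(probe) - k + 1)]
        expected = oracle_lower_median(counts)
        assert median_kmer_coverage(DnaSequence("r", probe), table) == expected

    def test_n_kmers_contribute_zero(self):
        table = build_kmer_table([pair_of("AAAAA", "AAAAA")], k=3)
        read = DnaSequence("r", "AANAA")
        counts = sorted(read_kmer_counts(read, table).tolist())
        assert counts == [0, 0, 0]  # every window touches the N


class TestFilterPairs:
    def _replicated_table(self, rng, medians):
        """One template pair per requested median, replicated to that count."""
        templates = {}
        pairs = []
        pool = []
        for m, med in enumerate(medians):
            seq = random_seq(rng, 50)
            templates[f"t{m}"] = pair_of(seq, revcomp(seq[:40]) + random_seq(rng, 10),
                                         pid=f"t{m}")
        # counting pool: mate1 of each template appears `med` times in total
        for m, med in enumerate(medians):
            t = templates[f"t{m}"]
            pool.append(t)
            for r in range(med - 2):  # template contributes 2 (mate1 + rc in mate2)
                pool.append(pair_of(t.mate1.bases, "T" * 50, pid=f"c{m}_{r}"))
        return templates, pool

    def test_boundary_40_retained_41_removed(self, rng):
        # build pairs whose mates have exact, known medians via replication
        seq40 = random_seq(rng, 60)
        seq41 = random_seq(rng, 60)
        pool = []
        for i in range(40):
            pool.append(pair_of(seq40, seq40, pid=f"a{i}"))
        for i in range(41):
            pool.append(pair_of(seq41, seq41, pid=f"b{i}"))
        table = build_kmer_table(pool, k=31)
        probe40 = pair_of(seq40, seq40, pid="probe40")
        probe41 = pair_of(seq41, seq41, pid="probe41")
        assert median_kmer_coverage(probe40.mate1, table) == 40 * 2
        cfg = DepletionConfig(high_cutoff=80)
        retained, report = filter_read_pairs([probe40, probe41], table, cfg)
        assert [p.pair_id for p in retained] == ["probe40"]
        assert report.removed_high == 1

    def test_low_cutoff_boundary(self, rng):
        seq = random_seq(rng, 60)
        table = build_kmer_table([pair_of(seq, seq)], k=31)
        probe = pair_of(seq, seq)
        # median is 2 (> low_cutoff 1) -> retained
        retained, _ = filter_read_pairs([probe], table)
        assert retained
        # raising low_cutoff to 2 removes it
        retained, report = filter_read_pairs(
            [probe], table, DepletionConfig(low_cutoff=2))
        assert not retained and report.removed_low == 1

    def test_mixed_pair_removed_by_high_mate(self, rng):
        hi, lo = random_seq(rng, 60), random_seq(rng, 60)
        pool = [pair_of(hi, hi, pid=f"h{i}") for i in range(25)]
        pool.append(pair_of(lo, lo, pid="lo"))
        table = build_kmer_table(pool, k=31)
        probe = pair_of(hi, lo, pid="probe")  # medians (50, 4)
        retained, report = filter_read_pairs([probe], table)
        assert not retained
        assert report.removed_high == 1

    def test_ambiguous_pair_removed(self, rng):
        seq = random_seq(rng, 60)
        table = build_kmer_table([pair_of(seq, seq)] * 5, k=31)
        probe = pair_of(seq[:30] + "N" + seq[31:], seq)
        retained, report = filter_read_pairs([probe], table)
        assert not retained
        assert report.removed_ambiguous == 1

    def test_monotone_in_cutoffs(self, rng):
        reads = [random_seq(rng, 50) for _ in range(30)]
        pairs = []
        for i, r in enumerate(reads):
            reps = int(rng.integers(1, 6))
            for j in range(reps):
                pairs.append(pair_of(r, revcomp(r), pid=f"p{i}_{j}"))
        table = build_kmer_table(pairs, k=31)

        def retained_ids(low, high):
            cfg = DepletionConfig(low_cutoff=low, high_cutoff=high)
            kept, _ = filter_read_pairs(pairs, table, cfg)
            return {p.pair_id for p in kept}

        for high in (2, 4, 8, 16):
            assert retained_ids(0, high) <= retained_ids(0, high + 2)
        for low in (0, 1, 2, 4):
            assert retained_ids(low + 1, 50) <= retained_ids(low, 50)

    def test_report_totals(self, rng):
        seq = random_seq(rng, 60)
        pairs = [pair_of(seq, seq, pid=f"p{i}") for i in range(4)]
        table = build_kmer_table(pairs, k=31)
        retained, report = filter_read_pairs(pairs, table)
        assert report.n_input == 4
        assert report.n_retained == len(retained)
        total_removed = (report.removed_low + report.removed_high
                         + report.removed_ambiguous)
        assert report.n_input == report.n_retained + total_removed


@pytest.mark.slow
class TestSyntheticDepletion:
    def test_repeat_pairs_removed_unique_retained(self):
        """On a genome with one identical 2 kb repeat at 100 copies, >=95% of
        pairs wholly inside repeat copies are removed and <5% of pairs wholly
        inside unique sequence are removed."""
        cfg = SimConfig(seed=77, genome_len=400_000, n_genes=0,
                        repeat_families=(RepeatFamily(2000, 100, 0.0),),
                        coverage=20, error_rate=0.0)
        truth = simulate_genome(cfg)
        pairs = simulate_reads(truth, cfg)
        table = build_kmer_table(pairs, 31)
        retained, _ = filter_read_pairs(pairs, table)
        retained_ids = {p.pair_id for p in retained}
        repeat_iv = [(r.start, r.end) for r in truth.repeats]
        in_repeat, in_unique = [], []
        margin = 50
        for prov in truth.read_provenance:
            span = (prov.start, prov.start + prov.insert)
            if any(s <= span[0] and span[1] <= e for s, e in repeat_iv):
                in_repeat.append(prov.pair_id)
            elif not any(s - margin < span[1] and span[0] < e + margin
                         for s, e in repeat_iv):
                in_unique.append(prov.pair_id)
        assert len(in_repeat) > 200 and len(in_unique) > 1000
        removed_repeat = sum(1 for pid in in_repeat
                             if pid not in retained_ids)
        removed_unique = sum(1 for pid in in_unique
                             if pid not in retained_ids)
        assert removed_repeat / len(in_repeat) >= 0.95
        assert removed_unique / len(in_unique) < 0.05
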