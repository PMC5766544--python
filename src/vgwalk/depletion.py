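"""Median k-mer coverage read-pair depletion.

Pairs dominated by high-copy repeats are removed by thresholding each mate's
median canonical 31-mer multiplicity; pairs containing ambiguous bases are
removed outright.  Counting is exact (hash/array backed), not sketch-based:
desk-scale inputs fit in memory and exactness keeps the oracles simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from . import kmers
from .core import DnaSequence, ReadPair


@dataclass(frozen=True, slots=True)
class DepletionConfig:
    """Thresholds for pair removal.

    A pair is removed if either mate's median coverage is <= ``low_cutoff``
    or > ``high_cutoff``, or (when ``drop_ambiguous``) either mate contains N.
    """

    k: int = 31
    low_cutoff: int = 1
    high_cutoff: int = 40
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.low_cutoff < self.high_cutoff):
            raise ValueError("need 0 <= low_cutoff < high_cutoff")
        if self.k % 2 == 0 or not (3 <= self.k <= 63):
            raise ValueError("k must be odd and within [3, 63]")


class KmerCountTable:
    """Multiplicities of canonical k-mers over a read set.

    Backed by a sorted uint64 code array plus counts; absent k-mers have
    count 0.  Strand symmetry holds by construction (canonical keys only).
    """

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray):
        self.k = k
        self._codes = codes
        self._counts = counts

    def __len__(self) -> int:
        return len(self._codes)

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Counts for an array of canonical codes (0 where absent)."""
        if len(self._codes) == 0:
            return np.zeros(len(codes), dtype=np.int64)
        idx = np.searchsorted(self._codes, codes)
        idx_c = np.minimum(idx, len(self._codes) - 1)
        hit = self._codes[idx_c] == codes
        out = np.where(hit, self._counts[idx_c], 0)
        return out.astype(np.int64)

    def get(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        codes, valid = kmers.canonical_codes(kmer, self.k)
        if not valid[0]:
            return 0
        return int(self.lookup(codes[:1])[0])

    def items(self) -> Iterator[tuple[str, int]]:
        """Decode all (kmer, count) entries; intended for small tables."""
        for code, count in zip(self._codes, self._counts):
            yield kmers.decode(int(code), self.k), int(count)


def _iter_mates(pairs: Iterable[ReadPair]) -> Iterator[DnaSequence]:
    for pair in pairs:
        yield pair.mate1
        yield pair.mate2


def build_kmer_table(pairs: Iterable[ReadPair], k: int = 31) -> KmerCountTable:
    """Count canonical k-mers across all mates; k-mers containing N are
    skipped.  Reads shorter than k contribute nothing (warning-free no-op;
    an entirely too-short read set yields an empty table).
    """
    chunks: list[np.ndarray] = []
    # group equal-length reads into batches for vectorized encoding
    by_len: dict[int, list[str]] = {}
    for mate in _iter_mates(pairs):
        if len(mate.bases) < k:
            continue
        by_len.setdefault(len(mate.bases), []).append(mate.bases)
    for length, seqs in sorted(by_len.items()):
        for i in range(0, len(seqs), 20000):
            batch = seqs[i : i + 20000]
            codes, valid = kmers.canonical_codes_batch(batch, k)
            chunks.append(codes[valid])
    if not chunks:
        return KmerCountTable(k, np.empty(0, np.uint64), np.empty(0, np.int64))
    all_codes = np.concatenate(chunks)
    codes, counts = np.unique(all_codes, return_counts=True)
    return KmerCountTable(k, codes, counts.astype(np.int64))


def read_kmer_counts(read: DnaSequence, table: KmerCountTable) -> np.ndarray:
    """The multiset of counts of the read's canonical k-mers.

    Windows containing N contribute count 0 (depressing the median) rather
    than being skipped; moot when ambiguous pairs are dropped anyway.
    """
    codes, valid = kmers.canonical_codes(read.bases, table.k)
    counts = table.lookup(codes)
    counts[~valid] = 0
    return counts


def median_kmer_coverage(read: DnaSequence, table: KmerCountTable) -> int | None:
    """Lower median of the read's k-mer counts; ``None`` ("uncounted") for
    reads shorter than k, treated as coverage 0 by the filter.

    The lower middle element is taken for even-sized multisets so the
    statistic stays integral, matching k-mer-counting tool conventions.
    """
    counts = read_kmer_counts(read, table)
    if len(counts) == 0:
        return None
    counts = np.sort(counts)
    return int(counts[(len(counts) - 1) // 2])


@dataclass(slots=True)
class DepletionReport:
    n_input: int = 0
    n_retained: int = 0
    removed_ambiguous: int = 0
    removed_low: int = 0
    removed_high: int = 0

    def to_tsv(self) -> str:
        header = "pairs_in\tretained\tremoved_ambiguous\tremoved_low\tremoved_high"
        row = (f"{self.n_input}\t{self.n_retained}\t{self.removed_ambiguous}"
               f"\t{self.removed_low}\t{self.removed_high}")
        return header + "\n" + row + "\n"


def median_coverages(seqs: list[str], table: KmerCountTable) -> np.ndarray:
    """Vectorized lower-median k-mer coverage for many reads at once.

    Reads shorter than k get median 0 ("uncounted").  Equal-length reads are
    batched; N-containing windows contribute count 0.
    """
    out = np.zeros(len(seqs), dtype=np.int64)
    k = table.k
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        if len(s) >= k:
            by_len.setdefault(len(s), []).append(i)
    for length, idxs in sorted(by_len.items()):
        for lo in range(0, len(idxs), 20000):
            chunk = idxs[lo : lo + 20000]
            codes, valid = kmers.canonical_codes_batch(
                [seqs[i] for i in chunk], k)
            counts = table.lookup(codes.ravel()).reshape(codes.shape)
            counts[~valid] = 0
            counts.sort(axis=1)
            med = counts[:, (counts.shape[1] - 1) // 2]
            out[chunk] = med
    return out


def filter_read_pairs(
    pairs: Iterable[ReadPair],
    table: KmerCountTable,
    cfg: DepletionConfig | None = None,
) -> tuple[list[ReadPair], DepletionReport]:
    """Apply the depletion rule pair-wise.

    Removal reason precedence when several rules fire: ambiguous, then low,
    then high.
    """
    cfg = cfg or DepletionConfig()
    pairs = list(pairs)
    report = DepletionReport(n_input=len(pairs))
    med1 = median_coverages([p.mate1.bases for p in pairs], table)
    med2 = median_coverages([p.mate2.bases for p in pairs], table)
    retained: list[ReadPair] = []
    for pair, m1, m2 in zip(pairs, med1, med2):
        if cfg.drop_ambiguous and ("N" in pair.mate1.bases
                                   or "N" in pair.mate2.bases):
            report.removed_ambiguous += 1
            continue
        if min(m1, m2) <= cfg.low_cutoff:
            report.removed_low += 1
            continue
        if max(m1, m2) > cfg.high_cutoff:
            report.removed_high += 1
            continue
        retained.append(pair)
        report.n_retained += 1
    return retained, report
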