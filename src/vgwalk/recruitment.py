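"""Read indexing and maximal-exact-match (MEM) recruitment.

Reads — not the reference — are indexed; a query recruits every read pair
one of whose mates shares a maximal exact match of at least the requested
length, on either strand.  Recruitment is on MEMs rather than strict SMEMs:
for a recruit/no-recruit decision the two differ only when a read carries
stacked matches, which cannot change set membership.

Implementation contract: fixed-length seeds located via a hash table, then
extended and verified for exactness and maximality.  Seeds are sampled with
a stride derived from the smallest match length the index guarantees
(``min_query_match``), so complete recall holds for any query threshold at
or above it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import kmers
from .core import DnaSequence, PairingError, ReadPair, revcomp


class IndexConfigError(ValueError):
    """Raised when a query threshold violates the index's recall guarantee."""


@dataclass(frozen=True, slots=True)
class MatchHit:
    """One maximal exact match between a query and a mate.

    ``strand == '-'`` means the read segment equals the reverse complement of
    the query segment.  Both intervals are 0-based half-open and equal in
    length.
    """

    pair_id: str
    mate: int
    read_interval: tuple[int, int]
    query_interval: tuple[int, int]
    strand: str
    length: int


class ReadIndex:
    """Seed table over a read-pair collection supporting MEM search.

    Immutable once built; rebuilding from the same reads yields identical
    search results.
    """

    def __init__(self, pairs: Sequence[ReadPair], seed_len: int = 20,
                 min_query_match: int | None = None):
        if min_query_match is None:
            min_query_match = seed_len
        if min_query_match < seed_len:
            raise IndexConfigError("min_query_match must be >= seed_len")
        self.seed_len = seed_len
        self.min_query_match = min_query_match
        self._stride = min_query_match - seed_len + 1
        self._pairs = list(pairs)
        self._by_id = {p.pair_id: p for p in self._pairs}
        if len(self._by_id) != len(self._pairs):
            raise PairingError("duplicate pair_id in read set")
        # flat mate arrays
        self._mate_seqs: list[str] = []
        self._mate_pair: list[int] = []
        self._mate_no: list[int] = []
        for i, p in enumerate(self._pairs):
            for mate_no, mate in ((1, p.mate1), (2, p.mate2)):
                self._mate_seqs.append(mate.bases)
                self._mate_pair.append(i)
                self._mate_no.append(mate_no)
        self._seeds: dict[int, list[tuple[int, int]]] = {}
        k = seed_len
        for mi, seq in enumerate(self._mate_seqs):
            if len(seq) < k:
                continue
            codes, valid = kmers.forward_codes(seq, k)
            last = len(seq) - k
            positions = list(range(0, last + 1, self._stride))
            if positions[-1] != last:
                positions.append(last)  # cover the read's tail window
            for pos in positions:
                if valid[pos]:
                    self._seeds.setdefault(int(codes[pos]), []).append((mi, pos))

    # -- accessors -------------------------------------------------------
    @property
    def pairs(self) -> list[ReadPair]:
        return list(self._pairs)

    def get_pair(self, pair_id: str) -> ReadPair:
        return self._by_id[pair_id]

    def __len__(self) -> int:
        return len(self._pairs)

    # -- search ----------------------------------------------------------
    def find_exact_matches(self, query: DnaSequence | str,
                           min_match_len: int) -> list[MatchHit]:
        """Exactly the maximal exact matches of length >= ``min_match_len``
        between the query and any mate, both strands, in deterministic order
        (pair_id, mate, query offset).
        """
        if min_match_len < self.min_query_match:
            raise IndexConfigError(
                f"min_match_len {min_match_len} below index guarantee "
                f"{self.min_query_match}")
        bases = query.bases if isinstance(query, DnaSequence) else query
        hits: dict[tuple, MatchHit] = {}
        for strand, q in (("+", bases), ("-", revcomp(bases))):
            self._search_strand(q, strand, len(bases), min_match_len, hits)
        out = list(hits.values())
        out.sort(key=lambda h: (h.pair_id, h.mate, h.query_interval,
                                h.read_interval, h.strand))
        return out

    def _search_strand(self, q: str, strand: str, qlen: int,
                       min_match_len: int, hits: dict) -> None:
        k = self.seed_len
        if len(q) < k:
            return
        codes, valid = kmers.forward_codes(q, k)
        diag_done: dict[tuple[int, int], int] = {}
        for qp in range(len(q) - k + 1):
            if not valid[qp]:
                continue
            entries = self._seeds.get(int(codes[qp]))
            if not entries:
                continue
            for mi, rp in entries:
                key = (mi, qp - rp)
                if qp < diag_done.get(key, -1):
                    continue
                read = self._mate_seqs[mi]
                # extend left
                left = 0
                while (qp - left > 0 and rp - left > 0
                       and q[qp - left - 1] == read[rp - left - 1]):
                    left += 1
                # extend right
                right = k
                while (qp + right < len(q) and rp + right < len(read)
                       and q[qp + right] == read[rp + right]):
                    right += 1
                diag_done[key] = qp + right
                length = left + right
                if length < min_match_len:
                    continue
                qs, qe = qp - left, qp + right
                rs, re = rp - left, rp + right
                if strand == "-":
                    qs, qe = qlen - qe, qlen - qs
                pi = self._mate_pair[mi]
                hit = MatchHit(self._pairs[pi].pair_id, self._mate_no[mi],
                               (rs, re), (qs, qe), strand, length)
                hits[(mi, strand, qs, rs)] = hit

    def recruit_pairs(self, queries: Iterable[DnaSequence | str],
                      min_match_len: int) -> set[str]:
        """pair_ids with >= 1 MEM against >= 1 query (mates travel together)."""
        recruited: set[str] = set()
        for query in queries:
            for hit in self.find_exact_matches(query, min_match_len):
                recruited.add(hit.pair_id)
        return recruited

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Persist to disk; ``load`` rebuilds an identical index."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"seed_len": self.seed_len,
                "min_query_match": self.min_query_match}
        (directory / "index.json").write_text(json.dumps(meta))
        with open(directory / "reads.tsv", "w") as fh:
            for p in self._pairs:
                fh.write(f"{p.pair_id}\t{p.mate1.bases}\t{p.mate2.bases}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "ReadIndex":
        directory = Path(directory)
        meta = json.loads((directory / "index.json").read_text())
        pairs = []
        with open(directory / "reads.tsv") as fh:
            for line in fh:
                pid, m1, m2 = line.rstrip("\n").split("\t")
                pairs.append(ReadPair(pid, DnaSequence(pid, m1),
                                      DnaSequence(pid, m2)))
        return cls(pairs, seed_len=meta["seed_len"],
                   min_query_match=meta["min_query_match"])


class ShardedReadIndex:
    """Union of per-shard indexes; search results equal the unsharded case."""

    def __init__(self, pairs: Sequence[ReadPair], n_shards: int,
                 seed_len: int = 20, min_query_match: int | None = None):
        pairs = list(pairs)
        self.shards = [
            ReadIndex(pairs[i::n_shards], seed_len=seed_len,
                      min_query_match=min_query_match)
            for i in range(n_shards)
        ]

    def find_exact_matches(self, query, min_match_len: int) -> list[MatchHit]:
        out: list[MatchHit] = []
        for shard in self.shards:
            out.extend(shard.find_exact_matches(query, min_match_len))
        out.sort(key=lambda h: (h.pair_id, h.mate, h.query_interval,
                                h.read_interval, h.strand))
        return out

    def recruit_pairs(self, queries, min_match_len: int) -> set[str]:
        out: set[str] = set()
        for shard in self.shards:
            out |= shard.recruit_pairs(queries, min_match_len)
        return out


def build_read_index(pairs: Sequence[ReadPair], seed_len: int = 20,
                     min_query_match: int | None = None) -> ReadIndex:
    return ReadIndex(pairs, seed_len=seed_len, min_query_match=min_query_match)


def find_exact_matches(query: DnaSequence, index: ReadIndex,
                       min_match_len: int) -> list[MatchHit]:
    return index.find_exact_matches(query, min_match_len)


def recruit_pairs(queries: Iterable[DnaSequence], index: ReadIndex,
                  min_match_len: int) -> set[str]:
    return index.recruit_pairs(queries, min_match_len)
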