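"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from vgwalk.core import DnaSequence, ReadPair, revcomp

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def tile_reads(seq: str, read_len: int = 100, stride: int = 10) -> list[str]:
    """Deterministic tiling reads covering every position of ``seq``."""
    if len(seq) <= read_len:
        return [seq]
    starts = list(range(0, len(seq) - read_len + 1, stride))
    if starts[-1] != len(seq) - read_len:
        starts.append(len(seq) - read_len)
    return [seq[s : s + read_len] for s in starts]


def make_pairs(reads: list[str], prefix: str = "p") -> list[ReadPair]:
    """Wrap single-end reads into pairs (mate2 is the reverse complement so
    both mates carry the same k-mers)."""
    return [
        ReadPair(f"{prefix}{i}", DnaSequence(f"{prefix}{i}", r),
                 DnaSequence(f"{prefix}{i}", revcomp(r)))
        for i, r in enumerate(reads)
    ]


def simulate_perfect_pairs(rng: np.random.Generator, seq: str,
                           coverage: float = 20.0, read_len: int = 100,
                           insert: int = 250, prefix: str = "p"
                           ) -> list[ReadPair]:
    """Error-free convergent pairs drawn uniformly over ``seq``."""
    n = max(1, round(coverage * len(seq) / (2 * read_len)))
    pairs = []
    hi = max(len(seq) - insert, 1)
    for i in range(n):
        s = int(rng.integers(0, hi))
        ins = min(insert, len(seq) - s)
        m1 = seq[s : s + read_len]
        m2 = revcomp(seq[s + ins - read_len : s + ins])
        pid = f"{prefix}{i}"
        pairs.append(ReadPair(pid, DnaSequence(pid, m1), DnaSequence(pid, m2)))
    return pairs


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_lower_median(values: list[int]) -> int:
    """Sort and take the lower middle element."""
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def oracle_maximal_matches(query: str, read: str, min_len: int
                           ) -> set[tuple[int, int, int, int, str]]:
    """All maximal exact matches >= min_len between query and read (both
    strands) by exhaustive run enumeration.

    Returns {(q_start, q_end, r_start, r_end, strand)} with query intervals
    on the original query coordinates.
    """
    out: set[tuple[int, int, int, int, str]] = set()

    def runs(q: str, r: str):
        nq, nr = len(q), len(r)
        for i0 in range(nq):
            for j0 in range(nr):
                if q[i0] != r[j0]:
                    continue
                if i0 > 0 and j0 > 0 and q[i0 - 1] == r[j0 - 1]:
                    continue  # not a run start
                length = 0
                while (i0 + length < nq and j0 + length < nr
                       and q[i0 + length] == r[j0 + length]):
                    length += 1
                if length >= min_len:
                    yield i0, j0, length

    for i0, j0, length in runs(query, read):
        out.add((i0, i0 + length, j0, j0 + length, "+"))
    rcq = revcomp(query)
    nq = len(query)
    for i0, j0, length in runs(rcq, read):
        out.add((nq - (i0 + length), nq - i0, j0, j0 + length, "-"))
    return out


def oracle_n50(lengths: list[int]) -> int:
    """Brute force: descending sort, cumulate, first length reaching half."""
    if not lengths:
        return 0
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    acc = 0
    for length in ordered:
        acc += length
        if 2 * acc >= total:
            return length
    return ordered[-1]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
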