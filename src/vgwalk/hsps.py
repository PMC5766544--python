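"""Seed-and-extend local alignment (HSPs) between two sequences.

Shared pairwise comparison engine for exon classification, contig
orientation, similarity grouping, ordering and transcript-to-scaffold
mapping.  Alignments are ungapped diagonal extensions
with an X-drop rule; isolated substitutions are crossed, long indels split an
alignment into separate HSPs which downstream consumers chain by coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import revcomp

_MATCH = 1
_MISMATCH = -2


@dataclass(frozen=True, slots=True)
class Hsp:
    """A local alignment block.  Intervals are 0-based half-open.

    For strand ``'-'`` the subject interval is on the subject's own forward
    coordinates and the aligned subject segment equals the reverse complement
    of the query segment.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    matches: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length

    @property
    def score(self) -> int:
        return _MATCH * self.matches + _MISMATCH * (self.length - self.matches)


def _seed_positions(seq: str, seed_len: int) -> dict[str, list[int]]:
    table: dict[str, list[int]] = {}
    for i in range(len(seq) - seed_len + 1):
        kmer = seq[i : i + seed_len]
        if "N" in kmer:
            continue
        table.setdefault(kmer, []).append(i)
    return table


def _extend(query: str, subject: str, qp: int, sp: int, seed_len: int, xdrop: int
            ) -> tuple[int, int, int]:
    """Ungapped X-drop extension of an exact seed at (qp, sp).

    Returns (q_start, q_end, matches) on the seed's diagonal.
    """
    # right
    score = best = seed_len
    i, best_right = seed_len, seed_len
    while qp + i < len(query) and sp + i < len(subject):
        score += _MATCH if query[qp + i] == subject[sp + i] else _MISMATCH
        i += 1
        if score > best:
            best, best_right = score, i
        elif best - score > xdrop:
            break
    # left
    score = best = 0
    j, best_left = 0, 0
    while qp - j > 0 and sp - j > 0:
        score += _MATCH if query[qp - j - 1] == subject[sp - j - 1] else _MISMATCH
        j += 1
        if score > best:
            best, best_left = score, j
        elif best - score > xdrop:
            break
    q_start, q_end = qp - best_left, qp + best_right
    seg_q = query[q_start:q_end]
    seg_s = subject[sp - best_left : sp + best_right]
    matches = sum(a == b for a, b in zip(seg_q, seg_s))
    return q_start, q_end, matches


def _find_hsps_one_strand(query: str, subject: str, min_len: int,
                          min_identity: float, seed_len: int, xdrop: int
                          ) -> list[Hsp]:
    seeds = _seed_positions(subject, seed_len)
    hsps: dict[tuple[int, int], Hsp] = {}
    diag_done: dict[int, int] = {}  # diagonal -> q_end already covered
    for qp in range(len(query) - seed_len + 1):
        kmer = query[qp : qp + seed_len]
        positions = seeds.get(kmer)
        if not positions:
            continue
        for sp in positions:
            diag = qp - sp
            if qp < diag_done.get(diag, -1):
                continue
            q_start, q_end, matches = _extend(query, subject, qp, sp, seed_len, xdrop)
            diag_done[diag] = q_end
            length = q_end - q_start
            if length < min_len:
                continue
            if 100.0 * matches / length < min_identity:
                continue
            key = (diag, q_start)
            prev = hsps.get(key)
            if prev is None or matches > prev.matches:
                hsps[key] = Hsp(q_start, q_end, q_start - diag, q_end - diag,
                                "+", matches)
    return list(hsps.values())


def find_hsps(query: str, subject: str, min_len: int = 40,
              min_identity: float = 90.0, seed_len: int = 16,
              xdrop: int = 12, both_strands: bool = True) -> list[Hsp]:
    """All HSPs of length >= ``min_len`` and identity >= ``min_identity``.

    Sorted by descending matches then coordinates (deterministic).
    """
    seed_len = min(seed_len, min_len)
    out = _find_hsps_one_strand(query, subject, min_len, min_identity,
                                seed_len, xdrop)
    if both_strands:
        rc = revcomp(subject)
        L = len(subject)
        for h in _find_hsps_one_strand(query, rc, min_len, min_identity,
                                       seed_len, xdrop):
            out.append(Hsp(h.q_start, h.q_end, L - h.s_end, L - h.s_start,
                           "-", h.matches))
    out.sort(key=lambda h: (-h.matches, h.q_start, h.s_start, h.strand))
    return out


def best_hsp(query: str, subject: str, **kwargs) -> Hsp | None:
    hs = find_hsps(query, subject, **kwargs)
    return hs[0] if hs else None


def chain_hsps(hsps: list[Hsp], max_overlap: int = 20) -> list[Hsp]:
    """Best colinear chain of same-strand HSPs (query and subject coordinates
    both increasing for '+', query increasing / subject decreasing for '-').

    Returns the chain ordered by query coordinate, maximizing total matches.
    Small block overlaps up to ``max_overlap`` are tolerated.
    """
    best_chain: list[Hsp] = []
    best_total = -1
    for strand in ("+", "-"):
        cand = sorted((h for h in hsps if h.strand == strand),
                      key=lambda h: (h.q_start, h.s_start))
        n = len(cand)
        if not n:
            continue
        total = [h.matches for h in cand]
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                a, b = cand[j], cand[i]
                if b.q_start < a.q_end - max_overlap:
                    continue
                if strand == "+":
                    ok = b.s_start >= a.s_end - max_overlap
                else:
                    ok = b.s_end <= a.s_start + max_overlap
                if ok and total[j] + b.matches > total[i]:
                    total[i] = total[j] + b.matches
                    prev[i] = j
        end = max(range(n), key=lambda i: total[i])
        if total[end] > best_total:
            best_total = total[end]
            chain = []
            i = end
            while i != -1:
                chain.append(cand[i])
                i = prev[i]
            best_chain = chain[::-1]
    return best_chain
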