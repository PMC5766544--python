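"""Post-walk cleanup per transcript: chimera detection/splitting, contig
orientation, similarity-group consensus, exon-order layout and 500-N gap
scaffolding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assembly import Contig, OverlapParams
from .core import DnaSequence, ReadPair, revcomp
from .hsps import Hsp, find_hsps

DEFAULT_GAP_LEN = 500


@dataclass(frozen=True, slots=True)
class GapRecord:
    length: int = DEFAULT_GAP_LEN
    reason: str = "no_overlap"


@dataclass(slots=True)
class Scaffold:
    """Ordered, oriented contigs with explicit N-gap records.

    ``parts`` alternates Contig and GapRecord, beginning and ending with a
    Contig.  An empty ``parts`` list is allowed only for flagged-empty
    scaffolds (every contig stripped).
    """

    scaffold_id: str
    parts: list = field(default_factory=list)
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        if not self.parts:
            return
        if isinstance(self.parts[0], GapRecord) or isinstance(
                self.parts[-1], GapRecord):
            raise ValueError("scaffold parts must begin and end with a contig")
        for a, b in zip(self.parts, self.parts[1:]):
            if isinstance(a, GapRecord) == isinstance(b, GapRecord):
                raise ValueError("scaffold parts must alternate contig / gap")

    def sequence(self) -> str:
        out = []
        for part in self.parts:
            out.append("N" * part.length if isinstance(part, GapRecord)
                       else part.bases)
        return "".join(out)

    def contig_layout(self) -> list[tuple[Contig, int, int]]:
        """(contig, start, end) in rendered-sequence coordinates."""
        pos = 0
        layout = []
        for part in self.parts:
            if isinstance(part, GapRecord):
                pos += part.length
            else:
                layout.append((part, pos, pos + len(part.bases)))
                pos += len(part.bases)
        return layout

    def gap_layout(self) -> list[tuple[GapRecord, int, int]]:
        pos = 0
        layout = []
        for part in self.parts:
            if isinstance(part, GapRecord):
                layout.append((part, pos, pos + part.length))
                pos += part.length
            else:
                pos += len(part.bases)
        return layout

    def contigs(self) -> list[Contig]:
        return [p for p in self.parts if isinstance(p, Contig)]

    def total_contig_length(self) -> int:
        return sum(len(c.bases) for c in self.contigs())

    def __len__(self) -> int:
        return (self.total_contig_length()
                + sum(g.length for g in self.parts if isinstance(g, GapRecord)))

    @classmethod
    def from_sequence(cls, scaffold_id: str, seq: str,
                      min_gap: int = 100) -> "Scaffold":
        """Re-parse a rendered scaffold, splitting on N-runs >= ``min_gap``."""
        parts: list = []
        i, n = 0, len(seq)
        start = 0
        idx = 0
        while i < n:
            if seq[i] == "N":
                j = i
                while j < n and seq[j] == "N":
                    j += 1
                if j - i >= min_gap:
                    if i > start:
                        parts.append(Contig(f"{scaffold_id}.c{idx}",
                                            seq[start:i]))
                        idx += 1
                    parts.append(GapRecord(length=j - i))
                    start = j
                i = j
            else:
                i += 1
        if n > start:
            parts.append(Contig(f"{scaffold_id}.c{idx}", seq[start:n]))
        # collapse leading/trailing gaps (renderings never start with one)
        while parts and isinstance(parts[0], GapRecord):
            parts.pop(0)
        while parts and isinstance(parts[-1], GapRecord):
            parts.pop()
        return cls(scaffold_id, parts)


@dataclass(slots=True)
class PairCoverageProfile:
    """Per-position perfect properly-paired coverage over one contig."""

    contig_id: str
    coverage: np.ndarray
    spanned: np.ndarray


# ---------------------------------------------------------------------------
# chimera detection and splitting
# ---------------------------------------------------------------------------

def detect_chimeric_contigs(
    transcript: DnaSequence, contigs: Sequence[Contig],
    hsps: dict[str, list[Hsp]] | None = None, min_overlap: int = 20,
) -> list[Contig]:
    """Contigs carrying >= 2 HSPs that cover overlapping transcript intervals
    at distinct contig intervals (the same exon assembled twice)."""
    flagged = []
    for contig in contigs:
        hs = (hsps or {}).get(contig.contig_id)
        if hs is None:
            hs = find_hsps(transcript.bases, contig.bases, min_len=40,
                           min_identity=90.0)
        chimeric = False
        for i in range(len(hs)):
            for j in range(i + 1, len(hs)):
                a, b = hs[i], hs[j]
                q_ov = min(a.q_end, b.q_end) - max(a.q_start, b.q_start)
                s_ov = min(a.s_end, b.s_end) - max(a.s_start, b.s_start)
                if q_ov >= min_overlap and s_ov < min_overlap:
                    chimeric = True
                    break
            if chimeric:
                break
        if chimeric:
            flagged.append(contig)
    return flagged


def _exact_placements(read: str, contig: str) -> list[tuple[int, bool]]:
    """(start, is_reverse) of every exact full-length occurrence."""
    out = []
    for seq, is_rc in ((read, False), (revcomp(read), True)):
        p = contig.find(seq)
        while p != -1:
            out.append((p, is_rc))
            p = contig.find(seq, p + 1)
    return out


def perfect_pair_coverage(
    contig: Contig, recruited_pairs: Sequence[ReadPair],
    insert_range: tuple[int, int] = (100, 1000),
) -> PairCoverageProfile:
    """Coverage from pairs whose mates both align full-length with zero
    mismatches, in convergent orientation, with an implied insert inside
    ``insert_range``.  Each contributing pair adds +1 over the union of its
    mate intervals and marks its full span as spanned.
    """
    n = len(contig.bases)
    coverage = np.zeros(n, dtype=np.int32)
    spanned = np.zeros(n, dtype=bool)
    for pair in recruited_pairs:
        placed = None
        p1s = _exact_placements(pair.mate1.bases, contig.bases)
        if not p1s:
            continue
        p2s = _exact_placements(pair.mate2.bases, contig.bases)
        for s1, rc1 in p1s:
            e1 = s1 + len(pair.mate1.bases)
            for s2, rc2 in p2s:
                e2 = s2 + len(pair.mate2.bases)
                if rc1 == rc2:
                    continue  # convergent pairs face each other
                left_s, left_e, left_rc = (s1, e1, rc1) if s1 <= s2 else (s2, e2, rc2)
                right_s, right_e = (s2, e2) if s1 <= s2 else (s1, e1)
                if left_rc:  # leftmost mate must be on the forward strand
                    continue
                insert = right_e - left_s
                if not (insert_range[0] <= insert <= insert_range[1]):
                    continue
                placed = (left_s, left_e, right_s, right_e)
                break
            if placed:
                break
        if placed:
            ls, le, rs, re = placed
            coverage[ls:le] += 1
            coverage[rs:re] += 1
            spanned[ls:re] = True
    return PairCoverageProfile(contig.contig_id, coverage, spanned)


def split_contig(contig: Contig, profile: PairCoverageProfile,
                 min_fragment: int = 1) -> list[Contig]:
    """Excise internal maximal regions with zero coverage or no spanning
    pair; zero-coverage runs touching either end are never removed."""
    bad = (profile.coverage == 0) | (~profile.spanned)
    n = len(contig.bases)
    # runs touching the ends are kept
    i = 0
    while i < n and bad[i]:
        bad[i] = False
        i += 1
    i = n - 1
    while i >= 0 and bad[i]:
        bad[i] = False
        i -= 1
    if not bad.any():
        return [contig]
    pieces: list[Contig] = []
    start = 0
    idx = 0
    pos = 0
    while pos < n:
        if bad[pos]:
            end = pos
            while pos < n and bad[pos]:
                pos += 1
            if end - start >= min_fragment:
                pieces.append(Contig(
                    f"{contig.contig_id}.s{idx}", contig.bases[start:end],
                    transcript_id=contig.transcript_id,
                    iteration=contig.iteration, weight=contig.weight))
                idx += 1
            start = pos
        else:
            pos += 1
    if n - start >= min_fragment:
        pieces.append(Contig(f"{contig.contig_id}.s{idx}",
                             contig.bases[start:n],
                             transcript_id=contig.transcript_id,
                             iteration=contig.iteration, weight=contig.weight))
    return pieces


# ---------------------------------------------------------------------------
# orientation, grouping, ordering
# ---------------------------------------------------------------------------

def orient_contigs(transcript: DnaSequence,
                   contigs: Sequence[Contig]) -> list[Contig]:
    """Reverse complement contigs whose best transcript HSP is on '-'.

    Contigs with no HSP pass through untouched; contigs with mixed-strand
    HSPs are oriented by the best-scoring HSP and flagged.
    """
    out = []
    for contig in contigs:
        hs = find_hsps(transcript.bases, contig.bases, min_len=40,
                       min_identity=90.0)
        if not hs:
            contig.orientation_flagged = True
            out.append(contig)
            continue
        strands = {h.strand for h in hs}
        best = hs[0]
        bases = revcomp(contig.bases) if best.strand == "-" else contig.bases
        new = Contig(contig.contig_id, bases,
                     transcript_id=contig.transcript_id,
                     iteration=contig.iteration, weight=contig.weight)
        if len(strands) > 1:
            new.orientation_flagged = True
        out.append(new)
    return out


def _column_consensus(columns: list[list[tuple[str, int]]],
                      anchor_rank: dict[int, int]) -> str:
    out = []
    for col in columns:
        if not col:
            continue
        votes: Counter = Counter()
        for base, member in col:
            votes[base] += 1
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            top = ranked[0][1]
            tied = {b for b, c in ranked if c == top}
            # tie goes to the longest member's base
            choice = min((anchor_rank[m], b) for b, m in col if b in tied)[1]
            out.append(choice)
        else:
            out.append(ranked[0][0])
    return "".join(out)


def group_and_consensus(contigs: Sequence[Contig], min_sim_len: int = 200,
                        min_identity: float = 95.0) -> list[Contig]:
    """Collapse groups of contigs sharing a long high-identity alignment into
    a single consensus each (transitive closure); singletons pass through.

    Consensus is a progressive layout anchored on the longest member with
    majority base per column, ties resolved toward the longest member.
    """
    n = len(contigs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    for i in range(n):
        for j in range(i + 1, n):
            for h in find_hsps(contigs[i].bases, contigs[j].bases,
                               min_len=min_sim_len, min_identity=min_identity):
                union(i, j)
                break
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out: list[Contig] = []
    for members in groups.values():
        if len(members) == 1:
            out.append(contigs[members[0]])
            continue
        ordered = sorted(members, key=lambda i: (-len(contigs[i].bases),
                                                 contigs[i].contig_id))
        anchor = contigs[ordered[0]]
        anchor_rank = {m: r for r, m in enumerate(ordered)}
        placements: list[tuple[int, str, int]] = [(0, anchor.bases, ordered[0])]
        for m in ordered[1:]:
            member = contigs[m]
            hs = find_hsps(anchor.bases, member.bases, min_len=min_sim_len,
                           min_identity=min_identity)
            if not hs:
                out.append(member)  # linked only transitively; keep as-is
                continue
            h = hs[0]
            seq = member.bases
            if h.strand == "-":
                seq = revcomp(seq)
                s_start = len(seq) - h.s_end
            else:
                s_start = h.s_start
            placements.append((h.q_start - s_start, seq, m))
        start = min(p[0] for p in placements)
        end = max(p[0] + len(p[1]) for p in placements)
        columns: list[list[tuple[str, int]]] = [[] for _ in range(end - start)]
        for off, seq, m in placements:
            for i, base in enumerate(seq):
                columns[off - start + i].append((base, m))
        consensus = _column_consensus(columns, anchor_rank)
        out.append(Contig(anchor.contig_id, consensus,
                          transcript_id=anchor.transcript_id,
                          iteration=anchor.iteration,
                          weight=sum(contigs[m].weight for m in members)))
    out.sort(key=lambda c: (-len(c.bases), c.contig_id))
    return out


def _join_overlap(a: Contig, b: Contig, min_len: int, min_identity: float,
                  end_slack: int = 10) -> Contig | None:
    """Fuse a's right end with b's left end when they overlap."""
    wa = a.bases[-(min(len(a.bases), 3000)):]
    wb = b.bases[: min(len(b.bases), 3000)]
    off_a = len(a.bases) - len(wa)
    for h in find_hsps(wa, wb, min_len=min_len, min_identity=min_identity,
                       both_strands=False):
        if (off_a + h.q_end >= len(a.bases) - end_slack
                and h.s_start <= end_slack):
            overlap_a = a.bases[off_a + h.q_start:]
            overlap_b = b.bases[: h.s_end]
            # consensus of the overlap region: higher-weight contig wins
            chosen = overlap_a if (a.weight, len(a.bases)) >= (
                b.weight, len(b.bases)) else overlap_b
            bases = a.bases[: off_a + h.q_start] + chosen + b.bases[h.s_end:]
            return Contig(a.contig_id, bases, transcript_id=a.transcript_id,
                          iteration=max(a.iteration, b.iteration),
                          weight=a.weight + b.weight)
    return None


def order_and_join(transcript: DnaSequence, contigs: Sequence[Contig],
                   gap_len: int = DEFAULT_GAP_LEN,
                   overlap_min_len: int = 30,
                   overlap_min_identity: float = 90.0) -> Scaffold:
    """Order contigs by the transcript coordinate of their best HSP, fuse
    adjacent contigs with a detectable end overlap, and join the rest with
    fixed N-gaps, yielding one scaffold for the transcript.

    Contigs without any transcript HSP cannot be ordered and are dropped
    (they would be stripped as non-mapping downstream anyway).
    """
    keyed = []
    for contig in contigs:
        hs = find_hsps(transcript.bases, contig.bases, min_len=40,
                       min_identity=90.0)
        if not hs:
            continue
        keyed.append((hs[0].q_start, -len(contig.bases), contig.contig_id,
                      contig))
    keyed.sort(key=lambda t: t[:3])
    scaffold_id = f"scaffold_{transcript.id}"
    if not keyed:
        return Scaffold(scaffold_id, [], flagged_empty=True)
    parts: list = [keyed[0][3]]
    for _, _, _, contig in keyed[1:]:
        fused = _join_overlap(parts[-1], contig, overlap_min_len,
                              overlap_min_identity)
        if fused is not None:
            parts[-1] = fused
        else:
            parts.append(GapRecord(length=gap_len))
            parts.append(contig)
    return Scaffold(scaffold_id, parts)
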