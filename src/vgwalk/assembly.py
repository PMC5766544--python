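"""Local assembly: de Bruijn unitigs, overlap-layout merging, elongation.

One canonical de Bruijn unitigger produces contigs from a recruited read
subset; an overhang-permissive overlap-layout-consensus step merges and
extends contig sets; a read-anchored elongation step grows contig ends.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import DnaSequence, revcomp
from .hsps import Hsp, find_hsps

END_STATES = ("extending", "stopped", "boundary-unknown")


@dataclass(slots=True)
class Contig:
    """A gap-free assembled sequence with provenance and end bookkeeping."""

    contig_id: str
    bases: str
    transcript_id: str | None = None
    iteration: int = 0
    weight: int = 1
    end_states: tuple[str, str] = ("boundary-unknown", "boundary-unknown")
    orientation_flagged: bool = False

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"contig {self.contig_id!r} is empty")
        if "N" * 100 in self.bases:
            raise ValueError(
                f"contig {self.contig_id!r} contains a >=100 N run; such runs "
                "exist only as inter-contig gaps in scaffolds")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True, slots=True)
class OverlapParams:
    """End-overlap acceptance thresholds for contig merging.

    The permissive profile tolerates long overhanging sequence; the strict
    profile stands in for default-parameter merging during elongation.
    """

    min_overlap_len: int = 30
    min_overlap_identity: float = 75.0
    max_overhang_fraction: float = 80.0
    max_internal_gap: int = 200
    profile: str = "permissive"

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap_identity <= 100):
            raise ValueError("identity must be in (0, 100]")
        if self.min_overlap_len < 10:
            raise ValueError("min_overlap_len must be >= 10")

    @classmethod
    def permissive(cls) -> "OverlapParams":
        return cls()

    @classmethod
    def strict(cls) -> "OverlapParams":
        return cls(min_overlap_len=40, min_overlap_identity=90.0,
                   max_overhang_fraction=20.0, profile="strict")


# ---------------------------------------------------------------------------
# de Bruijn unitigs
# ---------------------------------------------------------------------------

def _canon(km: str) -> str:
    rc = revcomp(km)
    return km if km <= rc else rc


def _count_kmers(reads: Iterable[str], k: int) -> Counter:
    counts: Counter = Counter()
    for seq in reads:
        if len(seq) < k:
            continue
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            counts[_canon(km)] += 1
    return counts


class _Graph:
    __slots__ = ("k", "kmers")

    def __init__(self, k: int, kmer_set: set[str]):
        self.k = k
        self.kmers = kmer_set

    def has(self, km: str) -> bool:
        return _canon(km) in self.kmers

    def successors(self, km: str) -> list[str]:
        stem = km[1:]
        return [stem + c for c in "ACGT" if self.has(stem + c)]

    def predecessors(self, km: str) -> list[str]:
        stem = km[:-1]
        return [c + stem for c in "ACGT" if self.has(c + stem)]


def _walk_unitigs(graph: _Graph) -> list[str]:
    """Maximal non-branching paths, canonicalized and sorted."""
    visited: set[str] = set()
    unitigs: set[str] = set()

    def is_start(o: str) -> bool:
        preds = graph.predecessors(o)
        if len(preds) != 1:
            return True
        if len(graph.successors(preds[0])) != 1:
            return True
        # guard against a 2-cycle km <-> rc(km)
        return preds[0] == revcomp(o)

    def walk(o: str) -> str:
        seq = o
        visited.add(_canon(o))
        cur = o
        while True:
            outs = graph.successors(cur)
            if len(outs) != 1:
                break
            nxt = outs[0]
            if len(graph.predecessors(nxt)) != 1:
                break
            if _canon(nxt) in visited:
                break
            seq += nxt[-1]
            visited.add(_canon(nxt))
            cur = nxt
        return seq

    for km in sorted(graph.kmers):
        for o in (km, revcomp(km)):
            if _canon(o) in visited:
                continue
            if is_start(o):
                seq = walk(o)
                unitigs.add(min(seq, revcomp(seq)))
    # leftover cycles
    for km in sorted(graph.kmers):
        if km not in visited:
            seq = walk(km)
            unitigs.add(min(seq, revcomp(seq)))
    return sorted(unitigs)


def _clip_tips(graph: _Graph, unitigs: list[str]) -> bool:
    """Remove dead-end unitigs shorter than 2k that hang off a branch."""
    k = graph.k
    removed = False
    for seq in unitigs:
        if len(seq) >= 2 * k:
            continue
        first, last = seq[:k], seq[-k:]
        left_open = len(graph.predecessors(first)) == 0
        right_open = len(graph.successors(last)) == 0
        # a tip dangles at exactly one side and attaches to a branch point
        if left_open == right_open:
            continue
        anchor = graph.successors(last) if left_open else graph.predecessors(first)
        branched = any(
            len(graph.predecessors(a)) > 1 or len(graph.successors(a)) > 1
            for a in anchor
        )
        if not branched:
            continue
        for i in range(len(seq) - k + 1):
            graph.kmers.discard(_canon(seq[i : i + k]))
        removed = True
    return removed


def dbg_unitigs(reads: Sequence[DnaSequence | str], k: int = 63,
                min_kmer_count: int = 2, clip_tips: bool = True) -> list[Contig]:
    """Unitigs of the canonical de Bruijn graph of the reads.

    K-mers below ``min_kmer_count`` are dropped (absorbing sequencing
    errors; set to 1 for error-free input) and tips shorter than 2k are
    clipped.  Output order is deterministic: lexicographic by canonical
    sequence.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    seqs = [r.bases if isinstance(r, DnaSequence) else r for r in reads]
    counts = _count_kmers(seqs, k)
    kmer_set = {km for km, c in counts.items() if c >= min_kmer_count}
    if not kmer_set:
        return []
    graph = _Graph(k, kmer_set)
    unitigs = _walk_unitigs(graph)
    if clip_tips:
        for _ in range(4):
            if not _clip_tips(graph, unitigs):
                break
            unitigs = _walk_unitigs(graph)
    return [Contig(f"u{i}", seq) for i, seq in enumerate(unitigs)]


# ---------------------------------------------------------------------------
# overlap-layout-consensus merging
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class _MergePlan:
    score: float
    i: int
    j: int
    hsp: Hsp
    flip_j: bool


_END_WINDOW = 2000  # dovetail search window for long contig pairs


def _hsps_between(a_bases: str, b_bases: str, params: OverlapParams) -> list[Hsp]:
    """HSPs between two contigs in full coordinates.

    For a pair of long contigs only end-to-end dovetails are searched (the
    four end-window combinations); mid-contig containments between two long
    contigs are the similarity-grouping step's job, not the merge step's.
    """
    w = _END_WINDOW
    if len(a_bases) <= 2 * w or len(b_bases) <= 2 * w:
        return find_hsps(a_bases, b_bases, min_len=params.min_overlap_len,
                         min_identity=params.min_overlap_identity)
    out: list[Hsp] = []
    seen: set[tuple] = set()
    a_offs = (0, len(a_bases) - w)
    b_offs = (0, len(b_bases) - w)
    for ao in a_offs:
        aw = a_bases[ao : ao + w]
        for bo in b_offs:
            bw = b_bases[bo : bo + w]
            for h in find_hsps(aw, bw, min_len=params.min_overlap_len,
                               min_identity=params.min_overlap_identity):
                full = Hsp(h.q_start + ao, h.q_end + ao, h.s_start + bo,
                           h.s_end + bo, h.strand, h.matches)
                key = (full.q_start, full.s_start, full.strand)
                if key not in seen:
                    seen.add(key)
                    out.append(full)
    out.sort(key=lambda h: (-h.matches, h.q_start, h.s_start, h.strand))
    return out


def _best_overlap(a: Contig, b: Contig, params: OverlapParams) -> _MergePlan | None:
    best: _MergePlan | None = None
    hsps = _hsps_between(a.bases, b.bases, params)
    for h in hsps:
        flip = h.strand == "-"
        if flip:
            bs, be = len(b.bases) - h.s_end, len(b.bases) - h.s_start
        else:
            bs, be = h.s_start, h.s_end
        left_hang = min(h.q_start, bs)
        right_hang = min(len(a.bases) - h.q_end, len(b.bases) - be)
        if left_hang + right_hang > params.max_overhang_fraction / 100 * h.length:
            continue
        score = h.identity * h.length
        if best is None or score > best.score:
            best = _MergePlan(score, -1, -1, h, flip)
    return best


def _merge_pair(a: Contig, b: Contig, plan: _MergePlan) -> Contig:
    b_seq = revcomp(b.bases) if plan.flip_j else b.bases
    h = plan.hsp
    if plan.flip_j:
        bs = len(b_seq) - h.s_end
    else:
        bs = h.s_start
    offset = h.q_start - bs  # b's layout position in a coordinates
    start = min(0, offset)
    end = max(len(a.bases), offset + len(b_seq))
    out = []
    prefer_a = (a.weight, len(a.bases)) >= (b.weight, len(b.bases))
    for pos in range(start, end):
        ca = a.bases[pos] if 0 <= pos < len(a.bases) else None
        cb = b_seq[pos - offset] if 0 <= pos - offset < len(b_seq) else None
        if ca is None:
            out.append(cb)
        elif cb is None or ca == cb:
            out.append(ca)
        else:
            # disagreeing column: higher-weight contig wins, longer on ties
            out.append(ca if prefer_a else cb)
    keep, drop = (a, b) if prefer_a else (b, a)
    return Contig(keep.contig_id, "".join(out),
                  transcript_id=keep.transcript_id or drop.transcript_id,
                  iteration=max(a.iteration, b.iteration),
                  weight=a.weight + b.weight)


def overlap_layout_merge(contigs: Sequence[Contig],
                         params: OverlapParams | None = None) -> list[Contig]:
    """Greedy merging of contigs whose best end-to-end overlap passes the
    length/identity/overhang thresholds; repeats until no merge applies.

    Merge order is by descending overlap score (identity x length), ties by
    contig id, so the layout is deterministic.  Idempotent: running the
    output through again changes nothing.
    """
    params = params or OverlapParams.permissive()
    items = [(serial, Contig(c.contig_id, c.bases,
                             transcript_id=c.transcript_id,
                             iteration=c.iteration, weight=c.weight))
             for serial, c in enumerate(contigs)]
    next_serial = len(items)
    cache: dict[tuple[int, int], _MergePlan | None] = {}
    while len(items) > 1:
        best: _MergePlan | None = None
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                key = (items[i][0], items[j][0])
                if key not in cache:
                    cache[key] = _best_overlap(items[i][1], items[j][1], params)
                plan = cache[key]
                if plan is None:
                    continue
                plan = _MergePlan(plan.score, i, j, plan.hsp, plan.flip_j)
                if best is None or (plan.score, -plan.i, -plan.j) > (
                        best.score, -best.i, -best.j):
                    best = plan
        if best is None:
            break
        merged = _merge_pair(items[best.i][1], items[best.j][1], best)
        items = [entry for idx, entry in enumerate(items)
                 if idx not in (best.i, best.j)]
        items.append((next_serial, merged))
        next_serial += 1
    out = [c for _, c in items]
    out.sort(key=lambda c: (-len(c.bases), c.contig_id))
    return out


# ---------------------------------------------------------------------------
# read-anchored elongation
# ---------------------------------------------------------------------------

def _extend_right(bases: str, seqs: list[str], anchor: int,
                  max_rounds: int) -> str:
    for _ in range(max_rounds):
        tail = bases[-anchor:]
        if "N" in tail:
            break
        extensions: list[str] = []
        for s in seqs:
            p = s.find(tail)
            while p != -1:
                ext = s[p + anchor:]
                if ext:
                    extensions.append(ext)
                p = s.find(tail, p + 1)
        if not extensions:
            break
        voted: list[str] = []
        col = 0
        while True:
            votes = Counter(e[col] for e in extensions if len(e) > col)
            if not votes:
                break
            ranked = votes.most_common()
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                break  # tie: stop extension at this column
            voted.append(ranked[0][0])
            col += 1
        if not voted:
            break
        bases += "".join(voted)
    return bases


def elongate_with_reads(contig: Contig, reads: Sequence[DnaSequence | str],
                        params: OverlapParams | None = None,
                        max_rounds: int = 500) -> Contig:
    """Extend a contig at both ends by majority vote over reads that anchor
    the terminal ``min_overlap_len`` bases exactly.

    Pure extension: the input contig is contained in the result; interior
    bases are never rewritten.
    """
    params = params or OverlapParams.strict()
    anchor = params.min_overlap_len
    if len(contig.bases) < anchor:
        return contig
    seqs = [r.bases if isinstance(r, DnaSequence) else r for r in reads]
    seqs = seqs + [revcomp(s) for s in seqs]
    bases = _extend_right(contig.bases, seqs, anchor, max_rounds)
    bases = revcomp(_extend_right(revcomp(bases), seqs, anchor, max_rounds))
    if bases == contig.bases:
        return contig
    return Contig(contig.contig_id, bases, transcript_id=contig.transcript_id,
                  iteration=contig.iteration, weight=contig.weight)
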