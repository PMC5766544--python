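"""Scaffold post-processing: transcript-to-scaffold mapping, removal of
non-mapping contigs, and collapsing of scaffolds derived from splice
variants or fragments of one gene.

Splice-aware alignment is replaced by coordinate-monotone HSP chaining:
scaffolds were built around these very transcripts, so near-exact blocks
exist and basepair-precise intron boundaries are not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import kmers
from .assembly import Contig, OverlapParams, overlap_layout_merge
from .core import DnaSequence
from .finishing import GapRecord, Scaffold, group_and_consensus, _join_overlap
from .hsps import Hsp, chain_hsps, find_hsps


@dataclass(frozen=True, slots=True)
class MappingBlock:
    transcript_interval: tuple[int, int]
    scaffold_interval: tuple[int, int]
    identity: float


@dataclass(slots=True)
class ExonMapping:
    """Chained HSP blocks of one transcript on one scaffold.

    Blocks are non-overlapping and increasing on the transcript.
    """

    transcript_id: str
    scaffold_id: str
    blocks: list[MappingBlock] = field(default_factory=list)
    strand: str = "+"

    @property
    def mapped_length(self) -> int:
        return sum(b.transcript_interval[1] - b.transcript_interval[0]
                   for b in self.blocks)

    def coverage_of(self, transcript: DnaSequence) -> float:
        return self.mapped_length / len(transcript)


def map_transcript_to_scaffold(transcript: DnaSequence, scaffold: Scaffold,
                               min_len: int = 40,
                               min_identity: float = 90.0) -> ExonMapping:
    """HSPs chained by increasing transcript and scaffold coordinate."""
    seq = scaffold.sequence()
    mapping = ExonMapping(transcript.id, scaffold.scaffold_id)
    if not seq:
        return mapping
    hs = find_hsps(transcript.bases, seq, min_len=min_len,
                   min_identity=min_identity)
    chain = chain_hsps(hs)
    if not chain:
        return mapping
    mapping.strand = chain[0].strand
    for h in chain:
        mapping.blocks.append(MappingBlock(
            (h.q_start, h.q_end), (h.s_start, h.s_end), h.identity))
    return mapping


def strip_unmapped_contigs(scaffold: Scaffold,
                           mappings: Sequence[ExonMapping]) -> Scaffold:
    """Remove gap-delimited contigs intersecting no mapping block; adjacent
    gaps collapse to one.  A scaffold whose every contig is unmapped comes
    back empty and flagged."""
    blocks = [b.scaffold_interval for m in mappings for b in m.blocks]
    kept: list[Contig] = []
    for contig, start, end in scaffold.contig_layout():
        if any(bs < end and start < be for bs, be in blocks):
            kept.append(contig)
    if not kept:
        return Scaffold(scaffold.scaffold_id, [], flagged_empty=True)
    parts: list = [kept[0]]
    gaps = [g for g in scaffold.parts if isinstance(g, GapRecord)]
    gap_len = gaps[0].length if gaps else 500
    for contig in kept[1:]:
        parts.append(GapRecord(length=gap_len))
        parts.append(contig)
    return Scaffold(scaffold.scaffold_id, parts)


# ---------------------------------------------------------------------------
# redundancy detection and group merging
# ---------------------------------------------------------------------------

def _sampled_kmer_codes(seq: str, k: int = 31, stride: int = 7) -> set[int]:
    codes, valid = kmers.canonical_codes(seq, k)
    return {int(c) for c in codes[::stride][valid[::stride]]}


def _scaffold_hsps(a: str, b: str) -> list[Hsp]:
    return find_hsps(a, b, min_len=100, min_identity=94.0)


def _block_in_hsp(block: tuple[int, int], hsps: Sequence[Hsp],
                  min_identity: float, slack: int = 5) -> bool:
    bs, be = block
    for h in hsps:
        if h.identity >= min_identity and h.q_start <= bs + slack \
                and be - slack <= h.q_end:
            return True
    return False


def find_redundant_groups(
    scaffolds: Sequence[Scaffold],
    transcripts: dict[str, DnaSequence],
    scaffold_transcript: dict[str, str],
    min_all_identity: float = 95.0,
    min_one_identity: float = 99.0,
    min_shared_kmers: int = 5,
) -> list[list[str]]:
    """Disjoint groups of scaffolds describing the same locus.

    Processing scaffolds longest-first, a candidate joins a group iff every
    exon block of its own transcript lies inside a candidate-to-seed scaffold
    HSP of >= ``min_all_identity`` and at least one block lies inside an HSP
    of >= ``min_one_identity``.  Candidate pairs are pre-filtered by shared
    sampled 31-mers for tractability.
    """
    by_id = {s.scaffold_id: s for s in scaffolds}
    order = sorted(by_id, key=lambda sid: (-len(by_id[sid]), sid))
    seqs = {sid: by_id[sid].sequence() for sid in order}
    kmer_sets = {sid: _sampled_kmer_codes(seqs[sid]) for sid in order}
    own_blocks: dict[str, list[tuple[int, int]]] = {}
    for sid in order:
        tid = scaffold_transcript[sid]
        mapping = map_transcript_to_scaffold(transcripts[tid], by_id[sid])
        own_blocks[sid] = [b.scaffold_interval for b in mapping.blocks]
    assigned: set[str] = set()
    groups: list[list[str]] = []
    for sid in order:
        if sid in assigned:
            continue
        group = [sid]
        assigned.add(sid)
        for cand in order:
            if cand in assigned:
                continue
            shared = len(kmer_sets[sid] & kmer_sets[cand])
            if shared < min_shared_kmers:
                continue
            blocks = own_blocks[cand]
            if not blocks:
                continue
            hsps = _scaffold_hsps(seqs[cand], seqs[sid])
            if all(_block_in_hsp(b, hsps, min_all_identity) for b in blocks) \
                    and any(_block_in_hsp(b, hsps, min_one_identity)
                            for b in blocks):
                group.append(cand)
                assigned.add(cand)
        groups.append(group)
    return groups


def _ordered_contig_ids(transcript: DnaSequence,
                        contigs: Sequence[Contig]) -> list[str]:
    keyed = []
    for contig in contigs:
        hs = find_hsps(transcript.bases, contig.bases, min_len=40,
                       min_identity=90.0)
        if hs:
            keyed.append((hs[0].q_start, -len(contig.bases),
                          contig.contig_id))
    keyed.sort()
    return [cid for _, _, cid in keyed]


def merge_group(
    group: Sequence[Scaffold],
    transcripts: Sequence[DnaSequence],
    gap_len: int = 500,
    overlap_params: OverlapParams | None = None,
) -> Scaffold:
    """Collapse one redundancy group into a single scaffold.

    Pooled contigs are merged by overlap layout; leftovers sharing similarity
    are collapsed to consensus; the final contigs are ordered by the member
    transcripts' mappings, ordering conflicts resolved by the longest
    transcript's order.
    """
    if len(group) == 1:
        return group[0]
    pooled: list[Contig] = []
    for scaffold in group:
        pooled.extend(scaffold.contigs())
    merged = overlap_layout_merge(pooled, overlap_params
                                  or OverlapParams.permissive())
    merged = group_and_consensus(merged)
    ts = sorted(transcripts, key=lambda t: (-len(t.bases), t.id))
    order: list[str] = []
    by_id = {c.contig_id: c for c in merged}
    for t in ts:
        t_order = _ordered_contig_ids(t, merged)
        if not order:
            order = t_order
            continue
        # insert this transcript's unplaced contigs after the nearest
        # preceding already-placed contig
        prev_placed = -1
        for cid in t_order:
            if cid in order:
                prev_placed = order.index(cid)
            else:
                order.insert(prev_placed + 1, cid)
                prev_placed += 1
    ordered = [by_id[cid] for cid in order]
    scaffold_id = group[0].scaffold_id
    if not ordered:
        return Scaffold(scaffold_id, [], flagged_empty=True)
    parts: list = [ordered[0]]
    for contig in ordered[1:]:
        fused = _join_overlap(parts[-1], contig, 30, 90.0)
        if fused is not None:
            parts[-1] = fused
        else:
            parts.append(GapRecord(length=gap_len))
            parts.append(contig)
    return Scaffold(scaffold_id, parts)
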