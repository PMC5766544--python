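"""Post-hoc reports: intron bridging, flank walk lengths, contig-end stop
classification, and assembly summary statistics.

Length accounting excludes artificial N-gap spacers throughout.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .assembly import Contig
from .finishing import Scaffold
from .recruitment import ReadIndex
from .scaffold_merge import ExonMapping
from .walker import WalkState


@dataclass(frozen=True, slots=True)
class IntronRecord:
    gene_id: str
    intron_index: int
    length: int
    bridged: bool
    reliable: bool


@dataclass(frozen=True, slots=True)
class EndStatusRecord:
    contig_id: str
    end: str  # 'left' | 'right'
    status: str  # 'extending' | 'repeat' | 'low_coverage'
    median_coverage: int


def intron_report(scaffold: Scaffold, mapping: ExonMapping) -> list[IntronRecord]:
    """One record per gap between consecutive exon blocks.

    Bridged iff no N-gap record lies between the flanking blocks; unreliable
    (length untrustworthy) iff two or more gap records — i.e. at least one
    whole extra contig — lie inside the intron.  Gap Ns never count toward
    the length; unplaced real bases between blocks do.
    """
    blocks = sorted(mapping.blocks, key=lambda b: b.transcript_interval)
    if len(blocks) < 2:
        return []
    gaps = scaffold.gap_layout()
    records = []
    for idx in range(len(blocks) - 1):
        left_end = blocks[idx].scaffold_interval[1]
        right_start = blocks[idx + 1].scaffold_interval[0]
        lo, hi = min(left_end, right_start), max(left_end, right_start)
        inner_gaps = [g for g, gs, ge in gaps if lo <= gs and ge <= hi]
        gap_bases = sum(g.length for g in inner_gaps)
        length = max(hi - lo - gap_bases, 0)
        records.append(IntronRecord(
            gene_id=mapping.transcript_id,
            intron_index=idx,
            length=length,
            bridged=not inner_gaps,
            reliable=len(inner_gaps) < 2,
        ))
    return records


def flank_report(scaffold: Scaffold, mapping: ExonMapping) -> tuple[int, int]:
    """(upstream, downstream) walked bases outside the outermost exon
    blocks, excluding N-gaps from the count."""
    if not mapping.blocks:
        raise ValueError("mapping has no blocks")
    starts = [b.scaffold_interval[0] for b in mapping.blocks]
    ends = [b.scaffold_interval[1] for b in mapping.blocks]
    first, last = min(starts), max(ends)
    total = len(scaffold)
    gaps = scaffold.gap_layout()
    up_gap = sum(g.length for g, gs, ge in gaps if ge <= first)
    down_gap = sum(g.length for g, gs, ge in gaps if gs >= last)
    return first - up_gap, (total - last) - down_gap


def mem_coverage(contig_bases: str, index: ReadIndex, min_mem: int = 30,
                 window: tuple[int, int] | None = None) -> np.ndarray:
    """Per-position depth over a contig (or a window of it) from maximal
    exact matches of the indexed reads."""
    if window is None:
        start, end = 0, len(contig_bases)
    else:
        start, end = window
    query = contig_bases[start:end]
    cov = np.zeros(end - start, dtype=np.int64)
    min_mem = max(min_mem, index.min_query_match)
    for hit in index.find_exact_matches(query, min_mem):
        qs, qe = hit.query_interval
        cov[qs:qe] += 1
    return cov


def end_status_report(
    walk_states: Sequence[WalkState],
    coverage_source: Callable[[Contig, str], np.ndarray],
    end_span: int = 60,
    fallback_threshold: int = 50,
) -> list[EndStatusRecord]:
    """Classify every final contig end as extending / repeat / low_coverage.

    ``coverage_source(contig, end)`` returns per-position depth over the
    terminal ``end_span`` bases of the given end.  Ends still extending at
    the final iteration stay 'extending'; for stopped ends the median depth
    is compared with the mode (1x-binned) of the extending ends' medians —
    above the mode means 'repeat', otherwise 'low_coverage'.
    """
    entries: list[tuple[str, str, str, int]] = []
    for state in walk_states:
        for contig in state.contigs:
            for side, end_state in zip(("left", "right"), contig.end_states):
                cov = coverage_source(contig, side)
                med = int(np.median(cov[-end_span:] if side == "right"
                                    else cov[:end_span]))
                entries.append((contig.contig_id, side, end_state, med))
    extending_meds = [m for _, _, st, m in entries if st == "extending"]
    if extending_meds:
        mode = Counter(extending_meds).most_common(1)[0][0]
    else:
        warnings.warn("no extending ends; falling back to the configured "
                      "coverage threshold", stacklevel=2)
        mode = fallback_threshold
    records = []
    for cid, side, end_state, med in entries:
        if end_state == "extending":
            status = "extending"
        elif med > mode:
            status = "repeat"
        else:
            status = "low_coverage"
        records.append(EndStatusRecord(cid, side, status, med))
    return records


def n50(lengths: Sequence[int]) -> int:
    """Standard N50: the length at which the cumulative sum of descending
    lengths first reaches half the total."""
    if not lengths:
        return 0
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    return ordered[-1]


def scaffold_n50(scaffolds: Sequence[Scaffold]) -> int:
    """N50 over scaffold lengths excluding the artificial N-gap spacers."""
    return n50([s.total_contig_length() for s in scaffolds])


def contig_n50(scaffolds: Sequence[Scaffold]) -> int:
    return n50([len(c.bases) for s in scaffolds for c in s.contigs()])
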