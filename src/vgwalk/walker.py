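"""The iteration engine: seed from a transcript, recruit-assemble-classify
each round, extend from contig ends, and apply the continue/stop/drop rules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

from .assembly import Contig, OverlapParams, dbg_unitigs, elongate_with_reads, \
    overlap_layout_merge
from .core import DnaSequence, ReadPair, revcomp
from .hsps import Hsp, find_hsps
from .recruitment import ReadIndex

_END_SIG = 32  # bases of terminal sequence used as an end identity signature


@dataclass(frozen=True, slots=True)
class WalkerConfig:
    min_match_initial: int = 40
    min_match_extend: int = 60
    end_window: int = 600
    assembly_k: int = 63
    max_iterations: int = 30
    max_contigs: int = 500
    contig_growth_drop_factor: float = 3.0
    min_pair_links: int = 3
    culling_limit: int = 2
    min_kmer_count: int = 2
    hsp_min_len: int = 40
    hsp_min_identity: float = 90.0
    link_min_identity: float = 95.0
    link_min_cover: float = 0.9

    def __post_init__(self) -> None:
        for name in ("min_match_initial", "min_match_extend", "end_window",
                     "assembly_k", "max_contigs", "min_pair_links",
                     "culling_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True, slots=True)
class IterationStats:
    max_contig_len: int
    sum_contig_len: int
    n_contigs: int


def _stats_of(contigs: Sequence[Contig]) -> IterationStats:
    lens = [len(c) for c in contigs]
    return IterationStats(max(lens, default=0), sum(lens), len(lens))


@dataclass(slots=True)
class WalkState:
    """Per-transcript iteration state.

    ``stats`` holds one entry per executed round including the seeding round;
    ``recruited`` grows monotonically across iterations.
    """

    transcript_id: str
    transcript: DnaSequence | None = None
    iteration: int = 0
    contigs: list[Contig] = field(default_factory=list)
    recruited: set[str] = field(default_factory=set)
    stats: list[IterationStats] = field(default_factory=list)
    status: str = "extending"
    stop_reason: str | None = None
    log: list[dict] = field(default_factory=list)
    end_stalls: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# classification and paired-end linking
# ---------------------------------------------------------------------------

def classify_exon_contigs(
    transcript: DnaSequence, contigs: Sequence[Contig], cfg: WalkerConfig
) -> tuple[list[Contig], list[Contig], dict[str, list[Hsp]]]:
    """Split contigs into exon-containing and other via transcript HSPs.

    Culling: an HSP is discarded when its transcript interval is enveloped by
    ``culling_limit`` or more higher-scoring HSPs from other contigs; a
    contig is exon-containing iff it retains at least one HSP.
    """
    scored: list[tuple[Hsp, str]] = []
    for contig in contigs:
        for h in find_hsps(transcript.bases, contig.bases,
                           min_len=cfg.hsp_min_len,
                           min_identity=cfg.hsp_min_identity):
            scored.append((h, contig.contig_id))
    scored.sort(key=lambda t: (-t[0].matches, t[1], t[0].q_start))
    kept: dict[str, list[Hsp]] = {}
    for idx, (h, cid) in enumerate(scored):
        enveloping = 0
        for h2, cid2 in scored[:idx]:
            if cid2 != cid and h2.q_start <= h.q_start and h.q_end <= h2.q_end:
                enveloping += 1
                if enveloping >= cfg.culling_limit:
                    break
        if enveloping < cfg.culling_limit:
            kept.setdefault(cid, []).append(h)
    exon = [c for c in contigs if c.contig_id in kept]
    other = [c for c in contigs if c.contig_id not in kept]
    return exon, other, kept


def _read_aligns(read: str, contig_bases: str, contig_20mers: set[str],
                 cfg: WalkerConfig) -> bool:
    """Mate-to-contig alignment test: identity >= link_min_identity over
    >= link_min_cover of the mate length."""
    rc = revcomp(read)
    if read in contig_bases or rc in contig_bases:
        return True
    if contig_20mers and not any(
            read[i : i + 20] in contig_20mers or rc[i : i + 20] in contig_20mers
            for i in range(0, len(read) - 19, 10)):
        return False
    for h in find_hsps(read, contig_bases, min_len=30, min_identity=90.0):
        if (h.length >= cfg.link_min_cover * len(read)
                and h.identity >= cfg.link_min_identity):
            return True
    return False


def _contig_20mers(bases: str) -> set[str]:
    return {bases[i : i + 20] for i in range(len(bases) - 19)}


def paired_link_contigs(
    exon_contigs: Sequence[Contig], other_contigs: Sequence[Contig],
    recruited_reads: Sequence[ReadPair], cfg: WalkerConfig,
) -> list[Contig]:
    """Non-exon contigs retained because >= ``min_pair_links`` pairs bridge
    them to an exon-containing contig (one mate on each)."""
    if not other_contigs or not exon_contigs:
        return []
    exon_sets = [(c.bases, _contig_20mers(c.bases)) for c in exon_contigs]
    retained: list[Contig] = []
    for contig in other_contigs:
        cset = _contig_20mers(contig.bases)
        links = 0
        for pair in recruited_reads:
            for here, there in ((pair.mate1, pair.mate2),
                                (pair.mate2, pair.mate1)):
                if not _read_aligns(here.bases, contig.bases, cset, cfg):
                    continue
                if any(_read_aligns(there.bases, eb, es, cfg)
                       for eb, es in exon_sets):
                    links += 1
                break  # count each pair at most once per contig
            if links >= cfg.min_pair_links:
                retained.append(contig)
                break
    return retained


# ---------------------------------------------------------------------------
# iteration rounds
# ---------------------------------------------------------------------------

def _assemble(reads: Sequence[DnaSequence], cfg: WalkerConfig) -> list[Contig]:
    return dbg_unitigs(reads, k=cfg.assembly_k,
                       min_kmer_count=cfg.min_kmer_count)


def _mates_of(index: ReadIndex, pair_ids: Sequence[str]) -> list[DnaSequence]:
    reads: list[DnaSequence] = []
    for pid in sorted(pair_ids):
        pair = index.get_pair(pid)
        reads.append(pair.mate1)
        reads.append(pair.mate2)
    return reads


def _finalize_round(state: WalkState, transcript: DnaSequence,
                    candidates: list[Contig], pairs: list[ReadPair],
                    cfg: WalkerConfig, iteration: int) -> None:
    merged = overlap_layout_merge(candidates, OverlapParams.permissive())
    exon, other, hsps = classify_exon_contigs(transcript, merged, cfg)
    linked = paired_link_contigs(exon, other, pairs, cfg)
    contigs = exon + linked

    def sort_key(c: Contig):
        hs = hsps.get(c.contig_id)
        qpos = min(h.q_start for h in hs) if hs else 10 ** 9
        return (qpos, -len(c), c.contig_id)

    contigs.sort(key=sort_key)
    renamed: list[Contig] = []
    prev_sigs = {sig for sig in state.end_stalls}
    new_stalls: dict[str, int] = {}
    for n, c in enumerate(contigs):
        contig = Contig(f"{state.transcript_id}.i{iteration}.c{n}", c.bases,
                        transcript_id=state.transcript_id, iteration=iteration,
                        weight=c.weight)
        states = []
        for sig in (contig.bases[:_END_SIG], revcomp(contig.bases[-_END_SIG:])):
            stall = state.end_stalls.get(sig, -1) + 1 if sig in prev_sigs else 0
            new_stalls[sig] = stall
            if stall == 0:
                states.append("extending")
            elif stall >= 2:
                states.append("stopped")
            else:
                states.append("boundary-unknown")
        contig.end_states = (states[0], states[1])
        renamed.append(contig)
    state.contigs = renamed
    state.end_stalls = new_stalls
    state.stats.append(_stats_of(renamed))


def seed_iteration(transcript: DnaSequence, index: ReadIndex,
                   cfg: WalkerConfig | None = None) -> WalkState:
    """First round: recruit pairs matching the transcript, assemble, classify
    and retain exon contigs plus paired-linked neighbours."""
    cfg = cfg or WalkerConfig()
    state = WalkState(transcript_id=transcript.id, transcript=transcript)
    if len(transcript) < cfg.min_match_initial:
        state.status = "failed_to_seed"
        state.stop_reason = (f"transcript shorter than min_match_initial "
                             f"({len(transcript)} < {cfg.min_match_initial})")
        return state
    recruited = index.recruit_pairs([transcript], cfg.min_match_initial)
    if not recruited:
        state.status = "failed_to_seed"
        state.stop_reason = "no read pair recruited at the initial threshold"
        return state
    state.recruited = set(recruited)
    reads = _mates_of(index, sorted(recruited))
    pairs = [index.get_pair(pid) for pid in sorted(recruited)]
    unitigs = _assemble(reads, cfg)
    candidates = [elongate_with_reads(u, reads) for u in unitigs]
    _finalize_round(state, transcript, candidates, pairs, cfg, iteration=0)
    if not state.contigs:
        state.status = "failed_to_seed"
        state.stop_reason = "no exon-containing contig assembled"
        return state
    state.log.append({"iteration": 0, "recruited": len(recruited),
                      **dataclasses.asdict(_stats_of(state.contigs))})
    return state


def end_queries(contigs: Sequence[Contig], end_window: int) -> list[tuple[str, str, str]]:
    """(contig_id, end, query bases) for each contig end; whole contig when
    shorter than the window."""
    queries = []
    for c in contigs:
        if len(c) <= end_window:
            queries.append((c.contig_id, "both", c.bases))
        else:
            queries.append((c.contig_id, "left", c.bases[:end_window]))
            queries.append((c.contig_id, "right", c.bases[-end_window:]))
    return queries


def extend_iteration(state: WalkState, index: ReadIndex,
                     cfg: WalkerConfig | None = None) -> WalkState:
    """One extension round: recruit from contig end windows at the longer
    threshold, assemble the newly recruited pairs, elongate, merge with the
    previous contigs, re-classify and re-link."""
    cfg = cfg or WalkerConfig()
    if state.status != "extending":
        raise ValueError(f"cannot extend a walk with status {state.status!r}")
    transcript = state.transcript
    assert transcript is not None
    iteration = state.iteration + 1
    queries = end_queries(state.contigs, cfg.end_window)
    recruited = index.recruit_pairs([q for _, _, q in queries],
                                   cfg.min_match_extend)
    new_ids = sorted(recruited - state.recruited)
    state.recruited |= recruited
    new_reads = _mates_of(index, new_ids)
    pairs = [index.get_pair(pid) for pid in sorted(state.recruited)]
    unitigs = _assemble(new_reads, cfg) if new_reads else []
    elong_reads = new_reads
    candidates = [elongate_with_reads(c, elong_reads) if elong_reads else c
                  for c in state.contigs]
    candidates = candidates + [
        elongate_with_reads(u, elong_reads) for u in unitigs]
    _finalize_round(state, transcript, candidates, pairs, cfg, iteration)
    state.iteration = iteration
    state.log.append({
        "iteration": iteration,
        "queries": [(cid, end, len(q)) for cid, end, q in queries],
        "new_pairs": len(new_ids),
        **dataclasses.asdict(_stats_of(state.contigs)),
    })
    return state


def assess_progress(prev_stats: IterationStats, curr_stats: IterationStats,
                    cfg: WalkerConfig | None = None) -> str:
    """'dropped' on contig explosion, 'continue' on growth, else 'finished'."""
    cfg = cfg or WalkerConfig()
    if curr_stats.n_contigs >= cfg.max_contigs:
        return "dropped"
    if curr_stats.n_contigs > cfg.contig_growth_drop_factor * prev_stats.n_contigs:
        return "dropped"
    if (curr_stats.max_contig_len > prev_stats.max_contig_len
            or curr_stats.sum_contig_len > prev_stats.sum_contig_len):
        return "continue"
    return "finished"


def run_walk(transcript: DnaSequence, index: ReadIndex,
             cfg: WalkerConfig | None = None) -> WalkState:
    """Seed then extend until finished, dropped or ``max_iterations``."""
    cfg = cfg or WalkerConfig()
    state = seed_iteration(transcript, index, cfg)
    if state.status == "failed_to_seed":
        return state
    for _ in range(cfg.max_iterations):
        extend_iteration(state, index, cfg)
        if not state.contigs:
            state.status = "finished"
            state.stop_reason = "no contigs retained"
            break
        verdict = assess_progress(state.stats[-2], state.stats[-1], cfg)
        if verdict == "dropped":
            state.status = "dropped"
            state.stop_reason = (
                f"contig count {state.stats[-1].n_contigs} hit the drop rule "
                f"at iteration {state.iteration}")
            break
        if verdict == "finished":
            state.status = "finished"
            break
    return state


def run_all(transcripts: Sequence[DnaSequence], index: ReadIndex,
            cfg: WalkerConfig | None = None) -> dict[str, WalkState]:
    """Walk every transcript with per-transcript isolation: one transcript's
    failure never aborts the batch."""
    cfg = cfg or WalkerConfig()
    out: dict[str, WalkState] = {}
    for transcript in sorted(transcripts, key=lambda t: t.id):
        try:
            out[transcript.id] = run_walk(transcript, index, cfg)
        except Exception as exc:  # noqa: BLE001 - per-transcript isolation
            state = WalkState(transcript_id=transcript.id, transcript=transcript)
            state.status = "failed_to_seed"
            state.stop_reason = f"error: {exc}"
            out[transcript.id] = state
    return out
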