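"""End-to-end orchestration: deplete -> index -> walk -> finish -> merge ->
metrics, with per-stage artifacts under one run directory.

Reruns with an identical config and seed reproduce identical FASTA outputs;
all randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import metrics as metrics_mod
from .assembly import OverlapParams
from .core import DnaSequence, ReadPair, read_fasta, read_fastq_pairs, \
    write_fasta
from .depletion import DepletionConfig, build_kmer_table, filter_read_pairs
from .finishing import DEFAULT_GAP_LEN, Scaffold, detect_chimeric_contigs, \
    group_and_consensus, order_and_join, orient_contigs, \
    perfect_pair_coverage, split_contig
from .recruitment import ReadIndex
from .scaffold_merge import find_redundant_groups, map_transcript_to_scaffold, \
    merge_group, strip_unmapped_contigs
from .walker import WalkState, WalkerConfig, classify_exon_contigs, run_all


@dataclass(frozen=True, slots=True)
class FinishingConfig:
    gap_len: int = DEFAULT_GAP_LEN
    join_overlap_min_len: int = 30
    join_overlap_min_identity: float = 90.0
    group_min_sim_len: int = 200
    group_min_identity: float = 95.0
    insert_range: tuple[int, int] = (100, 1000)


@dataclass(frozen=True, slots=True)
class MergeConfig:
    min_all_identity: float = 95.0
    min_one_identity: float = 99.0


@dataclass(slots=True)
class PipelineConfig:
    transcripts: str = ""
    reads1: str = ""
    reads2: str = ""
    seed: int = 0
    depletion: DepletionConfig = field(default_factory=DepletionConfig)
    walker: WalkerConfig = field(default_factory=WalkerConfig)
    finishing: FinishingConfig = field(default_factory=FinishingConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    index_seed_len: int = 20

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for key, sub in (("depletion", DepletionConfig),
                         ("walker", WalkerConfig),
                         ("finishing", FinishingConfig),
                         ("merge", MergeConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = kwargs[key]
                for name, value in sub_kwargs.items():
                    if isinstance(value, list):
                        sub_kwargs[name] = tuple(value)
                kwargs[key] = sub(**sub_kwargs)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


@dataclass(slots=True)
class PipelineResult:
    states: dict[str, WalkState]
    scaffolds: list[Scaffold]
    merged_scaffolds: list[Scaffold]
    groups: list[list[str]]
    scaffold_transcript: dict[str, str]
    retained_pairs: list[ReadPair]
    index: ReadIndex
    summary: dict


def finish_walk(state: WalkState, pairs: Sequence[ReadPair],
                cfg: PipelineConfig) -> Scaffold:
    """Per-transcript post-walk cleanup producing one scaffold.

    ``pairs`` are the transcript's recruited read pairs, used for chimera
    splitting coverage.
    """
    transcript = state.transcript
    assert transcript is not None
    contigs = list(state.contigs)
    _, _, hsps = classify_exon_contigs(transcript, contigs, cfg.walker)
    flagged = detect_chimeric_contigs(transcript, contigs, hsps)
    flagged_ids = {c.contig_id for c in flagged}
    cleaned = []
    for contig in contigs:
        if contig.contig_id in flagged_ids:
            profile = perfect_pair_coverage(
                contig, pairs, insert_range=cfg.finishing.insert_range)
            cleaned.extend(split_contig(contig, profile))
        else:
            cleaned.append(contig)
    oriented = orient_contigs(transcript, cleaned)
    grouped = group_and_consensus(
        oriented, min_sim_len=cfg.finishing.group_min_sim_len,
        min_identity=cfg.finishing.group_min_identity)
    grouped = orient_contigs(transcript, grouped)
    scaffold = order_and_join(
        transcript, grouped, gap_len=cfg.finishing.gap_len,
        overlap_min_len=cfg.finishing.join_overlap_min_len,
        overlap_min_identity=cfg.finishing.join_overlap_min_identity)
    return scaffold


def run_pipeline(
    transcripts: Sequence[DnaSequence],
    pairs: Sequence[ReadPair],
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage in memory; optionally write artifacts to ``out_dir``."""
    cfg = cfg or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    # 1. repeat depletion
    table = build_kmer_table(pairs, cfg.depletion.k)
    retained, report = filter_read_pairs(pairs, table, cfg.depletion)
    if out is not None:
        (out / "depletion.tsv").write_text(report.to_tsv())

    # 2. read index
    min_query = min(cfg.walker.min_match_initial, cfg.walker.min_match_extend)
    index = ReadIndex(retained, seed_len=cfg.index_seed_len,
                      min_query_match=min_query)

    # 3. walks
    states = run_all(list(transcripts), index, cfg.walker)
    if out is not None:
        with open(out / "walk_log.jsonl", "w") as fh:
            for tid in sorted(states):
                st = states[tid]
                fh.write(json.dumps({
                    "transcript": tid, "status": st.status,
                    "stop_reason": st.stop_reason,
                    "iterations": st.iteration,
                    "log": st.log}) + "\n")

    # 4. finishing
    scaffolds: list[Scaffold] = []
    scaffold_transcript: dict[str, str] = {}
    t_by_id = {t.id: t for t in transcripts}
    for tid in sorted(states):
        state = states[tid]
        if state.status == "failed_to_seed" or not state.contigs:
            continue
        recruited = [index.get_pair(pid) for pid in sorted(state.recruited)]
        scaffold = finish_walk(state, recruited, cfg)
        if scaffold.flagged_empty:
            continue
        mapping = map_transcript_to_scaffold(t_by_id[tid], scaffold)
        scaffold = strip_unmapped_contigs(scaffold, [mapping])
        if scaffold.flagged_empty:
            continue
        scaffolds.append(scaffold)
        scaffold_transcript[scaffold.scaffold_id] = tid

    # 5. redundancy merge
    groups = find_redundant_groups(
        scaffolds, t_by_id, scaffold_transcript,
        min_all_identity=cfg.merge.min_all_identity,
        min_one_identity=cfg.merge.min_one_identity)
    by_id = {s.scaffold_id: s for s in scaffolds}
    merged: list[Scaffold] = []
    for group in groups:
        members = [by_id[sid] for sid in group]
        ts = [t_by_id[scaffold_transcript[sid]] for sid in group]
        merged.append(merge_group(members, ts, gap_len=cfg.finishing.gap_len))

    # 6. summary
    statuses = [states[tid].status for tid in sorted(states)]
    summary = {
        "transcripts_in": len(transcripts),
        "pairs_in": report.n_input,
        "pairs_retained": report.n_retained,
        "seeded": sum(1 for s in statuses if s != "failed_to_seed"),
        "failed_to_seed": statuses.count("failed_to_seed"),
        "finished": statuses.count("finished"),
        "dropped": statuses.count("dropped"),
        "still_extending": statuses.count("extending"),
        "scaffolds_out": len(merged),
        "contig_n50": metrics_mod.contig_n50(merged),
        "scaffold_n50": metrics_mod.scaffold_n50(merged),
    }
    if out is not None:
        _write_outputs(out, transcripts, merged, scaffold_transcript, summary)
    return PipelineResult(states=states, scaffolds=scaffolds,
                          merged_scaffolds=merged, groups=groups,
                          scaffold_transcript=scaffold_transcript,
                          retained_pairs=retained, index=index,
                          summary=summary)


def _write_outputs(out: Path, transcripts, merged, scaffold_transcript,
                   summary) -> None:
    write_fasta(out / "scaffolds.fasta",
                [DnaSequence(s.scaffold_id, s.sequence()) for s in merged])
    t_by_id = {t.id: t for t in transcripts}
    with open(out / "exons.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for scaffold in merged:
            tid = scaffold_transcript.get(scaffold.scaffold_id)
            if tid is None:
                continue
            mapping = map_transcript_to_scaffold(t_by_id[tid], scaffold)
            for i, block in enumerate(mapping.blocks):
                s, e = block.scaffold_interval
                fh.write("\t".join([
                    scaffold.scaffold_id, "vgwalk", "exon_match",
                    str(s + 1), str(e), f"{block.identity:.1f}",
                    mapping.strand, ".",
                    f"transcript={tid};block={i}"]) + "\n")
    keys = sorted(summary)
    (out / "summary.tsv").write_text(
        "\t".join(keys) + "\n" + "\t".join(str(summary[k]) for k in keys) + "\n")


def run_pipeline_from_files(cfg: PipelineConfig,
                            out_dir: str | Path) -> PipelineResult:
    for path in (cfg.transcripts, cfg.reads1):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file missing: {path}")
    transcripts = read_fasta(cfg.transcripts)
    if cfg.reads2:
        if not Path(cfg.reads2).exists():
            raise FileNotFoundError(f"input file missing: {cfg.reads2}")
        pairs = read_fastq_pairs(cfg.reads1, cfg.reads2)
    else:
        pairs = read_fastq_pairs(cfg.reads1)
    return run_pipeline(transcripts, pairs, cfg, out_dir)
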