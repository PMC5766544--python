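"""Synthetic genomes, gene models, repeat families and paired reads with
ground-truth annotations.

Emulates the statistical structure of a low-coverage short-read genome
project at desk scale: ~20x uniform coverage, 100 bp pairs with a small
insert, multi-exon genes with multi-kb introns, interspersed high-copy
repeat families, and substitution sequencing errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import DnaSequence, ReadPair, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True, slots=True)
class RepeatFamily:
    unit_len: int
    copy_number: int
    divergence: float  # percent substitutions per copy

    def __post_init__(self) -> None:
        if not (0 <= self.divergence <= 50):
            raise ValueError("divergence must be within [0, 50]")


@dataclass(frozen=True, slots=True)
class SimConfig:
    seed: int = 0
    genome_len: int = 100_000
    n_genes: int = 2
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (200, 1500)
    repeat_families: tuple[RepeatFamily, ...] = ()
    read_len: int = 100
    insert_mean: float = 250.0
    insert_sd: float = 25.0
    coverage: float = 20.0
    error_rate: float = 0.0
    # plant one repeat copy in the middle of intron (gene_idx, intron_idx)
    plant_repeat_in_intron: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for name in ("genome_len", "read_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True, slots=True)
class ExonRecord:
    gene_id: str
    exon_index: int
    start: int
    end: int
    strand: str


@dataclass(frozen=True, slots=True)
class RepeatPlacement:
    family: int
    start: int
    end: int


@dataclass(frozen=True, slots=True)
class ReadProvenance:
    pair_id: str
    start: int
    insert: int
    flipped: bool  # mate1 originates from the reverse strand


@dataclass(slots=True)
class SyntheticTruth:
    genome: DnaSequence
    genes: list[ExonRecord] = field(default_factory=list)
    repeats: list[RepeatPlacement] = field(default_factory=list)
    read_provenance: list[ReadProvenance] = field(default_factory=list)

    def gene_ids(self) -> list[str]:
        seen: list[str] = []
        for rec in self.genes:
            if rec.gene_id not in seen:
                seen.append(rec.gene_id)
        return seen

    def exons_of(self, gene_id: str) -> list[ExonRecord]:
        return sorted((r for r in self.genes if r.gene_id == gene_id),
                      key=lambda r: r.start)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def simulate_genome(cfg: SimConfig) -> SyntheticTruth:
    """Background sequence with non-overlapping genes and repeat copies
    overwritten in place; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    genome = np.frombuffer(_random_bases(rng, cfg.genome_len).encode("ascii"),
                           dtype=np.uint8).copy()

    # draw gene structures
    gene_plans = []
    margin = 2000
    for g in range(cfg.n_genes):
        n_exons = int(rng.integers(cfg.exons_per_gene[0],
                                   cfg.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
                     for _ in range(n_exons)]
        intron_lens = [int(rng.integers(cfg.intron_len[0],
                                        cfg.intron_len[1] + 1))
                       for _ in range(n_exons - 1)]
        if cfg.plant_repeat_in_intron is not None and cfg.repeat_families:
            gi, ii = cfg.plant_repeat_in_intron
            if gi == g and ii < len(intron_lens):
                unit = cfg.repeat_families[0].unit_len
                intron_lens[ii] = max(intron_lens[ii], unit + 600)
        gene_plans.append((exon_lens, intron_lens))

    total_gene_len = sum(sum(e) + sum(i) for e, i in gene_plans)
    if total_gene_len + cfg.n_genes * margin > cfg.genome_len:
        raise ValueError("genes do not fit the genome; increase genome_len")

    # place genes left to right with randomized intergenic spacing
    free = cfg.genome_len - total_gene_len - 2 * margin
    spacings = rng.dirichlet(np.ones(max(cfg.n_genes, 1))) * free \
        if cfg.n_genes else []
    occupied: list[tuple[int, int]] = []
    genes: list[ExonRecord] = []
    pos = margin
    for g, (exon_lens, intron_lens) in enumerate(gene_plans):
        pos += int(spacings[g])
        gene_id = f"gene{g}"
        strand = "+" if rng.random() < 0.5 else "-"
        start = pos
        cursor = pos
        for e, elen in enumerate(exon_lens):
            genes.append(ExonRecord(gene_id, e, cursor, cursor + elen, strand))
            cursor += elen
            if e < len(intron_lens):
                cursor += intron_lens[e]
        occupied.append((start, cursor))
        pos = cursor

    # place repeat copies in unoccupied (intergenic) regions
    repeats: list[RepeatPlacement] = []
    forbidden = list(occupied)
    planted: tuple[int, int] | None = None
    if cfg.plant_repeat_in_intron is not None and cfg.repeat_families:
        gi, ii = cfg.plant_repeat_in_intron
        exons = [r for r in genes if r.gene_id == f"gene{gi}"]
        exons.sort(key=lambda r: r.start)
        if ii < len(exons) - 1:
            intron_start = exons[ii].end
            intron_end = exons[ii + 1].start
            unit = cfg.repeat_families[0].unit_len
            mid = (intron_start + intron_end - unit) // 2
            planted = (mid, mid + unit)
    for fam_idx, family in enumerate(cfg.repeat_families):
        unit = _random_bases(rng, family.unit_len)
        n_copies = family.copy_number
        copies_todo = n_copies
        if fam_idx == 0 and planted is not None:
            copy = _mutate(rng, unit, family.divergence / 100)
            genome[planted[0]:planted[1]] = np.frombuffer(
                copy.encode("ascii"), dtype=np.uint8)
            repeats.append(RepeatPlacement(fam_idx, planted[0], planted[1]))
            forbidden.append(planted)
            copies_todo -= 1
        attempts = 0
        while copies_todo > 0:
            attempts += 1
            if attempts > 200 * n_copies:
                raise ValueError("cannot place repeat copies; genome too full")
            s = int(rng.integers(0, cfg.genome_len - family.unit_len))
            e = s + family.unit_len
            if any(fs - 300 < e and s < fe + 300 for fs, fe in forbidden):
                continue
            copy = _mutate(rng, unit, family.divergence / 100)
            genome[s:e] = np.frombuffer(copy.encode("ascii"), dtype=np.uint8)
            repeats.append(RepeatPlacement(fam_idx, s, e))
            forbidden.append((s, e))
            copies_todo -= 1

    truth = SyntheticTruth(
        genome=DnaSequence("genome", genome.tobytes().decode("ascii")),
        genes=genes,
        repeats=sorted(repeats, key=lambda r: r.start),
    )
    return truth


def extract_transcripts(truth: SyntheticTruth,
                        variants: bool = False) -> list[DnaSequence]:
    """Spliced cDNA per gene (strand-corrected).  With ``variants`` genes of
    >= 4 exons additionally emit a transcript skipping one middle exon."""
    out: list[DnaSequence] = []
    genome = truth.genome.bases
    for gene_id in truth.gene_ids():
        exons = truth.exons_of(gene_id)
        strand = exons[0].strand
        spliced = "".join(genome[r.start:r.end] for r in exons)
        if strand == "-":
            spliced = revcomp(spliced)
        out.append(DnaSequence(gene_id, spliced))
        if variants and len(exons) >= 4:
            skip = len(exons) // 2
            var = "".join(genome[r.start:r.end]
                          for i, r in enumerate(exons) if i != skip)
            if strand == "-":
                var = revcomp(var)
            out.append(DnaSequence(f"{gene_id}_v1", var))
    return out


def simulate_reads(truth: SyntheticTruth, cfg: SimConfig,
                   seed: int | None = None) -> list[ReadPair]:
    """Convergent pairs drawn uniformly at the target coverage; substitution
    errors i.i.d. at ``cfg.error_rate``; provenance recorded on ``truth``."""
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    genome = truth.genome.bases
    glen = len(genome)
    rl = cfg.read_len
    n_pairs = round(cfg.coverage * glen / (2 * rl))
    inserts = np.maximum(
        rng.normal(cfg.insert_mean, cfg.insert_sd, n_pairs).astype(int),
        rl)
    starts = rng.integers(0, np.maximum(glen - inserts, 1))
    flips = rng.random(n_pairs) < 0.5
    err_counts = (rng.binomial(rl, cfg.error_rate, size=2 * n_pairs)
                  if cfg.error_rate > 0 else np.zeros(2 * n_pairs, int))
    pairs: list[ReadPair] = []
    truth.read_provenance.clear()
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        fwd = genome[s : s + rl]
        rev = revcomp(genome[s + ins - rl : s + ins])
        m1, m2 = (rev, fwd) if flips[i] else (fwd, rev)
        for j, seq in ((2 * i, m1), (2 * i + 1, m2)):
            n_err = int(err_counts[j])
            if n_err:
                arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                for p in rng.integers(0, rl, n_err):
                    choices = [b for b in b"ACGT" if b != arr[p]]
                    arr[p] = choices[rng.integers(0, 3)]
                seq = arr.tobytes().decode("ascii")
            if j % 2 == 0:
                m1 = seq
            else:
                m2 = seq
        pid = f"p{i}"
        pairs.append(ReadPair(pid, DnaSequence(pid, m1), DnaSequence(pid, m2)))
        truth.read_provenance.append(
            ReadProvenance(pid, s, ins, bool(flips[i])))
    return pairs


def write_truth_gff3(truth: SyntheticTruth, path) -> None:
    """Exon records as GFF3 (1-based inclusive per the format)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in truth.genes:
            fh.write("\t".join([
                truth.genome.id, "vgwalk-sim", "exon",
                str(rec.start + 1), str(rec.end), ".", rec.strand, ".",
                f"gene_id={rec.gene_id};exon_index={rec.exon_index}",
            ]) + "\n")
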