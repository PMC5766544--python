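"""Sequence primitives and FASTA/FASTQ input/output.

All coordinates throughout the package are 0-based, half-open; strand is
encoded as ``'+'``/``'-'``.  Lowercase input bases are uppercased on read and
FASTQ base qualities are parsed but discarded (no downstream stage uses them).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequences or records."""


class PairingError(SequenceError):
    """Raised when two mate files cannot be joined into pairs."""


class AmbiguousKmerError(SequenceError):
    """Raised when a k-mer containing ``N`` cannot be canonicalized."""


@dataclass(frozen=True, slots=True)
class DnaSequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceError(f"sequence {self.id!r} is empty")
        if not set(self.bases) <= DNA_ALPHABET:
            bad = sorted(set(self.bases) - DNA_ALPHABET)
            raise SequenceError(
                f"sequence {self.id!r} contains characters outside ACGTN: {bad}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "DnaSequence":
        return DnaSequence(self.id, revcomp(self.bases))


@dataclass(frozen=True, slots=True)
class ReadPair:
    """One mate pair of genomic reads.

    ``pair_id`` is stable across depletion and recruitment so mates can
    always be rejoined.
    """

    pair_id: str
    mate1: DnaSequence
    mate2: DnaSequence


def revcomp(bases: str) -> str:
    """Reverse complement of a plain base string (N maps to N)."""
    return bases.translate(_COMPLEMENT)[::-1]


def reverse_complement(seq: DnaSequence) -> DnaSequence:
    """Watson-Crick complement, reversed.  Involution: rc(rc(s)) == s."""
    return seq.reverse_complement()


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Raises :class:`AmbiguousKmerError` for k-mers containing ``N`` so callers
    can skip them.
    """
    if "N" in kmer:
        raise AmbiguousKmerError(f"k-mer contains N: {kmer!r}")
    if not set(kmer) <= DNA_ALPHABET:
        raise SequenceError(f"k-mer contains non-DNA characters: {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read a (possibly gzip-compressed) multi-record FASTA file."""
    out: list[DnaSequence] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta")):
            try:
                seq = DnaSequence(rec.id, str(rec.seq).upper())
            except SequenceError as exc:
                raise SequenceError(f"record {i} of {path}: {exc}") from exc
            if seq.id in seen:
                raise SequenceError(f"duplicate id {seq.id!r} in {path}")
            seen.add(seq.id)
            out.append(seq)
    return out


def write_fasta(path: str | Path, seqs: Iterable[DnaSequence], width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for seq in seqs:
            handle.write(f">{seq.id}\n")
            for i in range(0, len(seq.bases), width):
                handle.write(seq.bases[i : i + width] + "\n")


def _read_fastq(path: str | Path) -> Iterator[DnaSequence]:
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
            try:
                yield DnaSequence(rec.id, str(rec.seq).upper())
            except SequenceError as exc:
                raise SequenceError(f"record {i} of {path}: {exc}") from exc


def _strip_mate_suffix(name: str) -> str:
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name


def read_fastq_pairs(
    path1: str | Path, path2: str | Path | None = None
) -> list[ReadPair]:
    """Read paired FASTQ (two files, or one interleaved file when ``path2``
    is None).  Gzip input is accepted transparently; qualities are discarded.
    """
    pairs: list[ReadPair] = []
    if path2 is None:
        it = _read_fastq(path1)
        for i, mate1 in enumerate(it):
            mate2 = next(it, None)
            if mate2 is None:
                raise PairingError(
                    f"interleaved file {path1} has an odd number of records "
                    f"(mate1 at record {2 * i} is unpaired)"
                )
            pairs.append(_make_pair(mate1, mate2, i))
        return pairs
    it1, it2 = _read_fastq(path1), _read_fastq(path2)
    i = 0
    while True:
        m1, m2 = next(it1, None), next(it2, None)
        if m1 is None and m2 is None:
            return pairs
        if m1 is None or m2 is None:
            raise PairingError(
                f"mate files {path1} and {path2} differ in record count "
                f"(first unmatched record index {i})"
            )
        pairs.append(_make_pair(m1, m2, i))
        i += 1


def _make_pair(mate1: DnaSequence, mate2: DnaSequence, index: int) -> ReadPair:
    id1, id2 = _strip_mate_suffix(mate1.id), _strip_mate_suffix(mate2.id)
    if id1 != id2:
        raise PairingError(f"mate names disagree at record {index}: {id1!r} vs {id2!r}")
    return ReadPair(id1, DnaSequence(id1, mate1.bases), DnaSequence(id1, mate2.bases))


def write_fastq_pairs(
    path1: str | Path, path2: str | Path, pairs: Iterable[ReadPair]
) -> None:
    """Write pairs as two FASTQ files with constant placeholder qualities."""
    with _open_text(path1, "wt") as h1, _open_text(path2, "wt") as h2:
        for pair in pairs:
            h1.write(
                f"@{pair.pair_id}/1\n{pair.mate1.bases}\n+\n{'I' * len(pair.mate1)}\n"
            )
            h2.write(
                f"@{pair.pair_id}/2\n{pair.mate2.bases}\n+\n{'I' * len(pair.mate2)}\n"
            )
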