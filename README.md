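# vgwalk

Transcript-seeded iterative local assembly of gene-model scaffolds from
low-coverage paired-end whole-genome reads.

Given a set of cDNA/transcript sequences and a paired-end short-read set,
`vgwalk` locally assembles each gene's exons and iteratively walks outward
into introns and flanking sequence, producing one ordered, oriented scaffold
per gene (contigs separated by fixed 500-N spacers where no overlap exists).
Every stage is implemented internally — no external aligner or assembler is
invoked:

| stage | module | what it does |
|---|---|---|
| repeat depletion | `vgwalk.depletion` | removes read pairs with per-read median canonical 31-mer coverage ≤ 1 or > 40, and pairs containing `N` |
| read indexing / recruitment | `vgwalk.recruitment` | seed-and-verify maximal-exact-match search over the (indexed) read set; 40 bp minimum at seeding, 60 bp from contig ends |
| local assembly | `vgwalk.assembly` | canonical de Bruijn unitigger (k = 63) plus overhang-permissive overlap-layout-consensus merging and read-anchored contig elongation |
| the walker | `vgwalk.walker` | per-transcript iteration engine: recruit → assemble → classify exon contigs (culling limit 2) → retain paired-linked neighbours → extend from 600 bp end windows; stops on no growth, drops on contig explosion (≥ 500 or 3× in one round) |
| finishing | `vgwalk.finishing` | chimera detection/splitting by perfect-pair coverage, orientation, similarity-group consensus, exon-order layout, overlap joining, 500-N gap scaffolding |
| scaffold merging | `vgwalk.scaffold_merge` | strips non-mapping contigs and collapses scaffolds from splice variants / fragments of one gene under the 95 % / 99 % HSP-identity rule |
| metrics | `vgwalk.metrics` | intron bridging, flank walk lengths, contig-end stop classification (extending / repeat / low-coverage), N50 excluding gap Ns |
| synthetic data | `vgwalk.simulate` | seeded genome/gene/repeat/read simulator with ground-truth annotations |

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests (hypothesis) for
the invariants, brute-force oracle comparisons (median coverage, maximal
exact matches, N50), and `tests/test_acceptance.py` with end-to-end
truth-recovery runs on simulated genomes. The full run takes a few minutes;
the heavyweight simulations are marked `slow`
(`-m "not slow"` skips them).

## Command line

```bash
# generate a synthetic dataset with ground truth
vgwalk simulate --config sim.yaml --out-dir sim/

# run the whole pipeline from a config file
vgwalk all --config pipeline.yaml --out-dir run/

# or stage by stage
vgwalk deplete --reads1 sim/reads_1.fastq --reads2 sim/reads_2.fastq --out-prefix dep
vgwalk index   --reads1 dep_1.fastq --reads2 dep_2.fastq --out idx/
vgwalk recruit --index idx/ --query-fasta sim/transcripts.fasta --min-match 40 --out ids.txt
vgwalk walk    --index idx/ --transcripts sim/transcripts.fasta --out-dir walk/
vgwalk finish  --walk-dir walk/ --transcripts sim/transcripts.fasta \
               --reads1 dep_1.fastq --reads2 dep_2.fastq --out scaffolds.fasta
vgwalk merge   --scaffolds scaffolds.fasta --transcripts sim/transcripts.fasta --out merged.fasta
vgwalk metrics --scaffolds merged.fasta --transcripts sim/transcripts.fasta --out report.tsv
```

A minimal pipeline config:

```yaml
transcripts: sim/transcripts.fasta
reads1: sim/reads_1.fastq
reads2: sim/reads_2.fastq
walker:
  max_iterations: 30
```

FASTA/FASTQ inputs may be gzip-compressed. All intervals are 0-based
half-open; FASTQ qualities are parsed and ignored.

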