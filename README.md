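# haplopath

Haplotype-aware path indexing for population (variation) graphs.

`haplopath` turns a haplotype-annotated sequence DAG into a **null graph** —
an edge-free set of sequences that contains *exactly* the length-`k`
substrings of the encoded haplotypes, no more and no less. Because the result
is plain FASTA, any established linear read aligner (BWA, Bowtie2, ...) can
align reads to the graph by proxy; the alignments are then projected back
onto graph coordinates through per-base provenance intervals.

The haplotype constraint is the point: instead of enumerating all `k`-paths
(which explodes combinatorially with variant density), node duplication is
limited to haplotype-supported in/out edge pairings, so work in any region is
bounded by the number of encoded haplotypes.

## Layout

| module | role |
| --- | --- |
| `haplopath.graphcore` | graph/haplotype data model, validation, spelling, GFA1 I/O |
| `haplopath.vcf2graph` | reference FASTA + phased VCF → haplotyped graph |
| `haplopath.chopper` | collapse / extend / duplicate operations and the deterministic scheduler |
| `haplopath.nullindex` | null graph → FASTA with provenance headers, and back |
| `haplopath.backproject` | SAM against the index → graph paths (TSV or GAF) |
| `haplopath.popsim` | seeded population/variant/read simulator with string-editing truth oracle |
| `haplopath.cli` | `haplopath build / index / project / simulate` |

## Usage

```sh
# simulate a small phased population (writes FASTA/VCF/FASTQ/GFA + truth tables)
haplopath simulate --outdir sim --seed 1 --samples 5 --variants 20

# build a haplotyped graph from a reference and a phased VCF
haplopath build --ref sim/reference.fa --vcf sim/variants.vcf --out graph.gfa

# decompose into an edge-free FASTA index for k = 101 (match your read length;
# reads up to k bases always lie inside one record)
haplopath index --gfa graph.gfa -k 101 --out null.fa

# align reads with any linear aligner, e.g.
#   bwa index null.fa && bwa mem null.fa reads.fq > aln.sam

# project the alignments back onto graph coordinates
haplopath project --index null.fa --sam aln.sam --out aln.tsv          # or --format gaf
```

Null-graph FASTA headers carry the provenance grammar
`>{id} {origin}:{start}-{end}(;{origin}:{start}-{end})*` with 0-based
half-open intervals; aligners ignore everything after the first space.
Projection output (TSV) columns are
`read_id  strand  path  entry_offset  exit_offset  mapq  cigar`.

GFA1 input must use forward-strand segments, `0M` link overlaps, and P-lines
naming the haplotype paths (every link must be covered by a path unless
`--allow-uncovered` is given).

## Guarantees

* **Completeness & soundness** — the set of `k`-windows of the emitted
  sequences equals the set of `k`-mers of the spelled haplotypes (haplotypes
  shorter than `k` are kept whole).
* **Spelling preservation** — collapse and duplicate never change any
  haplotype's spelled sequence; the duplicate copy count never exceeds the
  number of haplotypes through the node.
* **Determinism** — identical inputs produce byte-identical GFA, FASTA and
  projection outputs.
* **Traceability** — every emitted base maps to a node interval of the input
  graph, and every record maps to a connected path.

These are enforced by the test suite (`tests/test_acceptance.py` runs the
full criteria, including a 100-population property sweep and a 500-read
projection round trip).

## Scope notes

Acyclic graphs only; single-end short reads (reads must be ≤ `k`); the
external aligner is not invoked by this package. Paired-end and long-read
support are out of scope.
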