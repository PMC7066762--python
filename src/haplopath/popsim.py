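"""Seeded population / variant / read simulator used as the test-fixture source.

Each simulated sample contributes a fixed number of variants; with
probability ``share_prob`` a variant is drawn from a population-wide shared
pool (so it can recur in other samples), otherwise it is unique to the
sample.  Genotypes are phased (diploid) or haploid.  Truth haplotype strings
are produced by direct string editing -- an oracle deliberately independent
of the graph builder -- and error-free reads can be sampled from them with
full truth coordinates in both string and graph-path space.

All randomness flows from ``SimConfig.seed`` through ``random.Random``; equal
configs give byte-identical FASTA/VCF/FASTQ output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .graphcore import PopulationGraph
from .vcf2graph import REF_HAPLOTYPE, VariantRecord, haplotype_ids

BASES = "ACGT"


class SimError(ValueError):
    """Raised on infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    ref_len: int = 2000
    n_samples: int = 5
    variants_per_sample: int = 20
    share_prob: float = 0.2
    snp_indel_ratio: float = 4.0  # SNP:indel odds; 4.0 means 4 SNPs per indel
    max_indel: int = 3
    ploidy: int = 2
    seed: int = 0
    read_length: int = 32
    reads_per_haplotype: int = 5
    contig: str = "sim"

    def __post_init__(self) -> None:
        if min(self.ref_len, self.n_samples, self.variants_per_sample) < 1:
            raise SimError("counts must be positive")
        if not 0.0 <= self.share_prob <= 1.0:
            raise SimError(f"share_prob must be in [0,1], got {self.share_prob}")
        if self.ploidy not in (1, 2):
            raise SimError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if self.max_indel < 1 or self.read_length < 1 or self.reads_per_haplotype < 0:
            raise SimError("invalid length parameters")
        if self.snp_indel_ratio < 0:
            raise SimError("snp_indel_ratio must be >= 0")


@dataclass(frozen=True)
class SimVariant:
    """A single VCF-style allele pair, anchors included."""

    pos: int  # 1-based
    ref: str
    alt: str


@dataclass
class Population:
    config: SimConfig
    reference: str
    sample_names: List[str]
    records: List[VariantRecord]
    truth: Dict[str, str]  # haplotype id -> spelled sequence (string-edit oracle)
    shared_draws: Dict[str, int]  # sample -> number of pool-drawn variants

    @property
    def haplotype_names(self) -> List[str]:
        ploidies = {s: self.config.ploidy for s in self.sample_names}
        return haplotype_ids(self.sample_names, ploidies)


def apply_variants(reference: str, variants: Sequence[Tuple[int, str, str]]) -> str:
    """Apply non-overlapping (pos, ref, alt) edits to a string.

    ``pos`` is 1-based; alleles carry their VCF anchor bases.  This is the
    independent spelling oracle: it never touches graph machinery.
    """
    edits = sorted(variants, key=lambda v: v[0], reverse=True)
    seen = set()
    s = reference
    for pos, ref, alt in edits:
        if pos in seen:
            raise SimError(f"duplicate edit position {pos}")
        seen.add(pos)
        if s[pos - 1 : pos - 1 + len(ref)] != ref:
            raise SimError(f"edit at {pos} does not match reference")
        s = s[: pos - 1] + alt + s[pos - 1 + len(ref) :]
    return s


def _make_variant(rng: random.Random, reference: str, pos0: int, cfg: SimConfig) -> SimVariant:
    snp_prob = cfg.snp_indel_ratio / (cfg.snp_indel_ratio + 1.0)
    anchor = reference[pos0]
    if rng.random() < snp_prob:
        alt = rng.choice([b for b in BASES if b != anchor])
        return SimVariant(pos0 + 1, anchor, alt)
    length = rng.randint(1, cfg.max_indel)
    if rng.random() < 0.5:  # insertion after the anchor base
        ins = "".join(rng.choice(BASES) for _ in range(length))
        return SimVariant(pos0 + 1, anchor, anchor + ins)
    ref = reference[pos0 : pos0 + 1 + length]
    return SimVariant(pos0 + 1, ref, anchor)


def simulate_population(cfg: SimConfig) -> Population:
    """Draw a reference, a phased variant population, and truth haplotypes."""
    rng = random.Random(cfg.seed)
    reference = "".join(rng.choice(BASES) for _ in range(cfg.ref_len))
    samples = [f"s{i}" for i in range(cfg.n_samples)]

    # candidate anchor positions on a grid spaced so no two variants can
    # overlap (builder rejects overlapping records)
    spacing = cfg.max_indel + 2
    slots = list(range(1, cfg.ref_len - cfg.max_indel - 2, spacing))
    pool_size = cfg.variants_per_sample
    worst_case = pool_size + cfg.n_samples * cfg.variants_per_sample
    if len(slots) < worst_case:
        raise SimError(
            f"reference of {cfg.ref_len} bp has {len(slots)} variant slots; "
            f"need up to {worst_case}"
        )
    rng.shuffle(slots)
    pool = [_make_variant(rng, reference, slots.pop(), cfg) for _ in range(pool_size)]

    carriers: Dict[SimVariant, Dict[str, Tuple[int, ...]]] = {}
    shared_draws: Dict[str, int] = {}

    def genotype(rng: random.Random) -> Tuple[int, ...]:
        if cfg.ploidy == 1:
            return (1,)
        return rng.choice([(1, 0), (0, 1), (1, 1)])

    for s in samples:
        chosen: List[SimVariant] = []
        n_shared = 0
        pool_left = list(pool)
        for _ in range(cfg.variants_per_sample):
            if pool_left and rng.random() < cfg.share_prob:
                v = pool_left.pop(rng.randrange(len(pool_left)))
                n_shared += 1
            else:
                v = _make_variant(rng, reference, slots.pop(), cfg)
            chosen.append(v)
        shared_draws[s] = n_shared
        for v in chosen:
            carriers.setdefault(v, {})[s] = genotype(rng)

    records: List[VariantRecord] = []
    for v in sorted(carriers, key=lambda v: v.pos):
        genotypes = {
            s: carriers[v].get(s, (0,) * cfg.ploidy) for s in samples
        }
        records.append(VariantRecord(cfg.contig, v.pos, v.ref, (v.alt,), genotypes))

    truth: Dict[str, str] = {REF_HAPLOTYPE: reference}
    ploidies = {s: cfg.ploidy for s in samples}
    for hap in haplotype_ids(samples, ploidies)[1:]:
        if cfg.ploidy == 1:
            sample, hi = hap, 0
        else:
            sample, idx = hap.rsplit("#", 1)
            hi = int(idx) - 1
        edits = [
            (r.pos, r.ref, r.alts[0])
            for r in records
            if r.genotypes[sample][hi] == 1
        ]
        truth[hap] = apply_variants(reference, edits)
    return Population(cfg, reference, samples, records, truth, shared_draws)


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    haplotype: str
    start: int  # 0-based offset into the haplotype string
    seq: str
    path: Tuple[str, ...] = ()
    entry: int = 0  # offset into the first path node
    exit: int = 0  # exclusive offset into the last path node


def _graph_coordinates(
    graph: PopulationGraph, hap: str, start: int, length: int
) -> Tuple[Tuple[str, ...], int, int]:
    path = graph.haplotype_paths[hap]
    lens = [len(graph.nodes[n].seq) for n in path]
    cum = [0]
    for n in lens:
        cum.append(cum[-1] + n)
    end = start + length
    if end > cum[-1]:
        raise SimError(f"read overruns haplotype {hap!r}")
    i = next(j for j in range(len(path)) if cum[j + 1] > start)
    j = next(j for j in range(len(path)) if cum[j + 1] >= end)
    return tuple(path[i : j + 1]), start - cum[i], end - cum[j]


def sample_reads(
    population: Population,
    cfg: Optional[SimConfig] = None,
    graph: Optional[PopulationGraph] = None,
) -> List[ReadTruth]:
    """Error-free reads from the truth haplotypes with known coordinates.

    When ``graph`` (the built population graph, haplotype paths intact) is
    given, each read also records its true node path with entry/exit offsets.
    """
    cfg = cfg or population.config
    rng = random.Random(f"{cfg.seed}:reads")
    reads: List[ReadTruth] = []
    for hap in population.haplotype_names:
        hap_seq = population.truth[hap]
        if cfg.read_length > len(hap_seq):
            raise SimError(
                f"read length {cfg.read_length} exceeds haplotype {hap!r} "
                f"length {len(hap_seq)}"
            )
        for i in range(cfg.reads_per_haplotype):
            start = rng.randint(0, len(hap_seq) - cfg.read_length)
            seq = hap_seq[start : start + cfg.read_length]
            rid = f"{hap}|{i}|{start}"
            if graph is not None:
                path, entry, exit_ = _graph_coordinates(
                    graph, hap, start, cfg.read_length
                )
                reads.append(ReadTruth(rid, hap, start, seq, path, entry, exit_))
            else:
                reads.append(ReadTruth(rid, hap, start, seq))
    return reads


# ---------------------------------------------------------------------------
# writers (plain-text formats only)


def write_reference_fasta(population: Population, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{population.config.contig}\n")
        seq = population.reference
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def write_vcf(population: Population, path: str) -> None:
    cfg = population.config
    sep = "|" if cfg.ploidy == 2 else None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cfg.contig},length={cfg.ref_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(population.sample_names)
            + "\n"
        )
        for rec in population.records:
            gts = []
            for s in population.sample_names:
                gt = rec.genotypes[s]
                gts.append("|".join(str(a) for a in gt) if sep else str(gt[0]))
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{','.join(rec.alts)}\t.\t"
                f"PASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_truth_table(population: Population, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype\tlength\tsequence\n")
        for hap in population.haplotype_names:
            seq = population.truth[hap]
            fh.write(f"{hap}\t{len(seq)}\t{seq}\n")


def write_fastq(reads: Sequence[ReadTruth], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_read_truth(reads: Sequence[ReadTruth], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\thaplotype\tstart\tpath\tentry\texit\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.haplotype}\t{r.start}\t"
                f"{','.join(r.path)}\t{r.entry}\t{r.exit}\n"
            )
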