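"""Build a haplotype-annotated PopulationGraph from a reference and phased variants.

The reference is split at variant breakpoints into backbone nodes; each
distinct carried alternate allele becomes an alt node (deletions become a
direct edge skipping reference sequence).  One haplotype path is registered
for the reference plus two per diploid sample (one per haploid sample), and
edge haplotype sets are derived from those paths, so spelling any haplotype
reproduces exactly the string obtained by applying its alleles to the
reference.

Node ids: reference nodes ``contig:start-end`` (0-based half-open), alt nodes
``contig:pos:altIndex`` (1-based VCF position, 1-based alt index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

from .graphcore import (
    GraphError,
    HaplotypeRegistry,
    PopulationGraph,
    VALID_BASES,
)

logger = logging.getLogger(__name__)

REF_HAPLOTYPE = "REF"


class VariantError(ValueError):
    """Raised on malformed, unphased, out-of-bounds, or colliding variants."""


@dataclass(frozen=True)
class VariantRecord:
    """One (possibly multi-allelic) variant with per-sample phased genotypes.

    ``pos`` is the 1-based reference position of the first REF base.
    ``genotypes`` maps sample name to a tuple of allele indices, one entry
    per haplotype (length 1 for haploid, 2 for diploid phased).
    """

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    genotypes: Dict[str, Tuple[int, ...]]

    def __post_init__(self) -> None:
        if not self.ref or set(self.ref) - VALID_BASES:
            raise VariantError(f"{self.chrom}:{self.pos}: invalid REF allele {self.ref!r}")
        for alt in self.alts:
            if not alt or set(alt) - VALID_BASES:
                raise VariantError(f"{self.chrom}:{self.pos}: invalid ALT allele {alt!r}")


@dataclass(frozen=True)
class _AltSpan:
    """Normalized footprint of one alt allele (anchor bases stripped)."""

    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive; start == end for pure insertions
    alt_seq: str  # replacement sequence; empty for pure deletions
    node_id: str


def _normalize_alt(chrom: str, pos: int, ref: str, alt: str, alt_index: int) -> _AltSpan:
    lcp = 0
    while lcp < min(len(ref), len(alt)) and ref[lcp] == alt[lcp]:
        lcp += 1
    # keep at least one differing/inserted base representable: if alleles are
    # identical the variant is a no-op, reject upstream via alt == ref check
    start = pos - 1 + lcp
    end = pos - 1 + len(ref)
    return _AltSpan(start, end, alt[lcp:], f"{chrom}:{pos}:{alt_index}")


def haplotype_ids(samples: Sequence[str], ploidies: Dict[str, int]) -> List[str]:
    """Registry order: REF first, then per-sample haplotypes in sample order."""
    out = [REF_HAPLOTYPE]
    for s in samples:
        if ploidies[s] == 1:
            out.append(s)
        else:
            out.extend(f"{s}#{i + 1}" for i in range(ploidies[s]))
    return out


def build_graph(
    reference: str,
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
    contig: str = "ref",
    on_overlap: str = "error",
) -> PopulationGraph:
    """Construct the population graph for ``reference`` plus phased ``variants``.

    ``variants`` must be position-sorted with REF alleles matching the
    reference.  Overlapping records raise :class:`VariantError` unless
    ``on_overlap="drop"``, which drops the later record and logs it.
    """
    if not reference:
        raise VariantError("empty reference sequence")
    if set(reference) - VALID_BASES:
        raise VariantError("reference contains invalid characters")
    if on_overlap not in ("error", "drop"):
        raise VariantError(f"on_overlap must be 'error' or 'drop', got {on_overlap!r}")

    ploidies: Dict[str, int] = {}
    for rec in variants:
        for s, gt in rec.genotypes.items():
            ploidies.setdefault(s, len(gt))
            if ploidies[s] != len(gt):
                raise VariantError(
                    f"{rec.chrom}:{rec.pos}: inconsistent ploidy for sample {s!r}"
                )
    for s in samples:
        ploidies.setdefault(s, 2)

    # bounds, reference-match, ordering and overlap checks
    kept: List[VariantRecord] = []
    prev_end = -1
    prev_rec: Optional[VariantRecord] = None
    for rec in variants:
        if rec.pos < 1 or rec.pos - 1 + len(rec.ref) > len(reference):
            raise VariantError(f"{rec.chrom}:{rec.pos}: variant outside reference bounds")
        if reference[rec.pos - 1 : rec.pos - 1 + len(rec.ref)] != rec.ref:
            raise VariantError(
                f"{rec.chrom}:{rec.pos}: REF allele {rec.ref!r} does not match reference "
                f"{reference[rec.pos - 1 : rec.pos - 1 + len(rec.ref)]!r}"
            )
        if any(alt == rec.ref for alt in rec.alts):
            raise VariantError(f"{rec.chrom}:{rec.pos}: ALT allele equal to REF")
        spans = [
            _normalize_alt(contig, rec.pos, rec.ref, alt, i + 1)
            for i, alt in enumerate(rec.alts)
        ]
        f_start = min(s.start for s in spans)
        f_end = max(s.end for s in spans)
        if kept and (f_start < prev_end or (f_start == prev_end == f_end and prev_end == prev_f_start)):
            msg = (
                f"overlapping variants: {prev_rec.chrom}:{prev_rec.pos} "
                f"({prev_rec.ref}>{','.join(prev_rec.alts)}) and "
                f"{rec.chrom}:{rec.pos} ({rec.ref}>{','.join(rec.alts)})"
            )
            if on_overlap == "error":
                raise VariantError(msg)
            logger.warning("dropping variant: %s", msg)
            continue
        if kept and rec.pos < kept[-1].pos:
            raise VariantError(f"variants not sorted at {rec.chrom}:{rec.pos}")
        kept.append(rec)
        prev_end = f_end
        prev_f_start = f_start
        prev_rec = rec

    hap_ids = haplotype_ids(samples, ploidies)
    registry = HaplotypeRegistry(hap_ids)

    # allele choice per haplotype per kept record (0 = REF)
    def hap_allele(rec: VariantRecord, sample: str, hap_idx: int) -> int:
        gt = rec.genotypes.get(sample)
        if gt is None:
            return 0
        return gt[hap_idx]

    # collect carried alt spans and backbone breakpoints
    carried: Dict[Tuple[int, int], _AltSpan] = {}  # (record idx, alt idx)
    for ri, rec in enumerate(kept):
        for s in samples:
            for hi in range(ploidies[s]):
                ai = hap_allele(rec, s, hi)
                if ai > 0:
                    if ai > len(rec.alts):
                        raise VariantError(
                            f"{rec.chrom}:{rec.pos}: allele index {ai} out of range"
                        )
                    key = (ri, ai)
                    if key not in carried:
                        carried[key] = _normalize_alt(
                            contig, rec.pos, rec.ref, rec.alts[ai - 1], ai
                        )
    breakpoints = {0, len(reference)}
    for span in carried.values():
        breakpoints.add(span.start)
        breakpoints.add(span.end)
    bounds = sorted(breakpoints)

    graph = PopulationGraph(registry)
    backbone: List[Tuple[int, int, str]] = []
    for s, e in zip(bounds, bounds[1:]):
        nid = f"{contig}:{s}-{e}"
        graph.add_node(nid, reference[s:e])
        backbone.append((s, e, nid))
    for span in sorted(set(carried.values()), key=lambda x: x.node_id):
        if span.alt_seq:
            graph.add_node(span.node_id, span.alt_seq)

    backbone_at = {s: (e, nid) for s, e, nid in backbone}

    def backbone_walk(frm: int, to: int) -> List[str]:
        out: List[str] = []
        cur = frm
        while cur < to:
            e, nid = backbone_at[cur]
            out.append(nid)
            cur = e
        if cur != to:
            raise GraphError(f"backbone walk misaligned at {cur} != {to}")
        return out

    # haplotype paths
    paths: Dict[str, List[str]] = {}
    hap_owner: List[Tuple[str, Optional[str], int]] = [(REF_HAPLOTYPE, None, 0)]
    for s in samples:
        if ploidies[s] == 1:
            hap_owner.append((s, s, 0))
        else:
            for hi in range(ploidies[s]):
                hap_owner.append((f"{s}#{hi + 1}", s, hi))
    for hap, sample, hi in hap_owner:
        path: List[str] = []
        cursor = 0
        for ri, rec in enumerate(kept):
            ai = 0 if sample is None else hap_allele(rec, sample, hi)
            if ai == 0:
                continue
            span = carried[(ri, ai)]
            path.extend(backbone_walk(cursor, span.start))
            if span.alt_seq:
                path.append(span.node_id)
            cursor = span.end
        path.extend(backbone_walk(cursor, len(reference)))
        if not path:
            raise VariantError(f"haplotype {hap!r} spells the empty string")
        paths[hap] = path

    graph.haplotype_paths = paths
    graph.derive_edges_from_paths()
    # drop nodes traversed by no haplotype (backbone fragments inside spans
    # cannot occur, but guard anyway)
    used = {n for p in paths.values() for n in p}
    for nid in sorted(set(graph.nodes) - used):
        graph.remove_node(nid)
    return graph


# ---------------------------------------------------------------------------
# VCF parsing


class ParseResult(List[VariantRecord]):
    """Ordered VariantRecords plus the count of skipped symbolic records."""

    def __init__(self, records: Iterable[VariantRecord] = (), skipped: int = 0):
        super().__init__(records)
        self.skipped = skipped


def _is_symbolic(alt: Optional[str]) -> bool:
    if alt is None:
        return True
    return bool(set(alt) - VALID_BASES)  # <INS>, breakends, '*', etc.


def parse_vcf(path: str, region: Optional[str] = None) -> ParseResult:
    """Read VCF 4.x (plain or bgzipped) into ordered VariantRecords.

    Multi-allelic sites are preserved as one record.  Records whose alleles
    are symbolic (e.g. ``<INS>``) or breakends are skipped and counted.
    Unphased heterozygous genotypes are an error.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VariantError(f"cannot parse VCF {path}: {exc}") from exc
    records: List[VariantRecord] = []
    skipped = 0
    with vf:
        samples = list(vf.header.samples)
        iterator = vf.fetch(region=region) if region else vf
        for rec in iterator:
            alts = rec.alts or ()
            if not alts or any(_is_symbolic(a) for a in alts) or _is_symbolic(rec.ref):
                skipped += 1
                continue
            genotypes: Dict[str, Tuple[int, ...]] = {}
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    raise VariantError(
                        f"{rec.chrom}:{rec.pos}: missing genotype for sample {s!r}"
                    )
                alleles = tuple(0 if a is None else int(a) for a in gt)
                if len(alleles) > 1 and len(set(alleles)) > 1 and not call.phased:
                    raise VariantError(
                        f"{rec.chrom}:{rec.pos}: unphased genotype for sample {s!r}"
                    )
                genotypes[s] = alleles
            records.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, tuple(alts), genotypes)
            )
    if skipped:
        logger.info("skipped %d symbolic/breakend records in %s", skipped, path)
    return ParseResult(records, skipped)
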