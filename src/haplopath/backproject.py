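"""Project linear alignments against the null-graph FASTA back onto the graph.

A SAM record aligned to a null-graph record covers an interval of that
record's sequence; walking the record's provenance segments across that
interval yields the ordered path of original-graph nodes with entry/exit
offsets.  Soft-clipped bases consume no reference and are excluded from the
projected span.  Reverse-strand alignments keep the forward-graph path with
the strand flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pysam

from .nullindex import NullIndex

# CIGAR operations that consume reference bases: M, D, N, =, X
_REF_CONSUMING = {0, 2, 3, 7, 8}


class ProjectionError(ValueError):
    """Raised for records that cannot be projected (bad reference, overrun)."""


@dataclass(frozen=True)
class GraphAlignment:
    read_id: str
    path: Tuple[str, ...]  # ordered original-graph node ids
    entry: int  # 0-based offset into the first node
    exit: int  # exclusive offset into the last node
    strand: str  # '+' or '-'
    mapq: int
    cigar: str

    def covered_span(self) -> int:
        """Reference bases consumed, summed over the path."""
        return _cigar_reference_length_str(self.cigar)


def _cigar_reference_length(cigartuples) -> int:
    return sum(n for op, n in cigartuples if op in _REF_CONSUMING)


def _cigar_reference_length_str(cigar: str) -> int:
    total = 0
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            if c in "MDN=X":
                total += int(num)
            num = ""
    return total


def project(index: NullIndex, record: "pysam.AlignedSegment") -> GraphAlignment:
    """Project one mapped SAM record onto the original graph."""
    if record.is_unmapped:
        raise ProjectionError(f"read {record.query_name!r} is unmapped")
    name = record.reference_name
    if name not in index:
        raise ProjectionError(f"unknown reference {name!r} for read {record.query_name!r}")
    rec = index.records[name]
    pos = record.reference_start
    reflen = _cigar_reference_length(record.cigartuples or ())
    if reflen <= 0:
        raise ProjectionError(f"read {record.query_name!r} consumes no reference bases")
    end = pos + reflen
    if end > rec.length:
        raise ProjectionError(
            f"read {record.query_name!r} overruns record {name!r} "
            f"({end} > {rec.length}); corrupt index or SAM"
        )
    path: List[str] = []
    entry = exit_ = 0
    for i, seg in enumerate(rec.segments):
        seg_lo = rec.starts[i]
        seg_hi = seg_lo + len(seg)
        if seg_hi <= pos or seg_lo >= end:
            continue
        lo = max(pos, seg_lo)
        hi = min(end, seg_hi)
        o_lo = seg.start + (lo - seg_lo)
        o_hi = seg.start + (hi - seg_lo)
        if path and path[-1] == seg.origin and exit_ == o_lo:
            exit_ = o_hi  # merge contiguous same-origin segments
        else:
            if not path:
                entry = o_lo
            path.append(seg.origin)
            exit_ = o_hi
    return GraphAlignment(
        read_id=record.query_name,
        path=tuple(path),
        entry=entry,
        exit=exit_,
        strand="-" if record.is_reverse else "+",
        mapq=record.mapping_quality,
        cigar=record.cigarstring or "",
    )


def to_tsv(aln: GraphAlignment) -> str:
    return "\t".join(
        [
            aln.read_id,
            aln.strand,
            ",".join(aln.path),
            str(aln.entry),
            str(aln.exit),
            str(aln.mapq),
            aln.cigar,
        ]
    )


def to_gaf(aln: GraphAlignment, record: "pysam.AlignedSegment", origin_lengths: Dict[str, int]) -> str:
    """GAF line with '>node' path syntax and path-space coordinates."""
    qlen = record.query_length or (record.infer_read_length() or 0)
    qstart = record.query_alignment_start
    qend = record.query_alignment_end
    path_len = sum(origin_lengths[n] for n in aln.path)
    pstart = aln.entry
    pend = path_len - (origin_lengths[aln.path[-1]] - aln.exit)
    reflen = _cigar_reference_length(record.cigartuples or ())
    return "\t".join(
        [
            aln.read_id,
            str(qlen),
            str(qstart),
            str(qend),
            aln.strand,
            "".join(f">{n}" for n in aln.path),
            str(path_len),
            str(pstart),
            str(pend),
            str(reflen),
            str(reflen),
            str(aln.mapq),
        ]
    )


def project_sam(
    index: NullIndex,
    sam_path: str,
    out_path: str,
    fmt: str = "tsv",
    include_secondary: bool = False,
) -> Dict[str, int]:
    """Project every primary mapped record of a SAM/BAM file.

    Writes one line per projected alignment to ``out_path`` (sorted stream
    order is preserved, so identical inputs give byte-identical outputs).
    Unmapped records and, by default, secondary/supplementary records are
    skipped and counted.  Per-record projection failures are aggregated and
    raised after the pass.
    """
    if fmt not in ("tsv", "gaf"):
        raise ProjectionError(f"unknown output format {fmt!r}")
    counts = {"projected": 0, "unmapped_skipped": 0, "secondary_skipped": 0}
    errors: List[str] = []
    origin_lengths = index.origin_lengths() if fmt == "gaf" else {}
    with pysam.AlignmentFile(sam_path, check_sq=False) as sam, open(out_path, "w") as out:
        for i, record in enumerate(sam):
            if record.is_unmapped:
                counts["unmapped_skipped"] += 1
                continue
            if (record.is_secondary or record.is_supplementary) and not include_secondary:
                counts["secondary_skipped"] += 1
                continue
            try:
                aln = project(index, record)
            except ProjectionError as exc:
                errors.append(f"record {i}: {exc}")
                continue
            line = to_tsv(aln) if fmt == "tsv" else to_gaf(aln, record, origin_lengths)
            out.write(line + "\n")
            counts["projected"] += 1
    if errors:
        raise ProjectionError(
            f"{len(errors)} records failed projection; first: {errors[0]}"
        )
    return counts
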