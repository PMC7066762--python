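"""Serialize a null graph as aligner-ready FASTA and load it for projection.

Each record's header carries the node's provenance intervals:

    >{id} {origin}:{start}-{end}(;{origin}:{start}-{end})*

with 0-based half-open intervals.  Linear aligners ignore everything after
the first whitespace, so record ids remain clean reference names.  Sequences
are wrapped at 60 columns and records are sorted by id, making serialization
byte-deterministic.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterator, List, Tuple

from .graphcore import PopulationGraph, ProvenanceSegment, prov_length


class IndexError_(ValueError):
    """Raised on malformed index files or out-of-range lookups."""


@dataclass(frozen=True)
class IndexRecord:
    name: str
    length: int
    segments: Tuple[ProvenanceSegment, ...]
    starts: Tuple[int, ...]  # cumulative start offset of each segment

    @staticmethod
    def build(name: str, length: int, segments: Tuple[ProvenanceSegment, ...]) -> "IndexRecord":
        if prov_length(segments) != length:
            raise IndexError_(
                f"record {name!r}: provenance length {prov_length(segments)} "
                f"!= sequence length {length}"
            )
        starts: List[int] = []
        off = 0
        for seg in segments:
            starts.append(off)
            off += len(seg)
        return IndexRecord(name, length, segments, tuple(starts))

    def locate(self, offset: int) -> Tuple[str, int]:
        if not 0 <= offset < self.length:
            raise IndexError_(
                f"offset {offset} out of range for record {self.name!r} "
                f"of length {self.length}"
            )
        i = bisect_right(self.starts, offset) - 1
        seg = self.segments[i]
        return seg.origin, seg.start + (offset - self.starts[i])


class NullIndex:
    """Record-name -> provenance mapping with O(log s) per-base lookup."""

    def __init__(self, records: Dict[str, IndexRecord]):
        self.records = records

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def locate(self, name: str, offset: int) -> Tuple[str, int]:
        """Map (record, offset) to (origin node, within-node offset)."""
        if name not in self.records:
            raise IndexError_(f"unknown record {name!r}")
        return self.records[name].locate(offset)

    def origin_lengths(self) -> Dict[str, int]:
        """Origin-node lengths inferred as the maximal covered end offset.

        The null graph covers every base of every input node, so the maximum
        interval end per origin equals the node's length.
        """
        out: Dict[str, int] = {}
        for rec in self.records.values():
            for seg in rec.segments:
                out[seg.origin] = max(out.get(seg.origin, 0), seg.end)
        return out

    @staticmethod
    def from_graph(null: PopulationGraph) -> "NullIndex":
        if null.n_edges:
            raise IndexError_(f"graph still has {null.n_edges} edges; not a null graph")
        records = {
            nid: IndexRecord.build(nid, len(node.seq), node.provenance)
            for nid, node in null.nodes.items()
        }
        return NullIndex(records)


def locate(index: NullIndex, name: str, offset: int) -> Tuple[str, int]:
    return index.locate(name, offset)


def _format_provenance(segments: Tuple[ProvenanceSegment, ...]) -> str:
    return ";".join(str(s) for s in segments)


def write_fasta(null: PopulationGraph, path: str, width: int = 60) -> int:
    """Emit one FASTA record per null-graph node; returns the record count."""
    if null.n_edges:
        raise IndexError_(f"graph still has {null.n_edges} edges; not a null graph")
    n = 0
    with open(path, "w") as fh:
        for nid in sorted(null.nodes):
            node = null.nodes[nid]
            fh.write(f">{nid} {_format_provenance(node.provenance)}\n")
            for i in range(0, len(node.seq), width):
                fh.write(node.seq[i : i + width] + "\n")
            n += 1
    return n


def _parse_segment(token: str, record: str) -> ProvenanceSegment:
    origin, _, interval = token.rpartition(":")
    start_s, _, end_s = interval.rpartition("-")
    if not origin or not start_s.isdigit() or not end_s.isdigit():
        raise IndexError_(f"record {record!r}: malformed provenance segment {token!r}")
    return ProvenanceSegment(origin, int(start_s), int(end_s))


def read_index(path: str) -> NullIndex:
    """Load a FASTA produced by :func:`write_fasta` back into a NullIndex."""
    records: Dict[str, IndexRecord] = {}
    name = None
    segments: Tuple[ProvenanceSegment, ...] = ()
    length = 0

    def flush() -> None:
        if name is None:
            return
        if name in records:
            raise IndexError_(f"duplicate record {name!r}")
        records[name] = IndexRecord.build(name, length, segments)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].split(None, 1)
                if len(head) != 2:
                    raise IndexError_(f"{path}:{lineno}: header without provenance")
                name = head[0]
                try:
                    segments = tuple(
                        _parse_segment(t, name) for t in head[1].split(";")
                    )
                except ValueError as exc:
                    raise IndexError_(f"{path}:{lineno}: {exc}") from exc
                length = 0
            else:
                if name is None:
                    raise IndexError_(f"{path}:{lineno}: sequence before first header")
                length += len(line)
        flush()
    return NullIndex(records)
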