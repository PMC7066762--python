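"""Haplotype-annotated sequence graph model plus GFA1 I/O.

A :class:`PopulationGraph` is a directed acyclic graph whose nodes carry DNA
sequences and whose edges carry the non-empty set of haplotypes observed to
traverse them.  Each haplotype is additionally stored as an explicit node
path; edge haplotype sets and paths are kept mutually consistent by the
builders in this package and checked by :func:`validate`.

Every node also carries a *provenance* list: ordered half-open intervals into
nodes of the original input graph whose concatenation spells the node's
sequence.  Provenance is what allows alignments against transformed nodes to
be traced back onto the input graph.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

VALID_BASES = frozenset("ACGTN")


class GraphError(ValueError):
    """Raised on structural errors in graph construction or I/O."""


# ---------------------------------------------------------------------------
# provenance


@dataclass(frozen=True)
class ProvenanceSegment:
    """Half-open interval ``[start, end)`` into original node ``origin``."""

    origin: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GraphError(
                f"invalid provenance interval {self.origin}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.origin}:{self.start}-{self.end}"


def prov_length(segments: Sequence[ProvenanceSegment]) -> int:
    return sum(len(s) for s in segments)


def prov_prefix(
    segments: Sequence[ProvenanceSegment], n: int
) -> Tuple[ProvenanceSegment, ...]:
    """First ``n`` bases of a provenance list, splitting the boundary segment."""
    if n < 0 or n > prov_length(segments):
        raise GraphError(f"cannot take {n}-base prefix of {prov_length(segments)}-base provenance")
    out: List[ProvenanceSegment] = []
    left = n
    for seg in segments:
        if left == 0:
            break
        take = min(left, len(seg))
        out.append(ProvenanceSegment(seg.origin, seg.start, seg.start + take))
        left -= take
    return tuple(out)


def prov_suffix(
    segments: Sequence[ProvenanceSegment], n: int
) -> Tuple[ProvenanceSegment, ...]:
    """Last ``n`` bases of a provenance list, splitting the boundary segment."""
    if n < 0 or n > prov_length(segments):
        raise GraphError(f"cannot take {n}-base suffix of {prov_length(segments)}-base provenance")
    out: List[ProvenanceSegment] = []
    left = n
    for seg in reversed(segments):
        if left == 0:
            break
        take = min(left, len(seg))
        out.append(ProvenanceSegment(seg.origin, seg.end - take, seg.end))
        left -= take
    out.reverse()
    return tuple(out)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Node:
    id: str
    seq: str
    provenance: Tuple[ProvenanceSegment, ...]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Edge:
    u: str
    v: str
    haplotypes: frozenset

    def key(self) -> Tuple[str, str]:
        return (self.u, self.v)


class HaplotypeRegistry:
    """Ordered set of haplotype identifiers."""

    def __init__(self, ids: Iterable[str] = ()) -> None:
        self._ids: List[str] = []
        self._set: Set[str] = set()
        for i in ids:
            self.add(i)

    def add(self, hap_id: str) -> None:
        if not hap_id:
            raise GraphError("empty haplotype id")
        if hap_id not in self._set:
            self._ids.append(hap_id)
            self._set.add(hap_id)

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(self._ids)

    def __contains__(self, hap_id: str) -> bool:
        return hap_id in self._set

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self._ids)

    def copy(self) -> "HaplotypeRegistry":
        return HaplotypeRegistry(self._ids)


class PopulationGraph:
    """Directed acyclic sequence graph with haplotype sets on edges."""

    def __init__(self, registry: Optional[HaplotypeRegistry] = None) -> None:
        self.nodes: Dict[str, Node] = {}
        self._succ: Dict[str, Dict[str, Set[str]]] = {}
        self._pred: Dict[str, Set[str]] = {}
        self.registry: HaplotypeRegistry = registry or HaplotypeRegistry()
        self.haplotype_paths: Dict[str, List[str]] = {}
        # haplotypes whose path begins/ends at a node that still has real
        # in/out edges behave like an extra (virtual) edge during the
        # transformation; maintained by the chopper, empty elsewhere
        self.virtual_starts: Dict[str, Set[str]] = {}
        self.virtual_ends: Dict[str, Set[str]] = {}

    # -- nodes --------------------------------------------------------------

    def add_node(
        self,
        node_id: str,
        seq: str,
        provenance: Optional[Sequence[ProvenanceSegment]] = None,
    ) -> Node:
        if node_id in self.nodes:
            raise GraphError(f"duplicate node id {node_id!r}")
        if not node_id or any(c.isspace() for c in node_id) or ";" in node_id:
            raise GraphError(f"invalid node id {node_id!r}")
        if not seq:
            raise GraphError(f"node {node_id!r} has empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise GraphError(f"node {node_id!r}: invalid characters {sorted(bad)}")
        if provenance is None:
            provenance = (ProvenanceSegment(node_id, 0, len(seq)),)
        provenance = tuple(provenance)
        if prov_length(provenance) != len(seq):
            raise GraphError(
                f"node {node_id!r}: provenance length {prov_length(provenance)} "
                f"!= sequence length {len(seq)}"
            )
        node = Node(node_id, seq, provenance)
        self.nodes[node_id] = node
        self._succ[node_id] = {}
        self._pred[node_id] = set()
        return node

    def remove_node(self, node_id: str) -> None:
        if node_id not in self.nodes:
            raise GraphError(f"unknown node {node_id!r}")
        for v in list(self._succ[node_id]):
            self.remove_edge(node_id, v)
        for u in list(self._pred[node_id]):
            self.remove_edge(u, node_id)
        del self.nodes[node_id]
        del self._succ[node_id]
        del self._pred[node_id]
        self.virtual_starts.pop(node_id, None)
        self.virtual_ends.pop(node_id, None)

    # -- edges --------------------------------------------------------------

    def add_edge(self, u: str, v: str, haplotypes: Iterable[str]) -> None:
        """Add (or union into) the edge ``(u, v)``.

        Duplicate edges on the same ordered pair union their haplotype sets:
        the edge set is a set of ordered pairs.
        """
        if u not in self.nodes or v not in self.nodes:
            raise GraphError(f"edge ({u!r},{v!r}) references unknown node")
        if u == v:
            raise GraphError(f"self loop on {u!r}")
        haps = set(haplotypes)
        if not haps:
            raise GraphError(f"empty haplotype set on ({u},{v})")
        if v in self._succ[u]:
            self._succ[u][v] |= haps
        else:
            self._succ[u][v] = haps
            self._pred[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        if not self.has_edge(u, v):
            raise GraphError(f"unknown edge ({u},{v})")
        del self._succ[u][v]
        self._pred[v].discard(u)

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._succ and v in self._succ[u]

    def edge_haplotypes(self, u: str, v: str) -> frozenset:
        if not self.has_edge(u, v):
            raise GraphError(f"unknown edge ({u},{v})")
        return frozenset(self._succ[u][v])

    def edges(self) -> Iterator[Edge]:
        for u, targets in self._succ.items():
            for v, haps in targets.items():
                yield Edge(u, v, frozenset(haps))

    def edge_keys(self) -> List[Tuple[str, str]]:
        """All edges as sorted ``(u, v)`` pairs (deterministic iteration aid)."""
        return sorted((u, v) for u, ts in self._succ.items() for v in ts)

    def successors(self, u: str) -> List[str]:
        return sorted(self._succ[u])

    def predecessors(self, v: str) -> List[str]:
        return sorted(self._pred[v])

    def in_degree(self, v: str) -> int:
        return len(self._pred[v])

    def out_degree(self, u: str) -> int:
        return len(self._succ[u])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self._succ.values())

    # -- whole-graph operations ----------------------------------------------

    def copy(self) -> "PopulationGraph":
        g = PopulationGraph(self.registry.copy())
        for node in self.nodes.values():
            g.add_node(node.id, node.seq, node.provenance)
        for edge in self.edges():
            g.add_edge(edge.u, edge.v, edge.haplotypes)
        g.haplotype_paths = {h: list(p) for h, p in self.haplotype_paths.items()}
        g.virtual_starts = {n: set(s) for n, s in self.virtual_starts.items()}
        g.virtual_ends = {n: set(s) for n, s in self.virtual_ends.items()}
        return g

    def init_virtual_endpoints(self) -> None:
        """Mark where each haplotype path begins and ends (from stored paths)."""
        self.virtual_starts = {}
        self.virtual_ends = {}
        for hap, path in self.haplotype_paths.items():
            if path:
                self.virtual_starts.setdefault(path[0], set()).add(hap)
                self.virtual_ends.setdefault(path[-1], set()).add(hap)

    def topological_order(self) -> List[str]:
        """Stable topological order (Kahn's algorithm, ties by node id)."""
        indeg = {n: self.in_degree(n) for n in self.nodes}
        heap = [n for n, d in indeg.items() if d == 0]
        heapq.heapify(heap)
        order: List[str] = []
        while heap:
            n = heapq.heappop(heap)
            order.append(n)
            for m in self._succ[n]:
                indeg[m] -= 1
                if indeg[m] == 0:
                    heapq.heappush(heap, m)
        if len(order) != len(self.nodes):
            rest = sorted(set(self.nodes) - set(order))
            raise GraphError(f"cycle detected involving nodes {rest[:5]}")
        return order

    def derive_edges_from_paths(self) -> None:
        """Recompute all edge haplotype sets from the stored haplotype paths."""
        self._succ = {n: {} for n in self.nodes}
        self._pred = {n: set() for n in self.nodes}
        for hap, path in self.haplotype_paths.items():
            for a, b in zip(path, path[1:]):
                self.add_edge(a, b, {hap})

    # -- haplotype spelling ---------------------------------------------------

    def spell_haplotype(self, hap: str) -> str:
        if hap not in self.haplotype_paths:
            raise GraphError(f"unknown haplotype {hap!r}")
        return "".join(self.nodes[n].seq for n in self.haplotype_paths[hap])

    def haplotype_kmers(self, k: int) -> Set[str]:
        """All length-k substrings over all haplotype spellings.

        Haplotypes shorter than k contribute their full spelling.
        """
        if k < 1:
            raise GraphError(f"k must be >= 1, got {k}")
        out: Set[str] = set()
        for hap in self.haplotype_paths:
            s = self.spell_haplotype(hap)
            if len(s) < k:
                out.add(s)
            else:
                out.update(sequence_windows(s, k))
        return out


def sequence_windows(seq: str, k: int) -> Set[str]:
    """The set of length-k windows of ``seq`` (empty if shorter than k)."""
    if k < 1:
        raise GraphError(f"k must be >= 1, got {k}")
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def is_null(graph: PopulationGraph) -> bool:
    return graph.n_edges == 0


# ---------------------------------------------------------------------------
# validation


def validate(graph: PopulationGraph) -> List[str]:
    """Check every PopulationGraph invariant; return human-readable violations."""
    out: List[str] = []
    for node in graph.nodes.values():
        if not node.seq:
            out.append(f"empty sequence on node {node.id}")
        bad = set(node.seq) - VALID_BASES
        if bad:
            out.append(f"invalid characters {sorted(bad)} on node {node.id}")
        if prov_length(node.provenance) != len(node.seq):
            out.append(
                f"provenance length {prov_length(node.provenance)} != "
                f"sequence length {len(node.seq)} on node {node.id}"
            )
    for edge in graph.edges():
        if not edge.haplotypes:
            out.append(f"empty haplotype set on ({edge.u},{edge.v})")
        unknown = set(edge.haplotypes) - set(graph.registry.ids)
        if unknown:
            out.append(f"unregistered haplotypes {sorted(unknown)} on ({edge.u},{edge.v})")
    try:
        graph.topological_order()
    except GraphError as exc:
        out.append(str(exc))
        return out  # path checks below assume a DAG
    derived: Dict[Tuple[str, str], Set[str]] = {}
    for hap, path in graph.haplotype_paths.items():
        if hap not in graph.registry:
            out.append(f"path for unregistered haplotype {hap!r}")
        if not path:
            out.append(f"empty path for haplotype {hap!r}")
            continue
        for n in path:
            if n not in graph.nodes:
                out.append(f"haplotype {hap!r} path references unknown node {n!r}")
        for a, b in zip(path, path[1:]):
            if not graph.has_edge(a, b):
                out.append(f"haplotype {hap!r} path uses missing edge ({a},{b})")
            elif hap not in graph.edge_haplotypes(a, b):
                out.append(f"haplotype {hap!r} missing from edge set of ({a},{b})")
            derived.setdefault((a, b), set()).add(hap)
    if graph.haplotype_paths:
        for edge in graph.edges():
            got = derived.get((edge.u, edge.v), set())
            if got != set(edge.haplotypes):
                out.append(
                    f"edge ({edge.u},{edge.v}) haplotype set {sorted(edge.haplotypes)} "
                    f"!= path-derived set {sorted(got)}"
                )
    return out


# ---------------------------------------------------------------------------
# GFA1 I/O
#
# Dialect: S lines with explicit sequences, L lines with 0M overlap only,
# forward ("+") orientations only, P lines naming haplotype paths.  Every
# L line must be covered by at least one P line unless ``allow_uncovered``
# assigns the synthetic "unknown" haplotype.

UNKNOWN_HAPLOTYPE = "unknown"


def write_gfa(graph: PopulationGraph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(graph.nodes):
            fh.write(f"S\t{nid}\t{graph.nodes[nid].seq}\n")
        for u, v in graph.edge_keys():
            fh.write(f"L\t{u}\t+\t{v}\t+\t0M\n")
        for hap in graph.registry:
            if hap in graph.haplotype_paths:
                members = ",".join(f"{n}+" for n in graph.haplotype_paths[hap])
                fh.write(f"P\t{hap}\t{members}\t*\n")


def read_gfa(path: str, allow_uncovered: bool = False) -> PopulationGraph:
    """Parse a GFA1 file into a PopulationGraph.

    Edge haplotype sets are reconstructed from P lines.  L lines covered by
    no P line are an error unless ``allow_uncovered`` is set, in which case
    they receive the synthetic ``unknown`` haplotype (the resulting graph
    will not pass strict path/edge consistency validation).
    """
    seqs: Dict[str, str] = {}
    links: List[Tuple[str, str]] = []
    paths: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("H", "#")):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3 or not fields[2] or fields[2] == "*":
                    raise GraphError(f"{path}:{lineno}: S line without explicit sequence")
                if fields[1] in seqs:
                    raise GraphError(f"{path}:{lineno}: duplicate segment {fields[1]!r}")
                seqs[fields[1]] = fields[2]
            elif tag == "L":
                if len(fields) < 6:
                    raise GraphError(f"{path}:{lineno}: malformed L line")
                u, uo, v, vo, overlap = fields[1:6]
                if uo != "+" or vo != "+":
                    raise GraphError(
                        f"{path}:{lineno}: reverse orientation not supported"
                    )
                if overlap not in ("0M", "*"):
                    raise GraphError(f"{path}:{lineno}: only 0M overlaps supported")
                links.append((u, v))
            elif tag == "P":
                if len(fields) < 3:
                    raise GraphError(f"{path}:{lineno}: malformed P line")
                name, members = fields[1], fields[2]
                if len(fields) >= 4 and fields[3] not in ("*",) and set(
                    fields[3].replace(",", "")
                ) - set("0M"):
                    raise GraphError(f"{path}:{lineno}: only 0M path overlaps supported")
                nodes = []
                for m in members.split(","):
                    if not m.endswith("+"):
                        raise GraphError(
                            f"{path}:{lineno}: reverse orientation not supported in path {name!r}"
                        )
                    nodes.append(m[:-1])
                paths[name] = nodes
            else:
                raise GraphError(f"{path}:{lineno}: unsupported record type {tag!r}")
    graph = PopulationGraph(HaplotypeRegistry(paths))
    for nid in seqs:
        graph.add_node(nid, seqs[nid])
    for name, nodes in paths.items():
        for n in nodes:
            if n not in graph.nodes:
                raise GraphError(f"path {name!r} references missing segment {n!r}")
    covered: Dict[Tuple[str, str], Set[str]] = {}
    for name, nodes in paths.items():
        for a, b in zip(nodes, nodes[1:]):
            covered.setdefault((a, b), set()).add(name)
    link_set = set(links)
    for key in covered:
        if key not in link_set:
            raise GraphError(f"path edge ({key[0]},{key[1]}) has no matching L line")
    uncovered = sorted(k for k in link_set if k not in covered)
    if uncovered and not allow_uncovered:
        raise GraphError(
            "L lines covered by no P line: "
            + ", ".join(f"({u},{v})" for u, v in uncovered)
        )
    for u, v in link_set:
        if u not in graph.nodes or v not in graph.nodes:
            raise GraphError(f"L line references missing segment in ({u},{v})")
        haps = covered.get((u, v))
        if haps is None:
            graph.registry.add(UNKNOWN_HAPLOTYPE)
            haps = {UNKNOWN_HAPLOTYPE}
        graph.add_edge(u, v, haps)
    graph.haplotype_paths = paths
    graph.topological_order()  # raises on cycles
    return graph
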