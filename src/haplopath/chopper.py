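"""Collapse / extend / duplicate operations and the null-graph scheduler.

The transformation removes every edge of a haplotype-annotated DAG while
guaranteeing that every length-k substring of every encoded haplotype ends up
as a substring of some surviving node, and that every k-window of every
surviving node is a genuine haplotype substring (no recombinant sequence is
ever emitted).

Three local operations drive this:

* ``collapse_edge``   -- merge ``u`` and ``v`` across an edge with
  ``out(u) == 1`` and ``in(v) == 1`` (a redundant traversal).
* ``extend_edge``     -- copy a (k-1)-length flank across an edge so the edge
  can be deleted without losing any spanning k-mer; legal as a prefix when
  ``in(v) == 1`` and ``|u| >= k-1``, as a suffix when ``out(u) == 1`` and
  ``|v| >= k-1``.
* ``duplicate_node``  -- split a node into copies, one per haplotype-supported
  (in-edge, out-edge) pair, so blocked edges become collapsible.  The
  haplotype constraint bounds the copy count by the number of haplotypes
  rather than in(u) * out(u).

The scheduler applies collapse, then extend, to a joint fixpoint, then
duplicates exactly one candidate node, and repeats until no edges remain.
That priority order is fixed to make the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .graphcore import (
    GraphError,
    PopulationGraph,
    prov_prefix,
    prov_suffix,
)


class ChopError(ValueError):
    """Raised on precondition violations or scheduler failure."""


@dataclass(frozen=True)
class ChopParams:
    """Target substring length (bp); reads up to this length stay alignable."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ChopError(f"k must be >= 2, got {self.k}")


# ---------------------------------------------------------------------------
# path bookkeeping
#
# Haplotype paths stay meaningful under collapse and duplicate (spellings are
# preserved) but not under extend, which intentionally duplicates flank
# sequence.  The first extension therefore clears the stored paths.


def _invalidate_paths(graph: PopulationGraph) -> None:
    graph.haplotype_paths = {}


def _starts(graph: PopulationGraph, n: str) -> Set[str]:
    return graph.virtual_starts.get(n, set())


def _ends(graph: PopulationGraph, n: str) -> Set[str]:
    return graph.virtual_ends.get(n, set())


# ---------------------------------------------------------------------------
# collapse


def collapse_edge(graph: PopulationGraph, u: str, v: str) -> str:
    """Collapse edge ``(u, v)``; returns the surviving node id.

    Requires ``out(u) == 1`` and ``in(v) == 1``.  The merged node spells
    ``u.seq + v.seq`` with concatenated provenance and absorbs both nodes'
    remaining edges with haplotype sets unchanged.  The collapse direction
    (v into u when ``in(u) > out(v)``, else u into v) only decides which
    endpoint's adjacency is rewritten -- an efficiency concern; the merged
    node itself always takes the lexicographically smaller of the two ids.
    """
    if not graph.has_edge(u, v):
        raise ChopError(f"unknown edge ({u},{v})")
    if graph.out_degree(u) != 1 or graph.in_degree(v) != 1:
        raise ChopError(
            f"({u},{v}) not collapsible: out({u})={graph.out_degree(u)}, "
            f"in({v})={graph.in_degree(v)}"
        )
    if _ends(graph, u) or _starts(graph, v):
        # a haplotype terminating at u (or starting at v) is a virtual edge:
        # merging across it would weld together contexts of different
        # haplotypes; the node must be duplicated instead
        raise ChopError(
            f"({u},{v}) not collapsible: haplotype path endpoint at the junction"
        )
    nu, nv = graph.nodes[u], graph.nodes[v]
    new_id = min(u, v)
    seq = nu.seq + nv.seq
    provenance = nu.provenance + nv.provenance
    in_edges = [(p, graph.edge_haplotypes(p, u)) for p in graph.predecessors(u)]
    out_edges = [(w, graph.edge_haplotypes(v, w)) for w in graph.successors(v)]
    starts = set(_starts(graph, u))  # ends(u) and starts(v) are empty (precondition)
    ends = set(_ends(graph, v))

    new_paths: Optional[Dict[str, List[str]]] = {}
    for hap, path in graph.haplotype_paths.items():
        if u in path:
            i = path.index(u)
            if i + 1 < len(path) and path[i + 1] == v:
                path = path[:i] + [new_id] + path[i + 2 :]
            else:
                new_paths = None  # path ends at u: spelling not preservable
                break
        elif v in path:
            new_paths = None  # path begins at v mid-edge
            break
        if new_paths is not None:
            new_paths[hap] = list(path)

    graph.remove_node(u)
    graph.remove_node(v)
    graph.add_node(new_id, seq, provenance)
    for p, haps in in_edges:
        graph.add_edge(p, new_id, haps)
    for w, haps in out_edges:
        graph.add_edge(new_id, w, haps)
    if starts:
        graph.virtual_starts[new_id] = starts
    if ends:
        graph.virtual_ends[new_id] = ends
    if graph.haplotype_paths:
        if new_paths is None:
            _invalidate_paths(graph)
        else:
            graph.haplotype_paths = new_paths
    return new_id


# ---------------------------------------------------------------------------
# extend


def extend_edge(graph: PopulationGraph, u: str, v: str, params: ChopParams) -> str:
    """Resolve edge ``(u, v)`` by copying a (k-1)-length flank across it.

    Returns ``"prefix"`` (flank of u prepended to v) or ``"suffix"`` (flank of
    v appended to u).  When both directions are legal the prefix direction is
    applied; either covers the same k-length substrings.  Raises
    :class:`ChopError` when neither direction is permitted (the caller must
    duplicate a neighbouring node first).
    """
    k = params.k
    if not graph.has_edge(u, v):
        raise ChopError(f"unknown edge ({u},{v})")
    nu, nv = graph.nodes[u], graph.nodes[v]
    can_prefix = (
        graph.in_degree(v) == 1 and not _starts(graph, v) and len(nu.seq) >= k - 1
    )
    can_suffix = (
        graph.out_degree(u) == 1 and not _ends(graph, u) and len(nv.seq) >= k - 1
    )
    if not can_prefix and not can_suffix:
        raise ChopError(
            f"extension blocked on ({u},{v}): in({v})={graph.in_degree(v)}, "
            f"out({u})={graph.out_degree(u)}, |{u}|={len(nu.seq)}, |{v}|={len(nv.seq)}"
        )
    if can_prefix:
        nv.seq = nu.seq[len(nu.seq) - (k - 1) :] + nv.seq
        nv.provenance = prov_suffix(nu.provenance, k - 1) + nv.provenance
        direction = "prefix"
    else:
        nu.seq = nu.seq + nv.seq[: k - 1]
        nu.provenance = nu.provenance + prov_prefix(nv.provenance, k - 1)
        direction = "suffix"
    graph.remove_edge(u, v)
    _invalidate_paths(graph)
    return direction


# ---------------------------------------------------------------------------
# duplicate


def supported_pairs(
    graph: PopulationGraph, u: str
) -> List[Tuple[str, str, FrozenSet[str]]]:
    """Haplotype-supported (in-edge, out-edge) pairs through ``u``.

    Returns ``(predecessor, successor, shared haplotypes)`` for every pair of
    an incoming and an outgoing edge whose haplotype sets intersect, in
    (predecessor, successor) lexicographic order.
    """
    if u not in graph.nodes:
        raise ChopError(f"unknown node {u!r}")
    pairs: List[Tuple[str, str, FrozenSet[str]]] = []
    for p in graph.predecessors(u):
        in_haps = graph.edge_haplotypes(p, u)
        for w in graph.successors(u):
            shared = in_haps & graph.edge_haplotypes(u, w)
            if shared:
                pairs.append((p, w, frozenset(shared)))
    return pairs


def delta(graph: PopulationGraph, u: str) -> int:
    """Number of haplotype-supported in/out edge pairs through ``u``."""
    return len(supported_pairs(graph, u))


def _fresh_copy_id(graph: PopulationGraph, base: str, idx: int) -> Tuple[str, int]:
    while f"{base}.{idx}" in graph.nodes:
        idx += 1
    return f"{base}.{idx}", idx


def duplicate_node(graph: PopulationGraph, u: str) -> List[str]:
    """Split ``u`` into haplotype-constrained copies; returns new node ids.

    One copy is created per supported (in-edge, out-edge) pair, receiving
    exactly that pair's edges with the pair's shared haplotype set.  In-edges
    carrying haplotypes that do not continue through any out-edge get a
    terminal copy holding just that in-edge (and symmetrically for haplotypes
    that originate at ``u``).  Copies inherit sequence and provenance
    verbatim; ``u`` is removed.  Total copies never exceed the number of
    haplotypes routed through ``u``.
    """
    if u not in graph.nodes:
        raise ChopError(f"unknown node {u!r}")
    if graph.in_degree(u) == 0 and graph.out_degree(u) == 0:
        raise ChopError(f"node {u!r} has no incident edges to duplicate over")
    node = graph.nodes[u]
    pairs = supported_pairs(graph, u)

    in_edges = {p: graph.edge_haplotypes(p, u) for p in graph.predecessors(u)}
    out_edges = {w: graph.edge_haplotypes(u, w) for w in graph.successors(u)}
    in_used: Dict[str, Set[str]] = {p: set() for p in in_edges}
    out_used: Dict[str, Set[str]] = {w: set() for w in out_edges}
    for p, w, shared in pairs:
        in_used[p] |= shared
        out_used[w] |= shared

    # (kind, in-edge spec, out-edge spec) in deterministic order
    plans: List[Tuple[Optional[Tuple[str, FrozenSet[str]]], Optional[Tuple[str, FrozenSet[str]]]]] = []
    for p, w, shared in pairs:
        plans.append(((p, shared), (w, shared)))
    terminal_of: Dict[str, int] = {}
    for p in sorted(in_edges):
        rest = frozenset(in_edges[p] - in_used[p])
        if rest:
            terminal_of[p] = len(plans)
            plans.append(((p, rest), None))
    origin_of: Dict[str, int] = {}
    for w in sorted(out_edges):
        rest = frozenset(out_edges[w] - out_used[w])
        if rest:
            origin_of[w] = len(plans)
            plans.append((None, (w, rest)))

    pair_index: Dict[Tuple[str, str], List[int]] = {}
    for i, (p, w, _) in enumerate(pairs):
        pair_index.setdefault((p, w), []).append(i)

    # rewrite haplotype paths before mutating the graph
    new_paths: Optional[Dict[str, List[str]]] = None
    bare_needed = False
    if graph.haplotype_paths:
        new_paths = {}
        plan_for_hap: Dict[str, int] = {}
        for hap, path in graph.haplotype_paths.items():
            if u not in path:
                new_paths[hap] = list(path)
                continue
            i = path.index(u)
            pred = path[i - 1] if i > 0 else None
            succ = path[i + 1] if i + 1 < len(path) else None
            idx: Optional[int] = None
            if pred is not None and succ is not None:
                for j in pair_index.get((pred, succ), []):
                    if hap in pairs[j][2]:
                        idx = j
                        break
            elif pred is not None:
                j = terminal_of.get(pred)
                if j is not None and hap in plans[j][0][1]:
                    idx = j
            elif succ is not None:
                j = origin_of.get(succ)
                if j is not None and hap in plans[j][1][1]:
                    idx = j
            else:
                bare_needed = True
                idx = -1  # single-node path: bare copy, resolved below
            if idx is None:
                raise ChopError(
                    f"haplotype {hap!r} path through {u!r} is not edge-supported"
                )
            plan_for_hap[hap] = idx

    copy_ids: List[str] = []
    next_idx = 0
    for in_spec, out_spec in plans:
        cid, next_idx = _fresh_copy_id(graph, u, next_idx)
        next_idx += 1
        copy_ids.append(cid)
    bare_id: Optional[str] = None
    if bare_needed:
        bare_id, _ = _fresh_copy_id(graph, u, next_idx)

    graph.remove_node(u)
    for cid, (in_spec, out_spec) in zip(copy_ids, plans):
        graph.add_node(cid, node.seq, node.provenance)
        if in_spec is not None:
            graph.add_edge(in_spec[0], cid, in_spec[1])
        if out_spec is not None:
            graph.add_edge(cid, out_spec[0], out_spec[1])
    if bare_id is not None:
        graph.add_node(bare_id, node.seq, node.provenance)
        copy_ids.append(bare_id)

    if new_paths is not None:
        for hap, idx in plan_for_hap.items():
            target = bare_id if idx == -1 else copy_ids[idx]
            path = list(graph.haplotype_paths[hap])
            path[path.index(u)] = target
            new_paths[hap] = path
        graph.haplotype_paths = new_paths
    return copy_ids


# ---------------------------------------------------------------------------
# scheduler


def _ein(graph: PopulationGraph, v: str) -> int:
    """In-degree counting a mid-graph haplotype start as a virtual edge."""
    return graph.in_degree(v) + (1 if _starts(graph, v) else 0)


def _eout(graph: PopulationGraph, u: str) -> int:
    return graph.out_degree(u) + (1 if _ends(graph, u) else 0)


def _collapsible(graph: PopulationGraph, u: str, v: str) -> bool:
    return (
        graph.out_degree(u) == 1
        and graph.in_degree(v) == 1
        and not _ends(graph, u)
        and not _starts(graph, v)
    )


def _extendible(graph: PopulationGraph, u: str, v: str, k: int) -> bool:
    can_prefix = (
        graph.in_degree(v) == 1 and not _starts(graph, v) and len(graph.nodes[u].seq) >= k - 1
    )
    can_suffix = (
        graph.out_degree(u) == 1 and not _ends(graph, u) and len(graph.nodes[v].seq) >= k - 1
    )
    return can_prefix or can_suffix


def _duplication_candidate(graph: PopulationGraph) -> str:
    """Earliest node in stable topological order with a splittable degree.

    At a collapse/extend fixpoint every remaining edge is blocked, and every
    blocked edge has an endpoint with effective in > 1 or out > 1 (virtual
    path-endpoint edges included), so a candidate always exists while edges
    remain.  Nodes without real incident edges are never candidates.
    """
    for nid in graph.topological_order():
        if graph.in_degree(nid) + graph.out_degree(nid) == 0:
            continue
        if _ein(graph, nid) > 1 or _eout(graph, nid) > 1:
            return nid
    raise ChopError("edges remain but no duplication candidate exists")


def chop(
    graph: PopulationGraph,
    params: ChopParams,
    trace: Optional[List[dict]] = None,
) -> PopulationGraph:
    """Transform ``graph`` into its edge-free (null) equivalent.

    The result's nodes jointly contain every length-k substring of every
    encoded haplotype, and nothing else: the k-window set of the output
    equals ``graph.haplotype_kmers(k)``.  Node provenance maps each output
    sequence onto a path of the input graph.  The run is deterministic.

    ``trace``, when given, collects one dict per applied operation
    (op, target, and for duplications the copy count).
    """
    k = params.k
    g = graph.copy()
    g.topological_order()  # raises "cycle detected" on cyclic input
    g.init_virtual_endpoints()
    # haplotypes spelling fewer than k bases have no k-mer; their full
    # spelling is retained as a dedicated node at the end
    short_specs: List[Tuple[str, tuple]] = []
    seen_short: Set[str] = set()
    for hap in g.registry:
        path = g.haplotype_paths.get(hap)
        if not path:
            continue
        s = g.spell_haplotype(hap)
        if len(s) < k and s not in seen_short:
            seen_short.add(s)
            prov: Tuple = ()
            for nid in path:
                prov = prov + g.nodes[nid].provenance
            short_specs.append((s, prov))
    limit = 40 * (g.n_nodes + g.n_edges + 1) * max(len(g.registry), 1) + 1000
    steps = 0
    while g.n_edges:
        changed = True
        while changed:
            changed = False
            # collapse to fixpoint
            collapsing = True
            while collapsing:
                collapsing = False
                for u, v in g.edge_keys():
                    if g.has_edge(u, v) and _collapsible(g, u, v):
                        survivor = collapse_edge(g, u, v)
                        if trace is not None:
                            trace.append({"op": "collapse", "edge": (u, v), "node": survivor})
                        collapsing = changed = True
                        steps += 1
            # one extension pass; any enabled collapses run next loop round
            for u, v in g.edge_keys():
                if not g.has_edge(u, v) or _collapsible(g, u, v):
                    continue
                if _extendible(g, u, v, k):
                    direction = extend_edge(g, u, v, params)
                    if trace is not None:
                        trace.append({"op": "extend", "edge": (u, v), "direction": direction})
                    changed = True
                    steps += 1
        if g.n_edges:
            cand = _duplication_candidate(g)
            copies = duplicate_node(g, cand)
            if trace is not None:
                trace.append({"op": "duplicate", "node": cand, "copies": len(copies)})
            steps += 1
        if steps > limit:
            raise ChopError("scheduler failed to converge (operation limit reached)")
    # nodes left shorter than k are stubs whose sequence was fully exported
    # as a flank (extension requires |flank donor| >= k-1); they carry no
    # k-window and are dropped
    for nid in sorted(g.nodes):
        if len(g.nodes[nid].seq) < k:
            g.remove_node(nid)
    existing = {node.seq for node in g.nodes.values()}
    idx = 0
    for s, prov in short_specs:
        if s in existing:
            continue
        while f"short.{idx}" in g.nodes:
            idx += 1
        g.add_node(f"short.{idx}", s, prov)
        idx += 1
    g.haplotype_paths = {}
    g.virtual_starts = {}
    g.virtual_ends = {}
    return g
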