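"""Shared fixtures and independent oracles.

The oracle helpers here deliberately avoid the package's own spelling /
k-mer machinery where they are used to check it: spellings are concatenated
from path node sequences directly, window sets are built by brute-force
string slicing, and truth haplotypes come from the string-editing simulator.
"""

from __future__ import annotations

import random
from typing import Dict, List, Set

import pytest

from haplopath.graphcore import HaplotypeRegistry, PopulationGraph
from haplopath.popsim import SimConfig, simulate_population
from haplopath.vcf2graph import build_graph


# ---------------------------------------------------------------------------
# independent oracles


def oracle_spellings(graph: PopulationGraph) -> Dict[str, str]:
    """Spell every haplotype by direct path concatenation."""
    return {
        hap: "".join(graph.nodes[n].seq for n in path)
        for hap, path in graph.haplotype_paths.items()
    }


def oracle_kmers(spellings: Dict[str, str], k: int) -> Set[str]:
    """Brute-force k-mer set over spelled strings (full string if shorter)."""
    out: Set[str] = set()
    for s in spellings.values():
        if len(s) < k:
            out.add(s)
        else:
            out.update(s[i : i + k] for i in range(len(s) - k + 1))
    return out


def null_windows(null: PopulationGraph, k: int) -> Set[str]:
    """k-window set of a null graph's nodes (full sequence if shorter)."""
    out: Set[str] = set()
    for node in null.nodes.values():
        if len(node.seq) < k:
            out.add(node.seq)
        out.update(node.seq[i : i + k] for i in range(len(node.seq) - k + 1))
    return out


# ---------------------------------------------------------------------------
# graph generators


def random_dag_graph(
    rng: random.Random,
    n_nodes: int = 8,
    n_haps: int = 4,
    max_len: int = 5,
) -> PopulationGraph:
    """Random haplotyped DAG with possibly partial (mid-graph) paths.

    Paths are sorted random node subsets under one global order, so edges
    derived from them always form a DAG and stay path-consistent.
    """
    ids = [f"n{i:02d}" for i in range(n_nodes)]
    g = PopulationGraph(HaplotypeRegistry([f"h{j}" for j in range(n_haps)]))
    seqs = {
        i: "".join(rng.choice("ACGT") for _ in range(rng.randint(1, max_len)))
        for i in ids
    }
    paths = {
        f"h{j}": sorted(rng.sample(ids, rng.randint(1, n_nodes)))
        for j in range(n_haps)
    }
    used = {n for p in paths.values() for n in p}
    for i in sorted(used):
        g.add_node(i, seqs[i])
    g.haplotype_paths = paths
    g.derive_edges_from_paths()
    return g


def population_graph(seed: int, **overrides) -> tuple:
    """(Population, PopulationGraph) for a seeded simulated population."""
    cfg = SimConfig(**{"seed": seed, **overrides})
    pop = simulate_population(cfg)
    graph = build_graph(pop.reference, pop.records, pop.sample_names, contig=cfg.contig)
    return pop, graph


# ---------------------------------------------------------------------------
# small fixed graphs


@pytest.fixture
def two_node_graph() -> PopulationGraph:
    g = PopulationGraph(HaplotypeRegistry(["ref"]))
    g.add_node("A", "AC")
    g.add_node("B", "GT")
    g.haplotype_paths = {"ref": ["A", "B"]}
    g.derive_edges_from_paths()
    return g
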