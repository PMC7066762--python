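"""Small worked-example graphs used in tests, docs, and the acceptance report."""

from __future__ import annotations

from .graphcore import HaplotypeRegistry, PopulationGraph


def shared_junction_example() -> PopulationGraph:
    """A 3-in / 2-out junction whose haplotypes rule out most edge pairings.

    Node ``d`` has in-edges from u ({h1}), v ({h2}), w ({h3}) and out-edges to
    e ({h1,h2}) and f ({h3}).  Of the 6 possible in/out pairings only 3 are
    haplotype-supported, so duplicating ``d`` must yield exactly 3 copies.
    """
    g = PopulationGraph(HaplotypeRegistry(["h1", "h2", "h3"]))
    g.add_node("u", "ACGT")
    g.add_node("v", "TGCA")
    g.add_node("w", "GGCC")
    g.add_node("d", "TA")
    g.add_node("e", "CCGG")
    g.add_node("f", "ATAT")
    g.haplotype_paths = {
        "h1": ["u", "d", "e"],
        "h2": ["v", "d", "e"],
        "h3": ["w", "d", "f"],
    }
    g.derive_edges_from_paths()
    return g


def three_haplotype_example() -> PopulationGraph:
    """A 9-node graph encoding three haplotypes over two variant sites.

    Haplotypes I and II differ at the first site, II and III at the second;
    chopping at k=4 decomposes this into a 3-node null graph whose 4-windows
    are exactly the haplotypes' 4-mers.
    """
    g = PopulationGraph(HaplotypeRegistry(["I", "II", "III"]))
    g.add_node("1", "TTGA")
    g.add_node("2", "C")
    g.add_node("3", "G")
    g.add_node("4", "AT")
    g.add_node("5", "CG")
    g.add_node("6", "A")
    g.add_node("7", "T")
    g.add_node("8", "GGTC")
    g.haplotype_paths = {
        "I": ["1", "2", "4", "5", "8"],
        "II": ["1", "3", "4", "5", "8"],
        "III": ["1", "3", "4", "6", "7", "8"],
    }
    g.derive_edges_from_paths()
    return g
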