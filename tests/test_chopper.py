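import random

import pytest

from haplopath.chopper import (
    ChopError,
    ChopParams,
    chop,
    collapse_edge,
    delta,
    duplicate_node,
    extend_edge,
    supported_pairs,
)
from haplopath.examples import shared_junction_example, three_haplotype_example
from haplopath.graphcore import (
    HaplotypeRegistry,
    PopulationGraph,
    ProvenanceSegment,
    validate,
)

from conftest import (
    null_windows,
    oracle_kmers,
    oracle_spellings,
    population_graph,
    random_dag_graph,
)


class TestChopParams:
    def test_k_below_two_rejected(self):
        with pytest.raises(ChopError):
            ChopParams(1)


class TestCollapse:
    def test_chain_collapse(self, two_node_graph):
        survivor = collapse_edge(two_node_graph, "A", "B")
        assert survivor == "A"
        node = two_node_graph.nodes["A"]
        assert node.seq == "ACGT"
        assert node.provenance == (
            ProvenanceSegment("A", 0, 2),
            ProvenanceSegment("B", 0, 2),
        )
        assert two_node_graph.n_edges == 0
        assert two_node_graph.spell_haplotype("ref") == "ACGT"

    def test_precondition_error_names_degrees(self):
        g = shared_junction_example()
        with pytest.raises(ChopError, match=r"in\(d\)=3"):
            collapse_edge(g, "u", "d")

    def test_fig9_duplicate_then_collapse(self):
        # after duplication the three in-edges become collapsible and each
        # merged node spells the concatenated pair
        g = shared_junction_example()
        copies = duplicate_node(g, "d")
        merged = set()
        for pred, cid in zip(["u", "v", "w"], copies):
            assert g.has_edge(pred, cid)
            merged.add(g.nodes[collapse_edge(g, pred, cid)].seq)
        assert merged == {"ACGTTA", "TGCATA", "GGCCTA"}

    def test_exhaustive_collapse_preserves_spellings(self):
        for seed in range(10):
            pop, g = population_graph(
                seed, ref_len=600, n_samples=3, variants_per_sample=6
            )
            before = oracle_spellings(g)
            changed = True
            while changed:
                changed = False
                for u, v in g.edge_keys():
                    if (
                        g.has_edge(u, v)
                        and g.out_degree(u) == 1
                        and g.in_degree(v) == 1
                    ):
                        collapse_edge(g, u, v)
                        changed = True
            assert oracle_spellings(g) == before
            assert validate(g) == []


class TestExtend:
    def _fork_graph(self):
        # u("A") with out(u)=2; v("C") with in(v)=1
        g = PopulationGraph(HaplotypeRegistry(["h1", "h2"]))
        g.add_node("u", "A")
        g.add_node("v", "C")
        g.add_node("w", "G")
        g.add_node("z", "T")
        g.haplotype_paths = {"h1": ["u", "v", "z"], "h2": ["u", "w", "z"]}
        g.derive_edges_from_paths()
        return g

    def test_k2_prefix_flank(self):
        g = self._fork_graph()
        assert extend_edge(g, "u", "v", ChopParams(2)) == "prefix"
        node = g.nodes["v"]
        assert node.seq == "AC"
        assert node.provenance == (
            ProvenanceSegment("u", 0, 1),
            ProvenanceSegment("v", 0, 1),
        )
        assert not g.has_edge("u", "v")

    def test_prefix_flank_is_exactly_last_k_minus_1_characters(self):
        g = PopulationGraph(HaplotypeRegistry(["h1", "h2"]))
        g.add_node("u", "ACGTC")
        g.add_node("v", "TTT")
        g.add_node("w", "AAA")
        g.haplotype_paths = {"h1": ["u", "v"], "h2": ["u", "w"]}
        g.derive_edges_from_paths()
        assert extend_edge(g, "u", "v", ChopParams(4)) == "prefix"
        assert g.nodes["v"].seq == "GTC" + "TTT"

    def test_blocked_extension_raises(self):
        # the both-sides-forked junction: out(u)>1 and in(v)>1
        g = PopulationGraph(HaplotypeRegistry(["h1", "h2", "h3"]))
        g.add_node("u", "AAAA")
        g.add_node("v", "TTTT")
        g.add_node("w", "C")
        g.add_node("s", "GG")
        g.add_node("t", "GG")
        g.haplotype_paths = {
            "h1": ["s", "u", "v", "t"],
            "h2": ["s", "u", "w", "v", "t"],
            "h3": ["s", "u", "v", "t"],
        }
        g.derive_edges_from_paths()
        with pytest.raises(ChopError, match="extension blocked"):
            extend_edge(g, "u", "v", ChopParams(4))

    def test_junction_windows_covered_after_extension(self):
        rng = random.Random(8)
        g = random_dag_graph(rng, n_nodes=7, n_haps=2, max_len=6)
        k = 3
        spells = oracle_spellings(g)
        for u, v in g.edge_keys():
            if not g.has_edge(u, v):
                continue
            haps = g.edge_haplotypes(u, v)
            crossing = set()
            for hap in haps:
                path = g.haplotype_paths[hap]
                i = path.index(v)
                off = sum(len(g.nodes[n].seq) for n in path[:i])
                hi = off + len(g.nodes[v].seq)  # windows past v belong to the next edge
                s = spells[hap]
                for j in range(max(0, off - k + 1), min(off, len(s) - k) + 1):
                    if j < off < j + k and j + k <= hi:
                        crossing.add(s[j : j + k])
            try:
                extend_edge(g, u, v, ChopParams(k))
            except ChopError:
                continue
            covered = set()
            for n in (u, v):
                seq = g.nodes[n].seq
                covered.update(seq[i : i + k] for i in range(len(seq) - k + 1))
            assert crossing <= covered
            break


class TestSupportedPairsAndDelta:
    def test_fig9_configuration(self):
        g = shared_junction_example()
        pairs = supported_pairs(g, "d")
        assert pairs == [
            ("u", "e", frozenset({"h1"})),
            ("v", "e", frozenset({"h2"})),
            ("w", "f", frozenset({"h3"})),
        ]
        assert delta(g, "d") == 3
        assert g.in_degree("d") * g.out_degree("d") == 6

    def test_pass_through_node(self, two_node_graph):
        two_node_graph.add_node("C", "TT")
        two_node_graph.haplotype_paths["ref"].append("C")
        two_node_graph.derive_edges_from_paths()
        assert delta(two_node_graph, "B") == 1

    def test_delta_matches_path_traversal_oracle(self):
        for seed in range(30):
            g = random_dag_graph(random.Random(seed))
            for u in g.nodes:
                used = set()
                for hap, path in g.haplotype_paths.items():
                    if u in path:
                        i = path.index(u)
                        if 0 < i < len(path) - 1:
                            used.add((path[i - 1], path[i + 1]))
                assert delta(g, u) == len(used)


class TestDuplicate:
    def test_fig9_three_copies_not_six(self):
        g = shared_junction_example()
        copies = duplicate_node(g, "d")
        assert len(copies) == 3
        assert copies == ["d.0", "d.1", "d.2"]
        assert validate(g) == []

    def test_degenerate_duplication_is_isomorphic(self, two_node_graph):
        two_node_graph.add_node("C", "TT")
        two_node_graph.haplotype_paths["ref"].append("C")
        two_node_graph.derive_edges_from_paths()
        copies = duplicate_node(two_node_graph, "B")
        assert copies == ["B.0"]
        assert two_node_graph.spell_haplotype("ref") == "ACGTTT"
        assert two_node_graph.in_degree("B.0") == 1
        assert two_node_graph.out_degree("B.0") == 1

    def test_no_incident_edges_rejected(self):
        g = PopulationGraph(HaplotypeRegistry(["h"]))
        g.add_node("A", "ACGT")
        with pytest.raises(ChopError):
            duplicate_node(g, "A")

    def test_spelling_preserved_and_copy_bound(self):
        for seed in range(25):
            g = random_dag_graph(random.Random(seed))
            h = len(g.registry)
            before = oracle_spellings(g)
            candidates = [
                n
                for n in g.topological_order()
                if g.in_degree(n) + g.out_degree(n) >= 1
            ]
            if not candidates:
                continue
            target = candidates[len(candidates) // 2]
            copies = duplicate_node(g, target)
            assert 1 <= len(copies) <= h
            assert oracle_spellings(g) == before
            assert validate(g) == []


class TestChop:
    def test_already_null_graph_is_identity(self):
        g = PopulationGraph(HaplotypeRegistry(["h"]))
        g.add_node("A", "ACGTACGT")
        g.haplotype_paths = {"h": ["A"]}
        null = chop(g, ChopParams(4))
        assert set(null.nodes) == {"A"}
        assert null.nodes["A"].seq == "ACGTACGT"
        assert null.n_edges == 0

    def test_three_haplotype_example_decomposes_to_three_nodes(self):
        g = three_haplotype_example()
        null = chop(g, ChopParams(4))
        assert null.n_edges == 0
        assert null.n_nodes == 3
        assert null_windows(null, 4) == oracle_kmers(oracle_spellings(g), 4)

    def test_cycle_rejected(self):
        g = PopulationGraph(HaplotypeRegistry(["h"]))
        g.add_node("A", "AC")
        g.add_node("B", "GT")
        g.add_edge("A", "B", {"h"})
        g.add_edge("B", "A", {"h"})
        with pytest.raises(Exception, match="cycle"):
            chop(g, ChopParams(2))

    @pytest.mark.parametrize("k", [8, 16, 32])
    def test_kmer_set_equality_on_populations(self, k):
        for seed in range(5):
            pop, g = population_graph(
                seed, ref_len=2000, n_samples=5, variants_per_sample=20
            )
            null = chop(g, ChopParams(k))
            assert null_windows(null, k) == oracle_kmers(oracle_spellings(g), k)

    def test_termination_on_1000_random_graphs(self):
        for trial in range(1000):
            rng = random.Random(trial)
            g = random_dag_graph(
                rng,
                n_nodes=rng.randint(2, 10),
                n_haps=rng.randint(1, 5),
                max_len=rng.randint(1, 6),
            )
            k = rng.choice([2, 3, 4, 6, 9])
            null = chop(g, ChopParams(k))
            assert null.n_edges == 0
            assert null_windows(null, k) == oracle_kmers(oracle_spellings(g), k)

    def test_duplication_copy_bound_over_runs(self):
        for seed in range(10):
            pop, g = population_graph(
                seed, ref_len=800, n_samples=4, variants_per_sample=10
            )
            h = len(g.registry)
            trace = []
            chop(g, ChopParams(16), trace=trace)
            for ev in trace:
                if ev["op"] == "duplicate":
                    assert ev["copies"] <= h

    def test_provenance_maps_onto_input_graph_paths(self):
        pop, g = population_graph(2, ref_len=1000, n_samples=3, variants_per_sample=8)
        null = chop(g, ChopParams(16))
        for node in null.nodes.values():
            spelled = "".join(
                g.nodes[s.origin].seq[s.start : s.end] for s in node.provenance
            )
            assert spelled == node.seq
            for a, b in zip(node.provenance, node.provenance[1:]):
                if a.origin == b.origin:
                    assert a.end == b.start
                else:
                    assert a.end == len(g.nodes[a.origin].seq)
                    assert b.start == 0
                    assert g.has_edge(a.origin, b.origin)

    def test_min_node_length(self):
        pop, g = population_graph(4, ref_len=1000, n_samples=3, variants_per_sample=8)
        for k in (8, 32):
            null = chop(g, ChopParams(k))
            for node in null.nodes.values():
                assert len(node.seq) >= k

    def test_determinism_is_byte_identical(self, tmp_path):
        from haplopath.graphcore import write_gfa
        from haplopath.nullindex import write_fasta

        outputs = []
        for run in range(2):
            pop, g = population_graph(9, ref_len=1500, n_samples=4, variants_per_sample=12)
            null = chop(g, ChopParams(16))
            gfa = tmp_path / f"g{run}.gfa"
            fa = tmp_path / f"n{run}.fa"
            write_gfa(g, str(gfa))
            write_fasta(null, str(fa))
            outputs.append((gfa.read_bytes(), fa.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_short_haplotype_spelling_retained(self):
        g = PopulationGraph(HaplotypeRegistry(["long", "tiny"]))
        g.add_node("A", "ACGTAC")
        g.add_node("B", "GT")
        g.add_node("C", "TTAGGC")
        g.haplotype_paths = {"long": ["A", "B", "C"], "tiny": ["B"]}
        g.derive_edges_from_paths()
        null = chop(g, ChopParams(5))
        assert null_windows(null, 5) == oracle_kmers(oracle_spellings(g), 5)
        assert any(n.seq == "GT" for n in null.nodes.values())
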