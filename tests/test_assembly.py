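"""Partial assembly: DAG conversion, longest paths, bottleneck consumption."""

import random

import networkx as nx
import pytest

from peakforge.assembly import (
    assemble_component,
    distribute_and_consume,
    enumerate_paths_through,
    find_bottleneck,
    longest_path,
    reconstruct_sequence,
    to_dag,
)
from peakforge.graph import Component, DeBruijnGraph, weakly_connected_components

from conftest import chain_graph, graph_from_strings, random_dna


def all_paths_bruteforce(graph: DeBruijnGraph):
    """Every directed path in a DAG, by exhaustive DFS from every vertex."""
    g = graph.g
    paths = []

    def extend(path):
        paths.append(list(path))
        for w in g.successors(path[-1]):
            extend(path + [w])

    for v in g.nodes:
        extend([v])
    return paths


def path_key(graph: DeBruijnGraph, path):
    """(length, total abundance, sequence) with the assembly's tie rules."""
    return (
        len(reconstruct_sequence(path, graph)),
        sum(graph.vertex_total_abundance(v) for v in path),
        reconstruct_sequence(path, graph),
    )


def best_path_bruteforce(graph: DeBruijnGraph):
    paths = all_paths_bruteforce(graph)
    return max(paths, key=lambda p: (path_key(graph, p)[0], path_key(graph, p)[1],
                                     [-ord(c) for c in path_key(graph, p)[2]]))


def random_component(seed: int, max_kmers: int = 40) -> Component:
    """A bubble-free-ish random component built from short noisy strings."""
    rng = random.Random(seed)
    n = rng.randint(6, max_kmers // 2 + 6)
    strings = [(random_dna(rng, rng.randint(6, n + 5), "ACG"), rng.randint(1, 9))
               for _ in range(rng.randint(1, 3))]
    g = graph_from_strings(strings, 4)
    comps = weakly_connected_components(g)
    return comps[0] if comps else Component(0, g)


class TestToDag:
    def test_acyclic_chain_unchanged(self):
        g = graph_from_strings([("ACGTTGCA", 2)], 4)
        dag = to_dag(Component(0, g))
        assert dag.removed_edges == []
        assert nx.is_directed_acyclic_graph(dag.graph.g)

    def test_three_cycle_loses_one_edge(self):
        # ACGACGACG: k-mers ACG->CGA->GAC->ACG cycle at k=3
        g = graph_from_strings([("ACGACGA", 1)], 3)
        dag = to_dag(Component(0, g))
        assert len(dag.removed_edges) == 1
        assert nx.is_directed_acyclic_graph(dag.graph.g)

    def test_self_loop_always_cut(self):
        g = graph_from_strings([("AAAAAA", 3)], 4)
        dag = to_dag(Component(0, g))
        assert (next(iter(g.g.nodes)),) * 2 in [tuple(e) for e in dag.removed_edges]
        assert nx.is_directed_acyclic_graph(dag.graph.g)

    def test_random_graphs_become_acyclic(self):
        for seed in range(25):
            comp = random_component(seed)
            dag = to_dag(comp)
            assert nx.is_directed_acyclic_graph(dag.graph.g)
            # mass is never lost by edge cutting
            assert dag.graph.total_abundance() == comp.graph.total_abundance()


class TestLongestPath:
    def test_single_vertex(self):
        g, ids = chain_graph(["ACGTT"], [[4, 3]], 4)
        dag = to_dag(Component(0, g))
        assert longest_path(dag) == ids

    def test_diamond_prefers_longer_branch(self):
        g = DeBruijnGraph(4)
        a = g.add_vertex("TACG", [5])
        b = g.add_vertex("ACGTTT", [1, 1, 1])  # longer arm
        c = g.add_vertex("ACGT", [9])
        d = g.add_vertex("TTTA", [2])
        e = g.add_vertex("CGTA", [2])
        g.g.add_edge(a, b)
        g.g.add_edge(a, c)
        g.g.add_edge(b, d)
        g.g.add_edge(c, e)
        dag = to_dag(Component(0, g))
        path = longest_path(dag)
        assert path == [a, b, d]

    def test_agrees_with_bruteforce_on_random_dags(self):
        for seed in range(40):
            comp = random_component(seed + 100, max_kmers=24)
            dag = to_dag(comp)
            if len(dag.graph) > 12:
                continue
            ours = longest_path(dag)
            oracle = best_path_bruteforce(dag.graph)
            assert path_key(dag.graph, ours) == path_key(dag.graph, oracle)


class TestBottleneck:
    def test_argmin_and_tie_rules(self):
        g, ids = chain_graph(["AACG", "ACGT", "CGTT"], [[5], [3], [7]], 4)
        v, a = find_bottleneck(ids, g)
        assert (v, a) == (ids[1], 3)
        g2, ids2 = chain_graph(["AACG", "ACGT"], [[4], [4]], 4)
        assert find_bottleneck(ids2, g2) == (ids2[0], 4)

    def test_unitig_min_over_constituents(self):
        g, ids = chain_graph(["ACGTTG"], [[4, 2, 9]], 4)
        assert find_bottleneck(ids, g) == (ids[0], 2)


class TestEnumerate:
    @staticmethod
    def cross(k=4, abund=3):
        """Two prefixes and two suffixes around a central bottleneck."""
        g = DeBruijnGraph(k)
        m = g.add_vertex("ACGT", [abund])
        a = g.add_vertex("TACG", [5])
        b = g.add_vertex("CACG", [6])
        c = g.add_vertex("CGTA", [5])
        d = g.add_vertex("CGTC", [7])
        for u in (a, b):
            g.g.add_edge(u, m)
        for w in (c, d):
            g.g.add_edge(m, w)
        return g, m

    def test_unique_chain_single_path(self):
        g, ids = chain_graph(["AACG", "ACGT", "CGTT"], [[5], [3], [7]], 4)
        dag = to_dag(Component(0, g))
        assert enumerate_paths_through(dag, ids[1], m_max=64) == [ids]

    def test_two_by_two_cross_gives_four(self):
        g, m = self.cross()
        dag = to_dag(Component(0, g))
        paths = enumerate_paths_through(dag, m, m_max=64)
        assert len(paths) == 4
        assert all(m in p and len(p) == 3 for p in paths)

    def test_m_max_truncates_to_top_ranked(self):
        g, m = self.cross()
        dag = to_dag(Component(0, g))
        (top,) = enumerate_paths_through(dag, m, m_max=1)
        full = enumerate_paths_through(dag, m, m_max=64)
        assert top == full[0]

    def test_agrees_with_bruteforce(self):
        for seed in range(40):
            comp = random_component(seed + 300, max_kmers=24)
            dag = to_dag(comp)
            if len(dag.graph) > 12:
                continue
            path = longest_path(dag)
            b, _ = find_bottleneck(path, dag.graph)
            ours = enumerate_paths_through(dag, b, m_max=10_000)
            through = [p for p in all_paths_bruteforce(dag.graph) if b in p]
            best_len = max(len(reconstruct_sequence(p, dag.graph)) for p in through)
            oracle = {tuple(p) for p in through
                      if len(reconstruct_sequence(p, dag.graph)) == best_len}
            assert {tuple(p) for p in ours} == oracle


class TestDistribute:
    def test_abundance_three_three_paths(self):
        """Bottleneck of abundance 3 with more candidate paths than abundance."""
        g, m = TestEnumerate.cross(abund=3)
        dag = to_dag(Component(0, g))
        paths = enumerate_paths_through(dag, m, m_max=64)
        assert len(paths) == 4
        out = distribute_and_consume(dag, m, 3, paths)
        assert [s.abundance for s in out] == [1, 1, 1]
        assert m not in dag.graph.g

    def test_more_abundance_than_paths_splits_unevenly(self):
        g, m = TestEnumerate.cross(abund=5)
        dag = to_dag(Component(0, g))
        paths = enumerate_paths_through(dag, m, m_max=64)[:2]
        out = distribute_and_consume(dag, m, 5, paths)
        assert [s.abundance for s in out] == [3, 2]

    def test_two_of_five_paths_used(self):
        g, m = TestEnumerate.cross(abund=2)
        dag = to_dag(Component(0, g))
        paths = enumerate_paths_through(dag, m, m_max=64)
        out = distribute_and_consume(dag, m, 2, paths)
        assert [s.abundance for s in out] == [1, 1]


class TestReconstruct:
    def test_contraction(self):
        g, ids = chain_graph(["ACGT", "CGTA"], [[1], [1]], 4)
        assert reconstruct_sequence(ids, g) == "ACGTA"

    def test_single_vertex_identity(self):
        g, ids = chain_graph(["ACGTT"], [[1, 1]], 4)
        assert reconstruct_sequence(ids, g) == "ACGTT"

    def test_three_vertex_chain_length(self):
        g, ids = chain_graph(["AACG", "ACGT", "CGTT"], [[1], [1], [1]], 4)
        assert len(reconstruct_sequence(ids, g)) == 4 + 2

    def test_overlap_mismatch_rejected(self):
        g = DeBruijnGraph(4)
        a = g.add_vertex("ACGT", [1])
        b = g.add_vertex("TTTT", [1])
        with pytest.raises(ValueError):
            reconstruct_sequence([a, b], g)


class TestAssembleComponent:
    def test_single_unitig_one_sequence(self):
        g = graph_from_strings([("ACGTTGCA", 6)], 4)
        comp = Component(0, g)
        out = assemble_component(comp)
        assert len(out) == 1
        assert out[0].sequence == "ACGTTGCA"
        assert out[0].abundance == 6
        assert len(comp.graph) != 0  # input untouched

    def test_consumption_bookkeeping_random(self):
        """Per-k-mer emitted mass never exceeds the initial abundance."""
        for seed in range(30):
            comp = random_component(seed + 600)
            initial = comp.graph.kmer_abundances()
            out = assemble_component(comp)
            emitted: dict[str, int] = {}
            k = comp.graph.k
            for s in out:
                assert len(s.sequence) >= k
                assert s.abundance >= 1
                for i in range(len(s.sequence) - k + 1):
                    m = s.sequence[i : i + k]
                    emitted[m] = emitted.get(m, 0) + s.abundance
            for m, mass in emitted.items():
                assert mass <= initial.get(m, 0), (seed, m)
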