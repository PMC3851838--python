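from __future__ import annotations

import networkx as nx
import pytest

from contigmix.extension_graph import IN, OUT, build_graph
from contigmix.milps import (
    ExtractedPath,
    expand_scc,
    find_sccs,
    longest_path,
    make_acyclic,
    milps,
)

import oracles
from conftest import aset_from, make_contigs


def wgraph(edges: list[tuple]) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_node(IN)
    g.add_node(OUT)
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    return g


class TestFindSccs:
    def test_dag_has_none(self):
        g = wgraph([(IN, 1, 1), (1, 2, 1), (2, OUT, 1)])
        assert find_sccs(g) == []

    def test_three_cycle(self):
        g = wgraph([(IN, 1, 1), (1, 2, 1), (2, 3, 1), (3, 1, 1), (3, OUT, 1)])
        (scc,) = find_sccs(g)
        assert scc == {1, 2, 3}

    def test_two_disjoint_two_cycles_match_reachability_oracle(self):
        g = wgraph(
            [(IN, 1, 1), (1, 2, 1), (2, 1, 1), (2, 3, 1), (3, 4, 1),
             (4, 3, 1), (4, OUT, 1)]
        )
        found = {frozenset(c) for c in find_sccs(g)}
        assert found == set(oracles.mutual_reachability_sccs(g))


class TestExpandScc:
    def test_two_cycle_entry_exit(self):
        g = wgraph([(IN, "u", 5), ("u", "v", 2), ("v", "u", 3), ("v", OUT, 1)])
        dag, relabel = make_acyclic(g)
        assert nx.is_directed_acyclic_graph(dag)
        # the only useful chain is u -> v; the longest path survives expansion
        assert oracles.brute_force_longest(g) == longest_path(dag, relabel=relabel).weight

    def test_three_cycle_all_simple_paths_preserved(self):
        g = wgraph(
            [(IN, "u", 1), ("u", "v", 2), ("v", "w", 3), ("w", "u", 4),
             ("v", OUT, 5), ("w", OUT, 6)]
        )
        dag, relabel = make_acyclic(g)
        assert nx.is_directed_acyclic_graph(dag)
        assert oracles.brute_force_longest(g) == longest_path(dag, relabel=relabel).weight

    def test_acyclic_graph_unchanged(self):
        g = wgraph([(IN, 1, 1), (1, 2, 2), (2, OUT, 3)])
        dag, relabel = make_acyclic(g)
        assert relabel == {}
        assert set(dag.nodes) == set(g.nodes)

    def test_dead_scc_dropped_with_warning(self):
        g = wgraph([(IN, 1, 1), (1, OUT, 1), (7, 8, 1), (8, 7, 1)])
        dag, _ = make_acyclic(g)
        assert 7 not in dag and 8 not in dag

    def test_path_cap_enforced(self):
        # complete digraph on 6 vertices embedded between In and Out
        g = nx.complete_graph(6, nx.DiGraph())
        nx.set_edge_attributes(g, 1.0, "weight")
        g.add_edge(IN, 0, weight=1.0)
        g.add_edge(5, OUT, weight=1.0)
        with pytest.raises(RuntimeError, match="cap"):
            make_acyclic(g, path_cap=10)


class TestLongestPath:
    def test_two_chain_comparison(self):
        g = wgraph([(IN, "a", 5), ("a", OUT, 3), (IN, "b", 2), ("b", OUT, 2)])
        p = longest_path(g)
        assert p.nodes == [IN, "a", OUT]
        assert p.weight == 8

    def test_unreachable_out(self):
        g = wgraph([(IN, "a", 5)])
        assert longest_path(g) is None

    def test_forbidden_interior_avoided(self):
        g = wgraph([(IN, "a", 5), ("a", OUT, 3), (IN, "b", 2), ("b", OUT, 2)])
        p = longest_path(g, forbidden={"a"})
        assert p.nodes == [IN, "b", OUT]

    def test_cyclic_input_rejected(self):
        g = wgraph([(IN, 1, 1), (1, 2, 1), (2, 1, 1), (2, OUT, 1)])
        with pytest.raises(ValueError):
            longest_path(g)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_dags(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        g = nx.DiGraph()
        g.add_node(IN)
        g.add_node(OUT)
        nodes = list(range(n))
        for i in nodes:
            for j in nodes:
                if i < j and rng.random() < 0.35:
                    g.add_edge(i, j, weight=float(rng.uniform(0.5, 10)))
        for i in nodes[: max(1, n // 3)]:
            g.add_edge(IN, i, weight=float(rng.uniform(0.5, 10)))
        for i in nodes[-max(1, n // 3):]:
            g.add_edge(i, OUT, weight=float(rng.uniform(0.5, 10)))
        expected = oracles.brute_force_longest(g)
        got = longest_path(g)
        if expected is None:
            assert got is None
        else:
            assert got.weight == pytest.approx(expected)


class TestMilps:
    def test_single_alignment_graph_single_path(self, dovetail_pair):
        aset, _ = dovetail_pair
        g = build_graph(aset)
        paths = milps(g, mirror_dedup=True)
        assert len(paths) == 1
        assert paths[0].weight == 160

    def test_two_disjoint_chains_longer_first(self):
        g = wgraph(
            [(IN, "a1", 4), ("a1", "a2", 4), ("a2", OUT, 4),
             (IN, "b", 3), ("b", OUT, 3)]
        )
        paths = milps(g)
        assert [p.weight for p in paths] == [12, 6]
        assert paths[0].nodes == [IN, "a1", "a2", OUT]

    def test_weights_non_increasing(self):
        g = wgraph(
            [(IN, x, i, ) for i, x in enumerate("abcde", start=1)]
            + [(x, OUT, 1) for x in "abcde"]
        )
        paths = milps(g)
        weights = [p.weight for p in paths]
        assert weights == sorted(weights, reverse=True)

    def test_output_satisfies_definition_conditions(self):
        import numpy as np

        checked = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            g = _random_digraph(rng)
            if len(list(nx.all_simple_paths(g, IN, OUT))) > 40:
                continue
            paths = milps(g)
            assert oracles.satisfies_ilps_conditions(g, [p.nodes for p in paths])
            checked += 1
        assert checked >= 25


def _random_digraph(rng, n_max: int = 10) -> nx.DiGraph:
    """Sparse random weighted digraph (cycles allowed, no In->Out edge)."""
    n = int(rng.integers(4, n_max + 1))
    g = nx.DiGraph()
    g.add_node(IN)
    g.add_node(OUT)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.18:
                g.add_edge(i, j, weight=float(rng.uniform(0.5, 10)))
    for i in range(n):
        if rng.random() < 0.3:
            g.add_edge(IN, i, weight=float(rng.uniform(0.5, 10)))
        if rng.random() < 0.3:
            g.add_edge(i, OUT, weight=float(rng.uniform(0.5, 10)))
    return g


def test_first_path_equals_dp_longest_on_acyclic():
    import numpy as np

    for seed in range(15):
        rng = np.random.default_rng(seed)
        g = _random_digraph(rng)
        dag, relabel = make_acyclic(g, path_cap=5000)
        first = longest_path(dag, relabel=relabel)
        expected = oracles.brute_force_longest(g)
        if expected is None:
            assert first is None
        else:
            assert first.weight == pytest.approx(expected)
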