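"""Maximal Independent Longest Path Set extraction.

Strongly connected components are replaced by explicit chains, one per
simple entry->exit path inside the component, yielding an acyclic graph.
Longest In->Out paths are then extracted iteratively by topological-order
dynamic programming; vertices of each extracted path (traced back to their
original labels through the relabeling map) become forbidden for later
iterations, which enforces pairwise vertex-independence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any, Callable, Hashable, Iterable

import networkx as nx

from .extension_graph import ExtNode, IN, OUT, reverse_variant

logger = logging.getLogger(__name__)

DEFAULT_SCC_PATH_CAP = 10_000


@dataclass(frozen=True, order=True)
class CopyNode:
    """A relabel-tracked copy inserted while expanding an SCC."""

    idx: int
    pos: int


def node_key(v: Hashable) -> str:
    """Deterministic total order over heterogeneous node labels."""
    return repr(v)


@dataclass
class ExtractedPath:
    nodes: list  # original labels, In ... Out
    weight: float

    @property
    def interior(self) -> list:
        return self.nodes[1:-1]


def find_sccs(g: nx.DiGraph) -> list[set]:
    """Non-singleton strongly connected components."""
    return [c for c in nx.strongly_connected_components(g) if len(c) > 1]


def expand_scc(
    g: nx.DiGraph,
    scc: set,
    relabel: dict,
    path_cap: int = DEFAULT_SCC_PATH_CAP,
    counter: list[int] | None = None,
) -> None:
    """Replace ``scc`` in ``g`` by acyclic chains, one per simple path
    between its entry and exit vertices.  ``relabel`` records the original
    label of every inserted copy.  Mutates ``g`` in place.
    """
    if counter is None:
        counter = [0]
    entries = sorted(
        (v for v in scc if any(u not in scc for u in g.predecessors(v))),
        key=node_key,
    )
    exits = sorted(
        (v for v in scc if any(u not in scc for u in g.successors(v))),
        key=node_key,
    )
    if not entries or not exits:
        logger.warning("SCC of size %d has no entry or no exit; dropped", len(scc))
        g.remove_nodes_from(scc)
        return

    sub = g.subgraph(scc)
    paths: list[list] = []
    for u in entries:
        for v in exits:
            if u == v:
                paths.append([u])
            else:
                for p in nx.all_simple_paths(sub, u, v):
                    paths.append(p)
            if len(paths) > path_cap:
                raise RuntimeError(
                    f"SCC expansion exceeded the path cap ({path_cap}); "
                    "raise the alignment length threshold t_a or the cap"
                )
    paths.sort(key=lambda p: [node_key(v) for v in p])

    ext_in = {
        v: [(u, dict(g.edges[u, v])) for u in g.predecessors(v) if u not in scc]
        for v in entries
    }
    ext_out = {
        v: [(w, dict(g.edges[v, w])) for w in g.successors(v) if w not in scc]
        for v in exits
    }

    for p in paths:
        counter[0] += 1
        chain = [CopyNode(counter[0], i) for i in range(len(p))]
        for c, orig in zip(chain, p):
            relabel[c] = relabel.get(orig, orig)
        for (c1, c2), (o1, o2) in zip(zip(chain, chain[1:]), zip(p, p[1:])):
            g.add_edge(c1, c2, **g.edges[o1, o2])
        for u, data in ext_in[p[0]]:
            g.add_edge(u, chain[0], **data)
        for w, data in ext_out[p[-1]]:
            g.add_edge(chain[-1], w, **data)

    g.remove_nodes_from(scc)


def make_acyclic(
    g: nx.DiGraph, path_cap: int = DEFAULT_SCC_PATH_CAP
) -> tuple[nx.DiGraph, dict]:
    """Copy ``g`` and expand every non-singleton SCC; return (dag, relabel)."""
    dag = g.copy()
    dag.remove_edges_from(list(nx.selfloop_edges(dag)))
    relabel: dict = {}
    counter = [0]
    while True:
        sccs = find_sccs(dag)
        if not sccs:
            break
        scc = min(sccs, key=lambda c: min(node_key(v) for v in c))
        expand_scc(dag, scc, relabel, path_cap, counter)
    return dag, relabel


def longest_path(
    g: nx.DiGraph,
    forbidden: frozenset | set = frozenset(),
    relabel: dict | None = None,
    order: list | None = None,
) -> ExtractedPath | None:
    """Maximum-weight In->Out path of an acyclic graph whose interior avoids
    ``forbidden`` (a set of *original* labels).  Ties between predecessors
    of equal accumulated weight are broken lexicographically, making the
    result deterministic.  Returns None when Out is unreachable.
    """
    relabel = relabel or {}

    def allowed(v) -> bool:
        return v in (IN, OUT) or relabel.get(v, v) not in forbidden

    if order is None:
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("longest_path requires an acyclic graph")
        order = list(nx.lexicographical_topological_sort(g, key=node_key))

    weight: dict = {IN: 0.0}
    pred: dict = {}
    for v in order:
        if v == IN or not allowed(v):
            continue
        best: tuple[float, str] | None = None
        best_u = None
        for u in g.predecessors(v):
            if u == OUT or not allowed(u) or u not in weight:
                continue
            cand = weight[u] + g.edges[u, v]["weight"]
            key = node_key(u)
            if best is None or cand > best[0] or (cand == best[0] and key < best[1]):
                best = (cand, key)
                best_u = u
        if best is not None:
            weight[v] = best[0]
            pred[v] = best_u
    if OUT not in weight:
        return None
    nodes = [OUT]
    while nodes[-1] != IN:
        nodes.append(pred[nodes[-1]])
    nodes.reverse()
    return ExtractedPath(nodes, weight[OUT])


def _mirror_sequence(nodes: list) -> list:
    return [IN] + [reverse_variant(v) for v in reversed(nodes[1:-1])] + [OUT]


def _canonical(nodes: list) -> list:
    """Pick one representative of a mirror pair: prefer the reading with
    more forward-direction vertices, then the lexicographically smaller."""
    mirror = _mirror_sequence(nodes)

    def rank(p: list) -> tuple:
        fwd = sum(1 for v in p[1:-1] if isinstance(v, ExtNode) and v.direction == "f")
        return (-fwd, [node_key(v) for v in p])

    return min(nodes, mirror, key=rank)


def milps(
    g: nx.DiGraph,
    path_cap: int = DEFAULT_SCC_PATH_CAP,
    mirror_dedup: bool = False,
) -> list[ExtractedPath]:
    """Iteratively extract the longest remaining independent In->Out paths.

    With ``mirror_dedup`` (used on extension graphs, whose direction-flipped
    mirror of any path is an equal-weight duplicate), each extracted path
    also forbids the direction-flipped twins of its vertices, and the
    lexicographically smaller of the path/mirror pair is emitted.
    """
    dag, relabel = make_acyclic(g, path_cap)
    order = list(nx.lexicographical_topological_sort(dag, key=node_key))
    forbidden: set = set()
    result: list[ExtractedPath] = []
    while True:
        p = longest_path(dag, forbidden, relabel, order)
        if p is None:
            break
        orig = [relabel.get(v, v) for v in p.nodes]
        interior = orig[1:-1]
        if not interior:
            break  # a direct In->Out edge can never be consumed
        forbidden.update(interior)
        if mirror_dedup:
            forbidden.update(
                reverse_variant(v) for v in interior if isinstance(v, ExtNode)
            )
            orig = _canonical(orig)
        logger.info("extracted path: weight %.0f, %d vertices", p.weight, len(orig))
        result.append(ExtractedPath(orig, p.weight))
    return result
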