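"""Independent brute-force oracles used by the test suite.

Everything here recomputes expectations from first principles (exhaustive
enumeration over small inputs) and deliberately shares no code with the
package's solvers.
"""

from __future__ import annotations

import itertools

import networkx as nx

IN = "In"
OUT = "Out"


def path_weight(g: nx.DiGraph, path: list) -> float:
    return sum(g.edges[u, v]["weight"] for u, v in zip(path, path[1:]))


def all_in_out_paths(g: nx.DiGraph) -> list[list]:
    if IN not in g or OUT not in g:
        return []
    return [list(p) for p in nx.all_simple_paths(g, IN, OUT)]


def brute_force_longest(g: nx.DiGraph) -> float | None:
    """Max In->Out simple path weight by exhaustive enumeration."""
    paths = all_in_out_paths(g)
    if not paths:
        return None
    return max(path_weight(g, p) for p in paths)


def independent(p: list, q: list) -> bool:
    return not (set(p[1:-1]) & set(q[1:-1]))


def satisfies_ilps_conditions(
    g: nx.DiGraph, chosen: list[list], tol: float = 1e-9
) -> bool:
    """Conditions of an independent longest path set, checked verbatim:

    1. every chosen path runs In -> Out;
    2. chosen paths are pairwise vertex-independent outside {In, Out};
    3. every simple In->Out path of the graph is either independent of all
       chosen paths or weighs no more than the heaviest chosen path it
       shares a vertex with.
    """
    for p in chosen:
        if p[0] != IN or p[-1] != OUT:
            return False
    for p, q in itertools.combinations(chosen, 2):
        if not independent(p, q):
            return False
    chosen_w = [path_weight(g, p) for p in chosen]
    for p in all_in_out_paths(g):
        touching = [
            w for q, w in zip(chosen, chosen_w) if not independent(p, q)
        ]
        if touching and path_weight(g, p) > max(touching) + tol:
            return False
    return True


def max_coverage_milps(g: nx.DiGraph, tol: float = 1e-9) -> int:
    """Maximum vertex coverage over all complete independent longest path
    sets, by exhaustive tie-branching: repeatedly pick *any* maximum-weight
    path among those vertex-independent of the current choice, branching on
    ties, until none remains.
    """
    paths = all_in_out_paths(g)
    weights = [path_weight(g, p) for p in paths]
    best = [0]

    def rec(chosen_idx: list[int]) -> None:
        used = set()
        for i in chosen_idx:
            used |= set(paths[i][1:-1])
        avail = [
            i for i in range(len(paths)) if not (set(paths[i][1:-1]) & used)
        ]
        if not avail:
            cov = len(used) + (2 if chosen_idx else 0)
            best[0] = max(best[0], cov)
            return
        wmax = max(weights[i] for i in avail)
        for i in avail:
            if weights[i] >= wmax - tol:
                rec(chosen_idx + [i])

    rec([])
    return best[0]


def mutual_reachability_sccs(g: nx.DiGraph) -> list[frozenset]:
    """Non-singleton SCCs via transitive-closure mutual reachability."""
    reach = {u: set(nx.descendants(g, u)) | {u} for u in g}
    comps: dict[frozenset, None] = {}
    for u in g:
        comp = frozenset(v for v in g if v in reach[u] and u in reach[v])
        if len(comp) > 1:
            comps[comp] = None
    return list(comps)


def interval_union_length(intervals: list[tuple[int, int]]) -> int:
    covered: set[int] = set()
    for lo, hi in intervals:
        covered.update(range(lo, hi))
    return len(covered)


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))
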