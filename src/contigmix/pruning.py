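"""Containment-based pruning of redundant output elements.

A coverage matrix over output elements (merged paths and leftover contigs)
is computed by projecting the *original* alignment set onto element
coordinates; entry (x, y) is the fraction of x's positions covered by
alignments to y's member contigs (interval union, no double counting).
Pairs above the threshold become directed edges source -> target ("source
is contained in target"), the source being the element with the higher
own-coverage ratio (ties: shorter element, then lexicographically smaller
id).  Cycles are broken by electing the longest element of each strongly
connected component as representative.  Finally, elements that cover
nothing but are covered (in-degree 0, out-degree >= 1) are removed,
iterating to a fixpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx

from .io_model import Assembly, AlignmentSet
from .stitcher import Layout

logger = logging.getLogger(__name__)

DEFAULT_COVERAGE_THRESHOLD = 0.90


@dataclass(frozen=True)
class _Placement:
    """Where a contig slice lands inside an element."""

    element: str
    start: int  # contig coords covered by this placement
    end: int
    offset: int  # element coord of contig position `start` (orient +) / `end` (-)
    orient: str


def _placements(
    elements: Mapping[str, Layout | str],
) -> dict[str, list[_Placement]]:
    """Map contig id -> placements inside elements.

    ``elements`` maps element id -> Layout (path elements) or contig id
    (leftover contigs standing for themselves).
    """
    by_contig: dict[str, list[_Placement]] = {}
    for eid, spec in elements.items():
        if isinstance(spec, str):
            by_contig.setdefault(spec, []).append(
                _Placement(eid, 0, 10**18, 0, "+")
            )
            continue
        off = 0
        for seg in spec.segments:
            by_contig.setdefault(seg.contig, []).append(
                _Placement(eid, seg.start, seg.end, off, seg.orient)
            )
            off += len(seg)
    return by_contig


def _project(p: _Placement, lo: int, hi: int) -> tuple[int, int] | None:
    """Project contig interval [lo, hi) through a placement, or None."""
    lo, hi = max(lo, p.start), min(hi, p.end)
    if hi <= lo:
        return None
    if p.orient == "+":
        return (p.offset + lo - p.start, p.offset + hi - p.start)
    return (p.offset + p.end - hi, p.offset + p.end - lo)


def _union_len(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last = -1
    for lo, hi in sorted(intervals):
        lo = max(lo, last)
        if hi > lo:
            total += hi - lo
            last = hi
    return total


def coverage_matrix(
    elements: Mapping[str, Layout | str],
    lengths: Mapping[str, int],
    aset: AlignmentSet,
) -> dict[tuple[str, str], float]:
    """Pairwise coverage ratios in [0, 1] over output elements.

    Alignments whose two contigs live inside the same element are skipped
    (self-coverage); the diagonal is never populated.
    """
    by_contig = _placements(elements)
    acc: dict[tuple[str, str], list[tuple[int, int]]] = {}
    # a contig shared by two elements covers itself: count the intersection
    # of its two placements as an identity alignment
    for placements in by_contig.values():
        for px in placements:
            for py in placements:
                if px.element == py.element:
                    continue
                iv = _project(px, max(px.start, py.start), min(px.end, py.end))
                if iv is not None:
                    acc.setdefault((px.element, py.element), []).append(iv)
    for a in aset:
        for c_self, c_other, lo, hi in (
            (a.ci, a.cj, a.bi, a.ei),
            (a.cj, a.ci, a.bj, a.ej),
        ):
            for px in by_contig.get(c_self, ()):
                iv = _project(px, lo, hi)
                if iv is None:
                    continue
                for py in by_contig.get(c_other, ()):
                    if px.element == py.element:
                        continue
                    acc.setdefault((px.element, py.element), []).append(iv)
    return {
        key: min(1.0, _union_len(ivs) / lengths[key[0]]) for key, ivs in acc.items()
    }


def build_coverage_graph(
    table: Mapping[tuple[str, str], float],
    lengths: Mapping[str, int],
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> nx.DiGraph:
    """Thresholded, oriented coverage graph over all elements."""
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    g = nx.DiGraph()
    g.add_nodes_from(lengths)
    for x in sorted(lengths):
        for y in sorted(lengths):
            if y <= x:
                continue
            rx = table.get((x, y), 0.0)
            ry = table.get((y, x), 0.0)
            if max(rx, ry) < threshold:
                continue
            if rx > ry:
                src, dst, ratio = x, y, rx
            elif ry > rx:
                src, dst, ratio = y, x, ry
            elif lengths[x] != lengths[y]:
                src, dst = (x, y) if lengths[x] < lengths[y] else (y, x)
                ratio = rx
            else:
                src, dst, ratio = x, y, rx  # length tie: smaller id is source
            g.add_edge(src, dst, ratio=ratio)
    return g


def break_cycles(g: nx.DiGraph, lengths: Mapping[str, int]) -> nx.DiGraph:
    """Make the coverage graph acyclic.

    Within each non-singleton SCC the longest element (ties: smaller id)
    survives as representative; intra-SCC edges are replaced by one edge
    from every other member to the representative.
    """
    g = g.copy()
    for scc in list(nx.strongly_connected_components(g)):
        if len(scc) < 2:
            continue
        rep = min(scc, key=lambda e: (-lengths[e], e))
        for u in scc:
            for v in list(g.successors(u)):
                if v in scc:
                    g.remove_edge(u, v)
        for u in scc:
            if u != rep:
                g.add_edge(u, rep, ratio=1.0)
    return g


def prune(
    g: nx.DiGraph, candidates: Assembly
) -> tuple[Assembly, list[tuple[str, str, str, float]]]:
    """Remove covered-but-covering-nothing elements, iterating to fixpoint.

    Returns the pruned assembly and report rows
    (element, decision, best covering element, ratio).
    """
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("prune requires an acyclic coverage graph")
    g = g.copy()
    removed: dict[str, tuple[str, float]] = {}
    while True:
        batch = sorted(
            v for v in g if g.out_degree(v) >= 1 and g.in_degree(v) == 0
        )
        if not batch:
            break
        for v in batch:
            best = max(
                g.successors(v), key=lambda t: (g.edges[v, t]["ratio"], t)
            )
            removed[v] = (best, g.edges[v, best]["ratio"])
        g.remove_nodes_from(batch)

    kept = [c for c in candidates if c.id not in removed]
    report: list[tuple[str, str, str, float]] = []
    for c in candidates:
        if c.id in removed:
            target, ratio = removed[c.id]
            report.append((c.id, "removed", target, ratio))
        else:
            report.append((c.id, "kept", "", 0.0))
    logger.info("pruning: %d -> %d elements", len(candidates), len(kept))
    return Assembly(candidates.label, kept), report


def write_pruning_report(
    rows: list[tuple[str, str, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("element\tdecision\tcovered_by\tratio\n")
        for element, decision, target, ratio in rows:
            fh.write(f"{element}\t{decision}\t{target}\t{ratio:.4f}\n")
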