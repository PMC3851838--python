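"""Weighted extension graph over terminal contig-contig alignments.

Every terminal alignment contributes eight vertices: for each of its two
contigs, the two footprint ends (role ``b`` for the end sitting at a contig
boundary, ``i`` for the internal end) in both reading directions (``f``
forward, ``r`` reverse-complement).  Two artificial vertices In and Out are
the unique source and sink.

Edge derivation
---------------

Node semantics make every In->Out traversal spell a consistent walk of each
visited contig in one chosen direction.  For an alignment side (a contig's
footprint) read in direction ``d``:

* the *entry* node is the footprint end reached first when reading the
  contig in direction ``d``; the *exit* node is the end reached last.

Edges, each carrying both a weight in bases and the sequence segment it
contributes to a stitched path (weight == segment length by construction):

* ``In -> entry(side, d)`` -- the contig chunk before the footprint in
  direction ``d`` (the remaining contig length outside the overlap);
  symmetrically ``exit(side, d) -> Out`` for the chunk after it.
* ``entry(i, d) -> exit(j, d')`` -- crossing from one contig to the other
  through the overlap, weight = source-side footprint span (= ``l`` when
  both spans agree).  Created only when the gluing is geometrically
  consistent: the source footprint must sit at the downstream end of its
  contig in direction ``d`` and the target footprint at the upstream end in
  ``d' = d`` (or flipped when the alignment is reverse-strand).
* ``exit(C, a1, d) -> entry(C, a2, d)`` -- inter-alignment edges on a
  contig participating in several alignments, weight = bases between the
  two footprints.  Pairs of footprints that overlap each other (negative
  gap) get no link edge: a zero-clamped link would let a path step
  backwards along the contig and re-render bases it already emitted,
  rewarding duplicated weaving.  Omissions are counted in the graph
  attribute ``n_negative_links``.

Within-alignment zero-weight edges between the ``b`` and ``i`` nodes of one
side are deliberately omitted: traversing them would let a path skip the
overlap bases and break weight/sequence conservation.  They carry no weight
and no sequence, so dropping them removes no useful traversal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import networkx as nx

from .io_model import Alignment, AlignmentSet, Contig

logger = logging.getLogger(__name__)

IN = "In"
OUT = "Out"

FWD = "f"
REV = "r"
ROLE_BOUNDARY = "b"
ROLE_INTERNAL = "i"


@dataclass(frozen=True, order=True)
class ExtNode:
    """One of the eight vertices of a terminal alignment."""

    contig: str
    aln: int
    role: str  # "b" boundary / "i" internal
    direction: str  # "f" / "r"


@dataclass(frozen=True)
class Segment:
    """A half-open slice of a contig, possibly reverse-complemented."""

    contig: str
    orient: str  # "+" / "-"
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


def reverse_variant(node: ExtNode) -> ExtNode:
    """Direction-flipped twin of a node (involution)."""
    if not isinstance(node, ExtNode):
        raise ValueError(f"reverse_variant undefined for {node!r}")
    return replace(node, direction=REV if node.direction == FWD else FWD)


@dataclass(frozen=True)
class _Side:
    """Geometry of one alignment footprint on one contig."""

    contig: str
    aln: int
    b: int
    e: int
    clen: int
    right_terminal: bool  # footprint sits at the right contig end

    @property
    def span(self) -> int:
        return self.e - self.b

    @property
    def mid(self) -> float:
        return (self.b + self.e) / 2

    def entry(self, d: str) -> ExtNode:
        coord_is_b = d == FWD
        return self._node(coord_is_b, d)

    def exit(self, d: str) -> ExtNode:
        coord_is_b = d == REV
        return self._node(coord_is_b, d)

    def _node(self, coord_is_b: bool, d: str) -> ExtNode:
        # role follows the coordinate: the footprint end at the contig
        # boundary is "b", the other is "i"
        if self.right_terminal:
            role = ROLE_INTERNAL if coord_is_b else ROLE_BOUNDARY
        else:
            role = ROLE_BOUNDARY if coord_is_b else ROLE_INTERNAL
        return ExtNode(self.contig, self.aln, role, d)

    def upstream_len(self, d: str) -> int:
        return self.b if d == FWD else self.clen - self.e

    def downstream_len(self, d: str) -> int:
        return self.clen - self.e if d == FWD else self.b

    def upstream_segment(self, d: str) -> Segment:
        if d == FWD:
            return Segment(self.contig, "+", 0, self.b)
        return Segment(self.contig, "-", self.e, self.clen)

    def downstream_segment(self, d: str) -> Segment:
        if d == FWD:
            return Segment(self.contig, "+", self.e, self.clen)
        return Segment(self.contig, "-", 0, self.b)

    def footprint_segment(self, d: str) -> Segment:
        return Segment(self.contig, "+" if d == FWD else "-", self.b, self.e)

    def downstream_terminal(self, d: str) -> bool:
        """Footprint at the end of the contig reached last in direction d."""
        return self.right_terminal if d == FWD else not self.right_terminal

    def upstream_terminal(self, d: str) -> bool:
        return not self.right_terminal if d == FWD else self.right_terminal


def _side_terminality(b: int, e: int, clen: int, eps: int) -> bool | None:
    """None if not terminal; else True when right-terminal, False when left."""
    left = b <= eps
    right = e >= clen - eps
    if left and right:
        # near-full footprint: pick the closer end, ties -> right
        return (clen - e) <= b
    if right:
        return True
    if left:
        return False
    return None


def is_terminal(a: Alignment, contigs: Mapping[str, Contig], eps: int = 0) -> bool:
    """True iff the alignment involves an extremity of both contigs.

    A coordinate counts as an extremity when within ``eps`` bases of 0 or
    of the contig length.
    """
    ti = _side_terminality(a.bi, a.ei, len(contigs[a.ci]), eps)
    tj = _side_terminality(a.bj, a.ej, len(contigs[a.cj]), eps)
    return ti is not None and tj is not None


def _flip(d: str) -> str:
    return REV if d == FWD else FWD


def build_graph(aset: AlignmentSet, eps: int = 0) -> nx.DiGraph:
    """Build the extension graph of a cleaned alignment set.

    Non-terminal alignments are dropped (counted in the graph attribute
    ``n_non_terminal``).  Edge attributes: ``weight`` (bases), ``kind``
    (``in``/``out``/``cross``/``link``) and ``seg`` (:class:`Segment`).
    """
    g = nx.DiGraph(n_non_terminal=0, n_negative_links=0)
    g.add_node(IN)
    g.add_node(OUT)
    sides_by_contig: dict[str, list[_Side]] = {}

    for aid, a in enumerate(aset.alignments):
        len_i = len(aset.contigs[a.ci])
        len_j = len(aset.contigs[a.cj])
        ti = _side_terminality(a.bi, a.ei, len_i, eps)
        tj = _side_terminality(a.bj, a.ej, len_j, eps)
        if ti is None or tj is None:
            g.graph["n_non_terminal"] += 1
            continue
        si = _Side(a.ci, aid, a.bi, a.ei, len_i, ti)
        sj = _Side(a.cj, aid, a.bj, a.ej, len_j, tj)

        for s in (si, sj):
            for d in (FWD, REV):
                en, ex = s.entry(d), s.exit(d)
                g.add_node(en)
                g.add_node(ex)
                g.add_edge(
                    IN, en,
                    weight=s.upstream_len(d), kind="in", seg=s.upstream_segment(d),
                )
                g.add_edge(
                    ex, OUT,
                    weight=s.downstream_len(d), kind="out", seg=s.downstream_segment(d),
                )
            sides_by_contig.setdefault(s.contig, []).append(s)

        # cross edges: traverse the overlap and switch contigs
        for src, dst in ((si, sj), (sj, si)):
            for d in (FWD, REV):
                dd = _flip(d) if a.reversed_j else d
                if src.downstream_terminal(d) and dst.upstream_terminal(dd):
                    g.add_edge(
                        src.entry(d), dst.exit(dd),
                        weight=src.span, kind="cross", seg=src.footprint_segment(d),
                    )

    # inter-alignment ("link") edges on contigs shared by several alignments
    for contig, sides in sides_by_contig.items():
        for s1 in sides:
            for s2 in sides:
                if s1.aln == s2.aln:
                    continue
                if (s1.mid, s1.aln) >= (s2.mid, s2.aln):
                    continue  # s1 strictly precedes s2 along the contig
                gap = s2.b - s1.e
                if gap < 0:
                    g.graph["n_negative_links"] += 1
                    logger.debug(
                        "overlapping footprints on %s (alignments %d/%d); "
                        "no link edge",
                        contig, s1.aln, s2.aln,
                    )
                    continue
                lo, hi = s1.e, s2.b
                g.add_edge(
                    s1.exit(FWD), s2.entry(FWD),
                    weight=hi - lo, kind="link", seg=Segment(contig, "+", lo, hi),
                )
                g.add_edge(
                    s2.exit(REV), s1.entry(REV),
                    weight=hi - lo, kind="link", seg=Segment(contig, "-", lo, hi),
                )

    logger.info(
        "extension graph: %d nodes, %d edges (%d non-terminal alignments dropped)",
        g.number_of_nodes(), g.number_of_edges(), g.graph["n_non_terminal"],
    )
    return g


def path_weight(g: nx.DiGraph, path: Iterable) -> float:
    nodes = list(path)
    return sum(g.edges[u, v]["weight"] for u, v in zip(nodes, nodes[1:]))


def dump_dot(g: nx.DiGraph, path: str) -> None:
    """Write the graph in DOT format for debugging."""

    def name(v) -> str:
        if isinstance(v, ExtNode):
            return f"{v.contig}.{v.aln}.{v.role}.{v.direction}"
        return str(v)

    with open(path, "w") as fh:
        fh.write("digraph extension {\n")
        for u, v, data in g.edges(data=True):
            fh.write(
                f'  "{name(u)}" -> "{name(v)}" '
                f'[label="{data.get("weight", 0)}:{data.get("kind", "?")}"];\n'
            )
        fh.write("}\n")
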