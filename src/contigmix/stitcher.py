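"""Turn extension paths into merged nucleotide sequences.

Every graph edge carries the contig slice it contributes, so a path's
layout is the concatenation of its edge segments (empty ones dropped,
adjacent collinear ones coalesced) and the rendered length always equals
the path weight.  Overlap bases are contributed by the contig appearing
earlier in the path; no consensus is called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .extension_graph import Segment
from .io_model import Assembly, Contig, revcomp
from .milps import ExtractedPath

PATH_ID_PREFIX = "MIX__path_"


@dataclass
class Layout:
    """Ordered contig slices whose concatenation spells a merged sequence."""

    segments: list[Segment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def total_length(self) -> int:
        return sum(len(s) for s in self.segments)

    def contig_ids(self) -> set[str]:
        return {s.contig for s in self.segments}

    def describe(self) -> str:
        return ",".join(
            f"{s.contig}:{s.orient}:{s.start}-{s.end}" for s in self.segments
        )


def _coalesce(segments: Iterable[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segments:
        if len(seg) == 0:
            continue
        if out:
            prev = out[-1]
            if prev.contig == seg.contig and prev.orient == seg.orient:
                if seg.orient == "+" and prev.end == seg.start:
                    out[-1] = Segment(seg.contig, "+", prev.start, seg.end)
                    continue
                if seg.orient == "-" and prev.start == seg.end:
                    out[-1] = Segment(seg.contig, "-", seg.start, prev.end)
                    continue
        out.append(seg)
    return out


def path_to_layout(path: ExtractedPath, g: nx.DiGraph) -> Layout:
    """Layout of an extracted path against the graph it came from."""
    segs: list[Segment] = []
    for u, v in zip(path.nodes, path.nodes[1:]):
        if not g.has_edge(u, v):
            raise ValueError(f"path edge {u!r} -> {v!r} not present in graph")
        seg = g.edges[u, v].get("seg")
        if seg is not None:
            segs.append(seg)
    return Layout(_coalesce(segs))


def render(layout: Layout, contigs: Mapping[str, Contig]) -> str:
    """Concatenate layout slices, reverse-complementing '-' segments."""
    parts: list[str] = []
    for s in layout.segments:
        contig = contigs.get(s.contig)
        if contig is None:
            raise ValueError(f"layout references unknown contig {s.contig!r}")
        if not (0 <= s.start <= s.end <= len(contig)):
            raise ValueError(
                f"segment [{s.start},{s.end}) out of bounds for |{s.contig}| = {len(contig)}"
            )
        chunk = contig.seq[s.start:s.end]
        parts.append(revcomp(chunk) if s.orient == "-" else chunk)
    return "".join(parts)


def final_candidates(
    paths: list[ExtractedPath],
    g: nx.DiGraph,
    combined: Assembly,
) -> tuple[Assembly, dict[str, Layout]]:
    """Pre-pruning candidate set: one contig per extension path plus every
    input contig not consumed by any path.  Returns the candidate assembly
    and the layout of each path element.
    """
    contigs: list[Contig] = []
    layouts: dict[str, Layout] = {}
    consumed: set[str] = set()
    for k, p in enumerate(paths, start=1):
        pid = f"{PATH_ID_PREFIX}{k}"
        layout = path_to_layout(p, g)
        layouts[pid] = layout
        consumed |= layout.contig_ids()
        contigs.append(Contig(pid, render(layout, combined.index)))
    for c in combined:
        if c.id not in consumed:
            contigs.append(c)
    return Assembly("MIX", contigs), layouts
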