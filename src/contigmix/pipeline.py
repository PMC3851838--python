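"""End-to-end orchestration: label -> clean -> graph -> paths -> stitch -> prune."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from . import align, extension_graph, milps, preprocess, pruning, stitcher
from .io_model import AlignmentSet, Assembly, combine, prefix_ids
from .preprocess import DEFAULT_TA, FilterReport
from .pruning import DEFAULT_COVERAGE_THRESHOLD
from .stats import AssemblyStats, assembly_stats
from .stitcher import Layout

logger = logging.getLogger(__name__)


@dataclass
class MixOptions:
    t_a: int = DEFAULT_TA
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD
    end_tolerance: int = 0
    scc_path_cap: int = milps.DEFAULT_SCC_PATH_CAP
    dump_graph: str | None = None


@dataclass
class MixResult:
    assembly: Assembly
    filter_report: FilterReport
    pruning_report: list[tuple[str, str, str, float]]
    layouts: dict[str, Layout]
    input_stats: list[AssemblyStats]
    output_stats: AssemblyStats
    n_paths: int = 0
    graph: nx.DiGraph = field(default=None, repr=False)

    def layout_descriptions(self) -> dict[str, str]:
        return {pid: layout.describe() for pid, layout in self.layouts.items()}


def run_mix(
    assemblies: Sequence[Assembly],
    aset: AlignmentSet,
    options: MixOptions | None = None,
) -> MixResult:
    """Merge two or more labeled assemblies given their pairwise alignments.

    ``assemblies`` must already carry globally unique contig ids (see
    :func:`contigmix.io_model.prefix_ids`); ``aset`` is the raw alignment
    set over the combined contigs.
    """
    if len(assemblies) < 2:
        raise ValueError("need at least two assemblies to mix")
    options = options or MixOptions()
    combined = combine(assemblies)

    cleaned, filter_report = preprocess.clean(aset, options.t_a)
    graph = extension_graph.build_graph(cleaned, eps=options.end_tolerance)
    if options.dump_graph:
        extension_graph.dump_dot(graph, options.dump_graph)

    paths = milps.milps(
        graph, path_cap=options.scc_path_cap, mirror_dedup=True
    )
    candidates, layouts = stitcher.final_candidates(paths, graph, combined)

    elements: dict[str, Layout | str] = {}
    lengths: dict[str, int] = {}
    for c in candidates:
        elements[c.id] = layouts.get(c.id, c.id)
        lengths[c.id] = len(c)
    table = pruning.coverage_matrix(elements, lengths, aset)
    cov_graph = pruning.build_coverage_graph(
        table, lengths, options.coverage_threshold
    )
    cov_graph = pruning.break_cycles(cov_graph, lengths)
    final, prune_report = pruning.prune(cov_graph, candidates)

    return MixResult(
        assembly=final,
        filter_report=filter_report,
        pruning_report=prune_report,
        layouts=layouts,
        input_stats=[assembly_stats(a) for a in assemblies],
        output_stats=assembly_stats(final),
        n_paths=len(paths),
        graph=graph,
    )


def load_and_run(
    fasta_paths: Sequence[str | Path],
    alignment_paths: Sequence[str | Path] = (),
    labels: Sequence[str] | None = None,
    use_builtin_aligner: bool = False,
    min_overlap: int = align.DEFAULT_MIN_OVERLAP,
    options: MixOptions | None = None,
) -> MixResult:
    """File-level front end used by the CLI."""
    from .io_model import Alignment, parse_coords, parse_tsv, read_fasta

    if len(fasta_paths) < 2:
        raise ValueError("need at least two input assemblies")
    if labels is not None and len(labels) != len(fasta_paths):
        raise ValueError("one label per input assembly required")
    raw = [
        read_fasta(p, labels[i] if labels else None)
        for i, p in enumerate(fasta_paths)
    ]
    seen: set[str] = set()
    for asm in raw:
        if asm.label in seen:
            raise ValueError(f"duplicate assembly label {asm.label!r}")
        seen.add(asm.label)
    assemblies = [prefix_ids(a, a.label) for a in raw]
    index = combine(assemblies).index

    if use_builtin_aligner:
        aset = align.exact_overlaps(assemblies, min_overlap)
    else:
        if not alignment_paths:
            raise ValueError(
                "no alignment files given (use the built-in aligner or "
                "provide show-coords/TSV files)"
            )
        alignments: list[Alignment] = []
        skipped = 0
        for p in alignment_paths:
            p = Path(p)
            sub = (
                parse_tsv(p, index)
                if p.suffix in (".tsv", ".txt")
                else parse_coords(p, index)
            )
            alignments.extend(sub.alignments)
            skipped += sub.skipped_unknown
        aset = AlignmentSet(alignments, index, skipped_unknown=skipped)
        _check_pair_coverage(assemblies, aset)

    return run_mix(assemblies, aset, options)


def _check_pair_coverage(
    assemblies: Sequence[Assembly], aset: AlignmentSet
) -> None:
    """Every assembly pair must be covered by at least one alignment."""
    label_of = {}
    for asm in assemblies:
        for c in asm:
            label_of[c.id] = asm.label
    seen_pairs = set()
    for a in aset:
        pair = tuple(sorted((label_of[a.ci], label_of[a.cj])))
        if pair[0] != pair[1]:
            seen_pairs.add(pair)
    labels = [a.label for a in assemblies]
    missing = [
        (x, y)
        for i, x in enumerate(labels)
        for y in labels[i + 1:]
        if (x, y) not in seen_pairs and (y, x) not in seen_pairs
    ]
    if missing:
        raise ValueError(
            "no alignments provided for assembly pair(s): "
            + ", ".join(f"{x}/{y}" for x, y in missing)
        )
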