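"""Alignment-set clean-up applied before graph construction.

Five rules, applied in order:

1. drop self alignments;
2. keep one representative of reciprocal duplicates covering the same region;
3. keep only alignments with length strictly greater than ``t_a``;
4. drop near-containments (``l`` exceeding 99% of either contig length);
5. drop alignments touching spurious contigs (outlier alignment counts).

Rule 5 iterates to a fixpoint so that the overall cleaning is idempotent.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import Alignment, AlignmentSet

logger = logging.getLogger(__name__)

DEFAULT_TA = 200


@dataclass
class FilterReport:
    removed_self: int = 0
    removed_reciprocal: int = 0
    removed_short: int = 0
    removed_contained: int = 0
    removed_spurious: int = 0
    spurious_contig_ids: set[str] = field(default_factory=set)

    @property
    def total_removed(self) -> int:
        return (
            self.removed_self
            + self.removed_reciprocal
            + self.removed_short
            + self.removed_contained
            + self.removed_spurious
        )

    def to_dict(self) -> dict:
        return {
            "removed_self": self.removed_self,
            "removed_reciprocal": self.removed_reciprocal,
            "removed_short": self.removed_short,
            "removed_contained": self.removed_contained,
            "removed_spurious": self.removed_spurious,
            "spurious_contig_ids": sorted(self.spurious_contig_ids),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def remove_self_alignments(aset: AlignmentSet) -> AlignmentSet:
    """Rule 1: eliminate alignments of a contig against itself."""
    return aset.with_alignments(a for a in aset if a.ci != a.cj)


def _overlap_len(iv1: tuple[int, int], iv2: tuple[int, int]) -> int:
    return max(0, min(iv1[1], iv2[1]) - max(iv1[0], iv2[0]))


def _same_region(a: Alignment, b: Alignment) -> bool:
    """True when reciprocal alignments a=<x,y>, b=<y,x> cover the same region.

    Operationalized as >=50% reciprocal overlap of the two footprints
    projected on a's reference contig (a's i-side vs b's j-side).
    """
    ov = _overlap_len((a.bi, a.ei), (b.bj, b.ej))
    return 2 * ov >= (a.ei - a.bi) and 2 * ov >= (b.ej - b.bj)


def dedupe_reciprocal(aset: AlignmentSet) -> AlignmentSet:
    """Rule 2: keep one of <Ci,Cj> / <Cj,Ci> covering the same region.

    Alignments are scanned in canonical sorted order so the survivor is the
    one with the lexicographically smallest (ci, cj), ties broken by bi.
    """
    kept: list[Alignment] = []
    by_pair: dict[tuple[str, str], list[Alignment]] = {}
    for a in sorted(aset, key=Alignment.key):
        dup = any(_same_region(b, a) for b in by_pair.get((a.cj, a.ci), []))
        if dup:
            continue
        kept.append(a)
        by_pair.setdefault(a.pair, []).append(a)
    order = {a.key(): i for i, a in enumerate(aset)}
    kept.sort(key=lambda a: order.get(a.key(), 0))  # restore input order
    return aset.with_alignments(kept)


def filter_by_length(aset: AlignmentSet, t_a: int) -> AlignmentSet:
    """Rule 3: keep only alignments with ``l`` strictly greater than ``t_a``."""
    if t_a < 0:
        raise ValueError(f"t_a must be >= 0, got {t_a}")
    return aset.with_alignments(a for a in aset if a.l > t_a)


def filter_containment(aset: AlignmentSet) -> AlignmentSet:
    """Rule 4: drop alignments with l/|si| > 99% or l/|sj| > 99%."""

    def contained(a: Alignment) -> bool:
        li = len(aset.contigs[a.ci])
        lj = len(aset.contigs[a.cj])
        return 100 * a.l > 99 * li or 100 * a.l > 99 * lj

    return aset.with_alignments(a for a in aset if not contained(a))


def detect_spurious(aset: AlignmentSet) -> set[str]:
    """Rule 5: contigs with an outlier-high number of alignments.

    A contig is flagged when its alignment count exceeds Q3 + 3*IQR of the
    per-contig count distribution (linear-interpolation quartiles).  When
    IQR is zero the fence degenerates, so the fallback is count > 3*median;
    in particular equal counts everywhere never flag anything.
    """
    counts: Counter[str] = Counter()
    for a in aset:
        counts[a.ci] += 1
        counts[a.cj] += 1
    if not counts:
        return set()
    values = np.array(list(counts.values()), dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    if iqr > 0:
        fence = q3 + 3 * iqr
    else:
        fence = 3 * float(np.median(values))
    return {cid for cid, n in counts.items() if n > fence}


def clean(aset: AlignmentSet, t_a: int = DEFAULT_TA) -> tuple[AlignmentSet, FilterReport]:
    """Apply rules 1-5 in order and tally removals per rule."""
    report = FilterReport()

    step = remove_self_alignments(aset)
    report.removed_self = len(aset) - len(step)

    before = len(step)
    step = dedupe_reciprocal(step)
    report.removed_reciprocal = before - len(step)

    before = len(step)
    step = filter_by_length(step, t_a)
    report.removed_short = before - len(step)

    before = len(step)
    step = filter_containment(step)
    report.removed_contained = before - len(step)

    # rule 5, iterated to fixpoint so clean() is idempotent
    while True:
        spurious = detect_spurious(step)
        if not spurious:
            break
        report.spurious_contig_ids |= spurious
        before = len(step)
        step = step.with_alignments(
            a for a in step if a.ci not in spurious and a.cj not in spurious
        )
        report.removed_spurious += before - len(step)

    logger.info(
        "clean: %d -> %d alignments (self=%d reciprocal=%d short=%d "
        "contained=%d spurious=%d)",
        len(aset),
        len(step),
        report.removed_self,
        report.removed_reciprocal,
        report.removed_short,
        report.removed_contained,
        report.removed_spurious,
    )
    return step, report
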