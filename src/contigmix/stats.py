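"""Reference-free assembly fragmentation statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_model import Assembly


@dataclass(frozen=True)
class AssemblyStats:
    label: str
    n_contigs: int
    largest: int
    total_length: int
    n50: int

    def row(self) -> str:
        return (
            f"{self.label}\t{self.n_contigs}\t{self.largest}\t"
            f"{self.total_length}\t{self.n50}"
        )


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L sum to >= half the total."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    raise AssertionError("unreachable")


def assembly_stats(assembly: Assembly) -> AssemblyStats:
    lengths = assembly.lengths()
    return AssemblyStats(
        label=assembly.label,
        n_contigs=len(lengths),
        largest=max(lengths),
        total_length=sum(lengths),
        n50=n50(lengths),
    )


STATS_HEADER = "assembly\tn_contigs\tlargest\ttotal_length\tn50"


def stats_table(assemblies: Sequence[Assembly]) -> str:
    lines = [STATS_HEADER]
    lines.extend(assembly_stats(a).row() for a in assemblies)
    return "\n".join(lines) + "\n"
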