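"""Synthetic genomes, fragmentations and ground-truth alignments.

Everything is seeded and text-only, so the whole pipeline is testable
without downloads or an external aligner.  Substitution errors only; no
simulated indels, so footprint spans agree on both sides of an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import Alignment, AlignmentSet, Assembly, Contig, combine, revcomp

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TruthEntry:
    """Genome placement of a simulated contig."""

    contig: str
    start: int
    end: int
    strand: str  # "+" / "-"


@dataclass
class SimSpec:
    genome_length: int = 100_000
    gc: float = 0.38
    n_assemblies: int = 2
    min_fragment: int = 12_000
    overlap_min: int = 500
    overlap_max: int = 5_000
    rc_prob: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if not (0 <= self.gc <= 1):
            raise ValueError("gc must be in [0, 1]")
        if self.overlap_min < 1 or self.overlap_max < self.overlap_min:
            raise ValueError("need 1 <= overlap_min <= overlap_max")


def simulate_genome(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. random genome at the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=length, p=p))


def fragment(
    genome: str,
    offsets: list[int],
    overlap: int | list[int],
    label: str,
    rng: np.random.Generator | None = None,
    rc_prob: float = 0.0,
    error_rate: float = 0.0,
) -> tuple[Assembly, dict[str, TruthEntry]]:
    """Cut a genome into contigs tiling it with pairwise overlaps.

    ``offsets`` are the (strictly increasing, starting at 0) fragment start
    positions; each fragment is extended rightward by ``overlap`` bases into
    its neighbour (scalar, or one value per internal junction).  With
    ``rc_prob`` whole contigs are reverse-complemented (recorded in the
    truth); with ``error_rate`` substitutions are sprinkled in.
    """
    n = len(genome)
    if not offsets or offsets[0] != 0 or any(
        b >= e for b, e in zip(offsets, offsets[1:])
    ):
        raise ValueError("offsets must start at 0 and be strictly increasing")
    junctions = len(offsets) - 1
    overlaps = [overlap] * junctions if isinstance(overlap, int) else list(overlap)
    if len(overlaps) != junctions:
        raise ValueError("need one overlap per internal junction")
    bounds = offsets + [n]
    contigs: list[Contig] = []
    truth: dict[str, TruthEntry] = {}
    for k in range(len(offsets)):
        start = bounds[k]
        end = bounds[k + 1]
        if k < junctions:
            ov = overlaps[k]
            if ov >= bounds[k + 2] - bounds[k + 1]:
                raise ValueError(
                    f"overlap {ov} >= length of fragment {k + 1}"
                )
            end = min(end + ov, n)
        seq = genome[start:end]
        strand = "+"
        if rng is not None and rc_prob > 0 and rng.random() < rc_prob:
            seq = revcomp(seq)
            strand = "-"
        if rng is not None and error_rate > 0:
            seq = _substitute(seq, error_rate, rng)
        cid = f"{label}__c{k + 1}"
        contigs.append(Contig(cid, seq))
        truth[cid] = TruthEntry(cid, start, end, strand)
    return Assembly(label, contigs), truth


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def true_alignments(
    asm1: Assembly,
    asm2: Assembly,
    truth: dict[str, TruthEntry],
) -> AlignmentSet:
    """Exact overlap alignments between two fragmentations of one genome."""
    alignments: list[Alignment] = []
    for c1 in asm1:
        t1 = truth[c1.id]
        for c2 in asm2:
            t2 = truth[c2.id]
            lo = max(t1.start, t2.start)
            hi = min(t1.end, t2.end)
            if hi <= lo:
                continue
            b1, e1 = _to_contig_coords(t1, lo, hi)
            b2, e2 = _to_contig_coords(t2, lo, hi)
            alignments.append(
                Alignment(
                    c1.id, c2.id, b1, e1, b2, e2, hi - lo,
                    reversed_j=t1.strand != t2.strand,
                )
            )
    return AlignmentSet(alignments, combine([asm1, asm2]).index)


def _to_contig_coords(t: TruthEntry, lo: int, hi: int) -> tuple[int, int]:
    if t.strand == "+":
        return lo - t.start, hi - t.start
    return t.end - hi, t.end - lo


def staggered_offsets(
    spec: SimSpec, rng: np.random.Generator
) -> list[list[int]]:
    """Breakpoint lists for ``n_assemblies`` staggered tilings of a genome.

    A common set of anchor positions (spaced at least ``min_fragment``) is
    shifted per assembly by multiples of a per-anchor stagger, so that the
    terminal overlap between contigs of consecutive assemblies at each
    junction falls in ``[overlap_min, overlap_max]``.
    """
    n = spec.n_assemblies
    max_shift = spec.overlap_max // max(1, n - 1)
    if max_shift < spec.overlap_min:
        raise ValueError("overlap band too narrow for this many assemblies")
    anchors: list[int] = []
    pos = spec.min_fragment
    while pos + spec.min_fragment + spec.overlap_max < spec.genome_length:
        anchors.append(pos + int(rng.integers(0, spec.min_fragment // 4 + 1)))
        pos += spec.min_fragment
    staggers = [
        int(rng.integers(spec.overlap_min, max_shift + 1)) for _ in anchors
    ]
    return [
        [0] + [a + k * s for a, s in zip(anchors, staggers)] for k in range(n)
    ]


def simulate(spec: SimSpec) -> tuple[str, list[Assembly], dict[str, TruthEntry]]:
    """Simulate a genome and ``n_assemblies`` staggered abutting tilings.

    Contigs within one assembly abut exactly; the staggering between
    assemblies produces the terminal contig-contig overlaps.
    """
    rng = np.random.default_rng(spec.seed)
    genome = simulate_genome(spec.genome_length, spec.gc, rng)
    assemblies: list[Assembly] = []
    truth: dict[str, TruthEntry] = {}
    for k, offsets in enumerate(staggered_offsets(spec, rng)):
        asm, t = fragment(
            genome,
            offsets,
            0,
            label=f"asm{k + 1}",
            rng=rng,
            rc_prob=spec.rc_prob,
            error_rate=spec.error_rate,
        )
        assemblies.append(asm)
        truth.update(t)
    return genome, assemblies, truth


def all_pairwise_true_alignments(
    assemblies: list[Assembly], truth: dict[str, TruthEntry]
) -> AlignmentSet:
    """Union of true alignments over every assembly pair."""
    alignments: list[Alignment] = []
    for i in range(len(assemblies)):
        for j in range(i + 1, len(assemblies)):
            alignments.extend(
                true_alignments(assemblies[i], assemblies[j], truth).alignments
            )
    return AlignmentSet(alignments, combine(assemblies).index)
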