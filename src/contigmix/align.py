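"""Alignment backends.

The built-in finder detects maximal exact suffix/prefix (dovetail) overlaps
between contigs of different assemblies, on either strand, so the pipeline
never requires an external aligner.  A thin ``nucmer``/``show-coords``
subprocess wrapper is provided as an optional convenience.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

from .io_model import (
    Alignment,
    AlignmentSet,
    Assembly,
    Contig,
    combine,
    parse_coords,
    revcomp,
    write_fasta,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 200


def _longest_suffix_prefix(x: str, y: str, min_len: int) -> int:
    """Largest k >= min_len with x[-k:] == y[:k], or 0."""
    for k in range(min(len(x), len(y)) - 1, min_len - 1, -1):
        if x[-k:] == y[:k]:
            return k
    return 0


def exact_overlaps(
    assemblies: Sequence[Assembly], min_len: int = DEFAULT_MIN_OVERLAP
) -> AlignmentSet:
    """Maximal exact dovetail overlaps between contigs of different assemblies."""
    alignments: list[Alignment] = []
    for ai in range(len(assemblies)):
        for aj in range(ai + 1, len(assemblies)):
            for ci in assemblies[ai]:
                for cj in assemblies[aj]:
                    alignments.extend(_pair_overlaps(ci, cj, min_len))
    return AlignmentSet(alignments, combine(assemblies).index)


def _pair_overlaps(ci: Contig, cj: Contig, min_len: int) -> list[Alignment]:
    out: list[Alignment] = []
    rc_j = revcomp(cj.seq)
    # suffix(ci) ~ prefix(cj), forward
    k = _longest_suffix_prefix(ci.seq, cj.seq, min_len)
    if k:
        out.append(Alignment(ci.id, cj.id, len(ci) - k, len(ci), 0, k, k, False))
    # suffix(cj) ~ prefix(ci), forward
    k = _longest_suffix_prefix(cj.seq, ci.seq, min_len)
    if k:
        out.append(Alignment(ci.id, cj.id, 0, k, len(cj) - k, len(cj), k, False))
    # suffix(ci) ~ prefix(revcomp(cj)): aligned region is cj's suffix
    k = _longest_suffix_prefix(ci.seq, rc_j, min_len)
    if k:
        out.append(Alignment(ci.id, cj.id, len(ci) - k, len(ci), len(cj) - k, len(cj), k, True))
    # suffix(revcomp(cj)) ~ prefix(ci): aligned region is cj's prefix
    k = _longest_suffix_prefix(rc_j, ci.seq, min_len)
    if k:
        out.append(Alignment(ci.id, cj.id, 0, k, 0, k, k, True))
    return out


def nucmer_available() -> bool:
    return shutil.which("nucmer") is not None and shutil.which("show-coords") is not None


def run_nucmer(
    asm1: Assembly, asm2: Assembly, contigs: dict[str, Contig]
) -> AlignmentSet:
    """Align two assemblies with nucmer and parse ``show-coords -rcl -T``."""
    if not nucmer_available():
        raise RuntimeError("nucmer/show-coords not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        ref = Path(tmp) / "ref.fa"
        qry = Path(tmp) / "qry.fa"
        write_fasta(asm1, ref)
        write_fasta(asm2, qry)
        prefix = Path(tmp) / "out"
        subprocess.run(
            ["nucmer", "--prefix", str(prefix), str(ref), str(qry)],
            check=True,
            capture_output=True,
        )
        coords = subprocess.run(
            ["show-coords", "-rcl", "-T", f"{prefix}.delta"],
            check=True,
            capture_output=True,
            text=True,
        )
        coords_path = Path(tmp) / "coords.tsv"
        coords_path.write_text(coords.stdout)
        return parse_coords(coords_path, contigs)
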