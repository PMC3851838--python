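from __future__ import annotations

import numpy as np
import pytest

from contigmix.io_model import Alignment, AlignmentSet, Assembly, Contig


def make_contigs(lengths: dict[str, int], seed: int = 0) -> dict[str, Contig]:
    """Random contigs with the requested lengths (content rarely matters)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        cid: Contig(cid, "".join(rng.choice(bases, size=n)))
        for cid, n in lengths.items()
    }


def aset_from(rows: list[tuple], contigs: dict[str, Contig]) -> AlignmentSet:
    """Rows are (ci, cj, bi, ei, bj, ej[, reversed_j]); l is derived."""
    alignments = []
    for row in rows:
        ci, cj, bi, ei, bj, ej = row[:6]
        rev = bool(row[6]) if len(row) > 6 else False
        alignments.append(Alignment(ci, cj, bi, ei, bj, ej, ei - bi, rev))
    return AlignmentSet(alignments, contigs)


@pytest.fixture
def dovetail_pair() -> tuple[AlignmentSet, dict[str, Contig]]:
    """A(|100|) end overlaps B(|80|) start by 20 bases."""
    contigs = make_contigs({"A": 100, "B": 80})
    aset = aset_from([("A", "B", 80, 100, 0, 20)], contigs)
    return aset, contigs


@pytest.fixture
def tiny_overlap() -> tuple[AlignmentSet, Assembly]:
    """A='ACGTACGTAA', B='TAAGGC' with exact terminal overlap 'TAA'."""
    a = Contig("A", "ACGTACGTAA")
    b = Contig("B", "TAAGGC")
    combined = Assembly("combined", [a, b])
    aset = AlignmentSet(
        [Alignment("A", "B", 7, 10, 0, 3, 3, False)], combined.index
    )
    return aset, combined
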