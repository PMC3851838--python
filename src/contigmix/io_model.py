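"""Domain types and I/O: contigs, assemblies, alignments.

Internal coordinate convention is 0-based half-open throughout.  The
``show-coords`` tabular dialect (1-based inclusive, descending query
coordinates on the reverse strand) is converted on ingest.  The single
alignment length ``l`` is the span on the first (reference-side) contig,
``l = ei - bi``; the span on the second contig may differ when the aligner
reported indels and is available as :attr:`Alignment.span_j`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

LABEL_SEP = "__"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse-complement of a sequence over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and map any character outside {A,C,G,T,N} to N."""
    seq = seq.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    return "".join(c if c in _VALID_BASES else "N" for c in seq)


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence; the atom of every assembly."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """An ordered collection of contigs with unique ids."""

    label: str
    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("assembly label must be non-empty")
        seen: set[str] = set()
        for c in self.contigs:
            if c.id in seen:
                raise ValueError(f"duplicate contig id {c.id!r} in assembly {self.label!r}")
            seen.add(c.id)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def index(self) -> dict[str, Contig]:
        return {c.id: c for c in self.contigs}

    def lengths(self) -> list[int]:
        return [len(c) for c in self.contigs]

    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


def combine(assemblies: Sequence[Assembly], label: str = "combined") -> Assembly:
    """Union of several assemblies; ids must already be globally unique."""
    contigs: list[Contig] = []
    for asm in assemblies:
        contigs.extend(asm.contigs)
    return Assembly(label, contigs)


@dataclass(frozen=True)
class Alignment:
    """A local alignment between two contigs.

    ``(bi, ei)`` and ``(bj, ej)`` are 0-based half-open footprints on the
    two contigs; ``l`` is the reference-side span ``ei - bi``.  When the
    second contig is read reverse-complemented, ``reversed_j`` is True and
    ``(bj, ej)`` are forward-strand coordinates of the aligned region.
    """

    ci: str
    cj: str
    bi: int
    ei: int
    bj: int
    ej: int
    l: int
    reversed_j: bool = False

    def __post_init__(self) -> None:
        if not self.ci or not self.cj:
            raise ValueError("alignment contig ids must be non-empty")
        if not (0 <= self.bi < self.ei):
            raise ValueError(f"invalid i-footprint [{self.bi},{self.ei}) on {self.ci}")
        if not (0 <= self.bj < self.ej):
            raise ValueError(f"invalid j-footprint [{self.bj},{self.ej}) on {self.cj}")
        if self.l != self.ei - self.bi:
            raise ValueError(
                f"alignment length l={self.l} != ei-bi={self.ei - self.bi} "
                f"for {self.ci} vs {self.cj}"
            )

    @property
    def span_j(self) -> int:
        return self.ej - self.bj

    @property
    def pair(self) -> tuple[str, str]:
        return (self.ci, self.cj)

    def key(self) -> tuple:
        return (self.ci, self.cj, self.bi, self.ei, self.bj, self.ej, self.reversed_j)


@dataclass
class AlignmentSet:
    """A collection of alignments plus the contig index resolving their ids."""

    alignments: list[Alignment]
    contigs: dict[str, Contig]
    skipped_unknown: int = 0

    def __post_init__(self) -> None:
        for a in self.alignments:
            for cid, end in ((a.ci, a.ei), (a.cj, a.ej)):
                contig = self.contigs.get(cid)
                if contig is None:
                    raise ValueError(f"alignment references unknown contig {cid!r}")
                if end > len(contig):
                    raise ValueError(
                        f"alignment end {end} exceeds |{cid}| = {len(contig)}"
                    )

    def __len__(self) -> int:
        return len(self.alignments)

    def __iter__(self) -> Iterator[Alignment]:
        return iter(self.alignments)

    def with_alignments(self, alignments: Iterable[Alignment]) -> "AlignmentSet":
        return AlignmentSet(list(alignments), self.contigs, self.skipped_unknown)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, label: str | None = None) -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Sequences are uppercased and non-ACGTN characters are mapped to N.
    Record order is preserved.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, normalize_seq(str(rec.seq))))
    if not contigs:
        raise ValueError(f"no contigs found in {path}")
    return Assembly(label or path.stem, contigs)


def write_fasta(
    assembly: Assembly,
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    """Write an assembly as FASTA, wrapped at 80 columns."""
    records = []
    for c in assembly:
        desc = descriptions.get(c.id, "") if descriptions else ""
        records.append(SeqRecord(Seq(c.seq), id=c.id, description=desc))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=80)
    writer.write_file(records)


def prefix_ids(assembly: Assembly, label: str) -> Assembly:
    """Prefix every contig id with ``<label>__`` for global uniqueness."""
    if not label:
        raise ValueError("label must be non-empty")
    if LABEL_SEP in label:
        raise ValueError(f"label must not contain {LABEL_SEP!r}: {label!r}")
    contigs = [replace(c, id=f"{label}{LABEL_SEP}{c.id}") for c in assembly]
    return Assembly(label, contigs)


# ---------------------------------------------------------------------------
# Alignment parsing


def _coords_row_to_alignment(fields: list[str]) -> Alignment:
    s1, e1, s2, e2 = (int(x) for x in fields[:4])
    ref_id, qry_id = fields[-2], fields[-1]
    if s1 > e1:  # defensive: reference side is normally ascending
        s1, e1 = e1, s1
        s2, e2 = e2, s2
    bi, ei = s1 - 1, e1
    if s2 <= e2:
        bj, ej, rev = s2 - 1, e2, False
    else:
        bj, ej, rev = e2 - 1, s2, True
    return Alignment(ref_id, qry_id, bi, ei, bj, ej, ei - bi, rev)


def parse_coords(path: str | Path, contigs: Mapping[str, Contig]) -> AlignmentSet:
    """Parse nucmer ``show-coords -rcl -T`` tabular output.

    1-based inclusive coordinates are converted to 0-based half-open; a
    descending query interval marks a reverse-strand alignment.  Rows naming
    contigs absent from ``contigs`` are skipped with a warning count
    (exposed as :attr:`AlignmentSet.skipped_unknown`).
    """
    path = Path(path)
    alignments: list[Alignment] = []
    skipped = 0
    data_started = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            is_data = fields[0].lstrip("-").isdigit()
            if not is_data:
                if data_started:
                    raise ValueError(f"{path}:{lineno}: malformed row: {line!r}")
                continue  # header (path line, NUCMER, [S1] banner, bars)
            data_started = True
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}")
            try:
                aln = _coords_row_to_alignment(fields)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}") from exc
            if aln.ci not in contigs or aln.cj not in contigs:
                skipped += 1
                logger.warning("%s:%d: unknown contig id, row skipped", path, lineno)
                continue
            alignments.append(aln)
    return AlignmentSet(alignments, dict(contigs), skipped_unknown=skipped)


TSV_COLUMNS = ["ci", "cj", "bi", "ei", "bj", "ej", "l", "reversed_j"]


def parse_tsv(path: str | Path, contigs: Mapping[str, Contig]) -> AlignmentSet:
    """Parse the internal alignment TSV dialect (already 0-based half-open)."""
    path = Path(path)
    alignments: list[Alignment] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(f"{path}: expected header {TSV_COLUMNS}, got {header}")
        for rowno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(TSV_COLUMNS):
                raise ValueError(f"{path}:{rowno}: expected {len(TSV_COLUMNS)} columns")
            try:
                aln = Alignment(
                    fields[0],
                    fields[1],
                    int(fields[2]),
                    int(fields[3]),
                    int(fields[4]),
                    int(fields[5]),
                    int(fields[6]),
                    fields[7].lower() in ("1", "true", "yes"),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{rowno}: {exc}") from exc
            alignments.append(aln)
    return AlignmentSet(alignments, dict(contigs))


def write_tsv(aset: AlignmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for a in aset:
            fh.write(
                f"{a.ci}\t{a.cj}\t{a.bi}\t{a.ei}\t{a.bj}\t{a.ej}\t{a.l}\t"
                f"{'true' if a.reversed_j else 'false'}\n"
            )
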