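"""Reading and validation of ELAND3 mapping files and chromosome-size tables.

The ELAND3 dialect is the per-occurrence output of the SeqMap aligner run
with ``/output_all_matches``: one tab-separated line per mapping occurrence,
sorted by genome coordinate within each target sequence.  The default column
order is SeqMap's documented one::

    target  coordinate  target_seq  read_id  read_seq  mismatches  strand

Coordinates are 1-based inclusive.  A read that maps to several genomic
positions appears on several lines with the same read sequence; the parser
deduplicates reads by sequence and counts the occurrences as the read's
``genomic_hits``.  Read identifiers may carry the sequencing frequency of
the read (its copy number), e.g. ``piR-7_x15``; the trailing integer is
extracted with a configurable pattern.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Default pattern for extracting a read's copy number from its identifier:
#: the integer following the last non-digit character.
DEFAULT_COUNT_PATTERN = r"(\d+)$"

#: Default ELAND3 column order (SeqMap): indices of
#: (target, coordinate, target_seq, read_id, read_seq, mismatches, strand).
DEFAULT_COLUMNS = (0, 1, 2, 3, 4, 5, 6)

_VALID_BASES = frozenset("ACGTN")
_STRANDS = frozenset("+-")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class MappedRead:
    """A distinct sequenced small-RNA read.

    ``copy_number`` is the sequencing frequency parsed from the identifier
    (1 when absent); ``genomic_hits`` is the number of genomic positions the
    read maps to, i.e. its number of occurrences in the input file.
    """

    read_id: str
    sequence: str
    copy_number: int = 1
    genomic_hits: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if self.copy_number < 1 or self.genomic_hits < 1:
            raise ValueError("copy_number and genomic_hits must be >= 1")


@dataclass
class GenomicHit:
    """One mapping occurrence of a read: a putative piRNA locus.

    ``start``/``end`` are 1-based inclusive genome coordinates.
    """

    chromosome: str
    start: int
    end: int
    strand: str
    read: MappedRead
    mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("chromosome name must be non-empty")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def normalize_sequence(seq: str) -> str:
    """Uppercase a read sequence and convert RNA U to DNA T."""
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise FormatError(f"invalid base(s) {sorted(bad)} in read sequence {seq!r}")
    return seq


def parse_copy_number(read_id: str, pattern: str | None = DEFAULT_COUNT_PATTERN) -> int:
    """Extract a copy number from a read identifier; 1 when no match."""
    if not pattern:
        return 1
    m = re.search(pattern, read_id)
    if not m:
        return 1
    try:
        value = int(m.group(1) if m.groups() else m.group(0))
    except ValueError:
        return 1
    return max(1, value)


def parse_eland3(
    path: str | Path,
    count_pattern: str | None = DEFAULT_COUNT_PATTERN,
    columns: Sequence[int] = DEFAULT_COLUMNS,
    max_mismatches: int | None = None,
) -> tuple[list[GenomicHit], list[MappedRead]]:
    """Parse an ELAND3 mapping file into hits and deduplicated reads.

    Parameters
    ----------
    path
        Tab-separated mapping file, coordinate-sorted within each chromosome.
    count_pattern
        Regex with one capture group applied to read identifiers to extract
        the copy number.  ``None`` disables extraction (all copies = 1).
    columns
        Indices of (target, coordinate, target_seq, read_id, read_seq,
        mismatches, strand) for non-standard column orders.
    max_mismatches
        Optional filter: occurrences with more mismatches are dropped.

    Returns
    -------
    (hits, reads)
        One :class:`GenomicHit` per retained line, in file order, and the
        distinct :class:`MappedRead` objects (deduplicated by normalized
        sequence) with ``genomic_hits`` set to the per-read occurrence count
        across the whole file (before any mismatch filter).
    """
    path = Path(path)
    (i_tgt, i_coord, _i_tseq, i_rid, i_rseq, i_mm, i_strand) = columns
    need = max(columns) + 1

    reads: dict[str, MappedRead] = {}
    raw: list[tuple[str, int, str, str, int]] = []  # chrom, start, strand, seq, mm
    last_coord: dict[str, int] = {}

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < need:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {need} tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[i_tgt]
            try:
                coord = int(fields[i_coord])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate "
                                  f"{fields[i_coord]!r}") from None
            strand = fields[i_strand]
            if strand not in _STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand symbol "
                                  f"{strand!r} (expected '+' or '-')")
            try:
                mm = int(fields[i_mm])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer mismatch count "
                                  f"{fields[i_mm]!r}") from None
            if mm < 0:
                raise FormatError(f"{path}:{lineno}: negative mismatch count")
            try:
                seq = normalize_sequence(fields[i_rseq])
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None

            if chrom in last_coord and coord < last_coord[chrom]:
                raise FormatError(
                    f"{path}:{lineno}: coordinates on {chrom} are not sorted "
                    f"({coord} after {last_coord[chrom]}); sort the input by "
                    f"genome coordinate first"
                )
            last_coord[chrom] = coord

            read = reads.get(seq)
            if read is None:
                reads[seq] = MappedRead(
                    read_id=fields[i_rid],
                    sequence=seq,
                    copy_number=parse_copy_number(fields[i_rid], count_pattern),
                    genomic_hits=1,
                )
            else:
                read.genomic_hits += 1
            raw.append((chrom, coord, strand, seq, mm))

    hits: list[GenomicHit] = []
    for chrom, coord, strand, seq, mm in raw:
        if max_mismatches is not None and mm > max_mismatches:
            continue
        read = reads[seq]
        hits.append(
            GenomicHit(
                chromosome=chrom,
                start=coord,
                end=coord + len(seq) - 1,
                strand=strand,
                read=read,
                mismatches=mm,
            )
        )
    return hits, list(reads.values())


def write_eland3(hits: Iterable[GenomicHit], path: str | Path) -> None:
    """Write hits back out in the default ELAND3 column order."""
    path = Path(path)
    with path.open("w") as fh:
        for h in hits:
            fh.write(
                f"{h.chromosome}\t{h.start}\t{h.read.sequence}\t"
                f"{h.read.read_id}\t{h.read.sequence}\t{h.mismatches}\t{h.strand}\n"
            )


def read_chrom_sizes(
    path: str | Path | None,
    hits: Sequence[GenomicHit] = (),
) -> dict[str, int]:
    """Load a two-column chromosome-sizes table, with a fallback from hits.

    When ``path`` is None (or a chromosome with hits is absent from the
    file), the chromosome length falls back to the maximum hit end
    coordinate, logged as approximate.  A declared length shorter than a
    hit's end coordinate is an error.
    """
    sizes: dict[str, int] = {}
    if path is not None:
        path = Path(path)
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected two columns (name, length)"
                    )
                try:
                    length = int(parts[1])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer length {parts[1]!r}"
                    ) from None
                if length < 1:
                    raise FormatError(f"{path}:{lineno}: length must be >= 1")
                sizes[parts[0]] = length

    max_end: dict[str, int] = {}
    for h in hits:
        max_end[h.chromosome] = max(max_end.get(h.chromosome, 0), h.end)

    for chrom, end in max_end.items():
        if chrom in sizes:
            if end > sizes[chrom]:
                raise FormatError(
                    f"hit ends at {end} on {chrom} but declared length is "
                    f"{sizes[chrom]}"
                )
        else:
            logger.warning(
                "no declared length for %s; using approximate fallback %d "
                "(maximum hit end coordinate)", chrom, end,
            )
            sizes[chrom] = end
    return sizes
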