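"""Whole-dataset statistics consumed by every cluster score.

All ratios are locus-weighted: each genomic mapping occurrence (hit) counts
once, so a read mapping to ten positions contributes ten loci.  This matches
the scoring model, which compares cluster loci against the dataset's loci.

The normalized-hits machinery partitions the distinct reads into 8 groups by
ascending number of genomic hits per read (quantile split); ``a_i`` is the
mean hit count ascribed to every read of group i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_eland3 import GenomicHit, MappedRead

N_GROUPS = 8

#: Default typical piRNA length range in nt (~26-32 nt mature piRNAs).
DEFAULT_TYPICAL_LENGTH = (26, 32)


@dataclass(frozen=True)
class HitGroup:
    """One of the 8 read groups: size and mean genomic hits per read."""

    n_reads: int
    mean_hits: float


@dataclass
class DatasetProfile:
    """Dataset-wide statistics: base-composition and length ratios, the
    8-group read partition and per-chromosome hit totals."""

    total_reads: int
    total_hits: int
    ratio_1T: float
    ratio_10A: float
    ratio_typical_length: float
    groups: tuple[HitGroup, ...]
    per_chromosome: dict[str, int]

    def summary_lines(self) -> list[str]:
        """Plain-text report of the profile (logged at startup)."""
        lines = [
            f"distinct reads (R): {self.total_reads}",
            f"total genomic hits: {self.total_hits}",
            f"ratio 1T: {self.ratio_1T:.4f}",
            f"ratio 10A: {self.ratio_10A:.4f}",
            f"ratio typical length: {self.ratio_typical_length:.4f}",
            "group\treads\tmean hits/read",
        ]
        for i, g in enumerate(self.groups, start=1):
            lines.append(f"{i}\t{g.n_reads}\t{g.mean_hits:.3f}")
        return lines


def partition_groups(reads: Sequence[MappedRead]) -> tuple[HitGroup, ...]:
    """Split reads into 8 near-equal groups by ascending genomic hit count.

    Remainder reads go to the earliest groups.  With fewer than 8 reads some
    groups are empty; an empty group inherits the mean of the previous group
    so that the ``a_i`` sequence stays non-decreasing.
    """
    if not reads:
        raise ValueError("cannot partition an empty read list")
    counts = sorted(r.genomic_hits for r in reads)
    base, rem = divmod(len(counts), N_GROUPS)
    sizes = [base + 1] * rem + [base] * (N_GROUPS - rem)
    groups: list[HitGroup] = []
    idx = 0
    prev_mean = 1.0
    for size in sizes:
        if size == 0:
            groups.append(HitGroup(0, prev_mean))
            continue
        chunk = counts[idx:idx + size]
        idx += size
        prev_mean = sum(chunk) / size
        groups.append(HitGroup(size, prev_mean))
    return tuple(groups)


def build_profile(
    hits: Sequence[GenomicHit],
    reads: Sequence[MappedRead],
    typical_length: tuple[int, int] = DEFAULT_TYPICAL_LENGTH,
) -> DatasetProfile:
    """Compute the dataset profile from the parsed mapping model.

    1T means T at read position 1; 10A means A at position 10 (reads shorter
    than 10 nt never count as 10A).  Typical length means a read length
    within ``typical_length`` (inclusive).
    """
    if not hits:
        raise ValueError("cannot profile an empty hit list")
    lo, hi = typical_length
    n_1t = n_10a = n_typ = 0
    per_chrom: dict[str, int] = {}
    for h in hits:
        seq = h.read.sequence
        if seq[0] == "T":
            n_1t += 1
        if len(seq) >= 10 and seq[9] == "A":
            n_10a += 1
        if lo <= len(seq) <= hi:
            n_typ += 1
        per_chrom[h.chromosome] = per_chrom.get(h.chromosome, 0) + 1
    n = len(hits)
    return DatasetProfile(
        total_reads=len(reads),
        total_hits=n,
        ratio_1T=n_1t / n,
        ratio_10A=n_10a / n,
        ratio_typical_length=n_typ / n,
        groups=partition_groups(reads),
        per_chromosome=per_chrom,
    )
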