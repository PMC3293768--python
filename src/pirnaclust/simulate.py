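"""Synthetic small-RNA mapping landscapes with planted piRNA clusters.

The generator emulates the null and the signal the detector is built for:
background hits fall uniformly over each chromosome (so 1 kb window counts
are Poisson), while planted clusters concentrate loci with controllable
strand bias, 1T/10A base composition, read length distribution, per-read
genomic hit multiplicity (steering the NTR) and copy numbers.  Multi-mapping
reads are realized by emitting the same read sequence at several genomic
positions; for "uniform"-strand decoy regions the extra placements stay
inside the region, reproducing accumulations of multi-copy loci that are
not transcribed into piRNA precursors.

Everything is reproducible from the seed; output files are plain text in
the same ELAND3 / chrom-sizes dialects the parser consumes, plus a
tab-separated truth table of the planted spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedCluster:
    """Specification of one planted cluster region."""

    chromosome: str
    start: int
    span: int
    n_loci: int
    strand_mode: str = "mono"  # mono | bi | uniform
    p_main: float = 0.9
    main_strand: str = "+"
    t1_prob: float = 0.75
    a10_prob: float = 0.25
    length_range: tuple[int, int] = (26, 32)
    #: genomic hit multiplicities drawn uniformly from these choices
    multiplicity_choices: tuple[int, ...] = (1,)
    copy_range: tuple[int, int] = (1, 20)

    @property
    def end(self) -> int:
        return self.start + self.span - 1


@dataclass(frozen=True)
class SimSpec:
    """Full description of a synthetic landscape."""

    seed: int
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 10_000_000),)
    background_hits: int = 10_000
    background_length_range: tuple[int, int] = (18, 35)
    background_t1_prob: float = 0.25
    background_a10_prob: float = 0.25
    background_multi_fraction: float = 0.1
    background_multi_range: tuple[int, int] = (2, 20)
    background_copy_range: tuple[int, int] = (1, 20)
    planted: tuple[PlantedCluster, ...] = ()

    def validate(self) -> None:
        sizes = dict(self.chromosomes)
        for pc in self.planted:
            if pc.chromosome not in sizes:
                raise ValueError(f"planted cluster on unknown chromosome "
                                 f"{pc.chromosome}")
            if pc.end > sizes[pc.chromosome]:
                raise ValueError(
                    f"planted span {pc.start}-{pc.end} exceeds {pc.chromosome} "
                    f"length {sizes[pc.chromosome]}"
                )
            for p in (pc.p_main, pc.t1_prob, pc.a10_prob):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class SimResult:
    eland3_path: Path
    chrom_sizes_path: Path
    truth_path: Path


def _random_sequence(rng: np.random.Generator, length: int,
                     t1: bool, a10: bool) -> str:
    seq = _BASES[rng.integers(0, 4, size=length)]
    if t1:
        seq[0] = "T"
    elif seq[0] == "T":
        seq[0] = _BASES[rng.integers(0, 3)]  # A, C or G
    if length >= 10:
        if a10:
            seq[9] = "A"
        elif seq[9] == "A":
            seq[9] = _BASES[1 + rng.integers(0, 3)]  # C, G or T
    return "".join(seq)


def _unique_sequence(rng: np.random.Generator, length: int, t1: bool,
                     a10: bool, seen: set[str]) -> str:
    for _ in range(100):
        seq = _random_sequence(rng, length, t1, a10)
        if seq not in seen:
            seen.add(seq)
            return seq
    raise RuntimeError("could not draw a unique read sequence")  # pragma: no cover


def _uniform_position(rng: np.random.Generator,
                      chromosomes: Sequence[tuple[str, int]],
                      read_len: int) -> tuple[str, int]:
    lengths = np.array([length for _, length in chromosomes], dtype=float)
    idx = int(rng.choice(len(chromosomes), p=lengths / lengths.sum()))
    name, length = chromosomes[idx]
    pos = int(rng.integers(1, max(2, length - read_len + 1)))
    return name, pos


def generate(spec: SimSpec) -> tuple[list[str], list[str]]:
    """Build the ELAND3 lines (coordinate-sorted) and truth-table rows."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    placements: list[tuple[str, int, str, str, str]] = []
    # (chrom, pos, read_seq, read_id, strand)
    read_counter = 0

    def new_read_id(copies: int) -> str:
        nonlocal read_counter
        read_counter += 1
        return f"r{read_counter:06d}_x{copies}"

    # --- background ---
    remaining = spec.background_hits
    lo_len, hi_len = spec.background_length_range
    while remaining > 0:
        multi = rng.random() < spec.background_multi_fraction
        k = int(rng.integers(spec.background_multi_range[0],
                             spec.background_multi_range[1] + 1)) if multi else 1
        k = min(k, remaining)
        length = int(rng.integers(lo_len, hi_len + 1))
        seq = _unique_sequence(
            rng, length,
            t1=rng.random() < spec.background_t1_prob,
            a10=rng.random() < spec.background_a10_prob,
            seen=seen,
        )
        copies = int(rng.integers(spec.background_copy_range[0],
                                  spec.background_copy_range[1] + 1))
        rid = new_read_id(copies)
        for _ in range(k):
            chrom, pos = _uniform_position(rng, spec.chromosomes, length)
            strand = "+" if rng.random() < 0.5 else "-"
            placements.append((chrom, pos, seq, rid, strand))
        remaining -= k

    # --- planted clusters ---
    truth_rows = []
    for pc in spec.planted:
        lo, hi = pc.length_range
        for _ in range(pc.n_loci):
            length = int(rng.integers(lo, hi + 1))
            pos = int(rng.integers(pc.start, pc.end - length + 2))
            if pc.strand_mode == "mono":
                other = "-" if pc.main_strand == "+" else "+"
                strand = pc.main_strand if rng.random() < pc.p_main else other
            elif pc.strand_mode == "bi":
                midpoint = pc.start + pc.span // 2
                main = "-" if pos < midpoint else "+"
                other = "+" if main == "-" else "-"
                strand = main if rng.random() < pc.p_main else other
            elif pc.strand_mode == "uniform":
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                raise ValueError(f"unknown strand mode {pc.strand_mode!r}")
            seq = _unique_sequence(
                rng, length,
                t1=rng.random() < pc.t1_prob,
                a10=rng.random() < pc.a10_prob,
                seen=seen,
            )
            copies = int(rng.integers(pc.copy_range[0], pc.copy_range[1] + 1))
            rid = new_read_id(copies)
            mult = int(rng.choice(pc.multiplicity_choices))
            placements.append((pc.chromosome, pos, seq, rid, strand))
            for _ in range(mult - 1):
                if pc.strand_mode == "uniform":
                    # multi-copy accumulation: extra placements stay in-region
                    pos2 = int(rng.integers(pc.start, pc.end - length + 2))
                    strand2 = "+" if rng.random() < 0.5 else "-"
                    placements.append((pc.chromosome, pos2, seq, rid, strand2))
                else:
                    chrom2, pos2 = _uniform_position(rng, spec.chromosomes, length)
                    strand2 = "+" if rng.random() < 0.5 else "-"
                    placements.append((chrom2, pos2, seq, rid, strand2))
        truth_rows.append(
            f"{pc.chromosome}\t{pc.start}\t{pc.end}\t{pc.n_loci}\t"
            f"{pc.strand_mode}\t{pc.p_main:g}\t{pc.t1_prob:g}"
        )

    placements.sort(key=lambda p: (p[0], p[1]))
    lines = [
        f"{chrom}\t{pos}\t{seq}\t{rid}\t{seq}\t0\t{strand}"
        for chrom, pos, seq, rid, strand in placements
    ]
    return lines, truth_rows


def simulate(spec: SimSpec, out_dir: str | Path) -> SimResult:
    """Write the ELAND3 file, chrom-sizes file and truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines, truth_rows = generate(spec)
    eland3 = out_dir / "mapped.eland3"
    eland3.write_text("".join(line + "\n" for line in lines))
    sizes = out_dir / "chrom.sizes"
    sizes.write_text(
        "".join(f"{name}\t{length}\n" for name, length in spec.chromosomes)
    )
    truth = out_dir / "truth.tsv"
    truth.write_text(
        "chromosome\tstart\tend\tn_loci\tstrand_mode\tp_main\tt1_prob\n"
        + "".join(row + "\n" for row in truth_rows)
    )
    return SimResult(eland3, sizes, truth)


def landscape_spec(
    seed: int,
    n_clusters: int = 10,
    loci_per_cluster: int = 50,
    chrom_length: int = 10_000_000,
    background_hits: int = 10_000,
    cluster_span: int = 5_000,
) -> SimSpec:
    """Standard benchmark landscape: uniform background at ~1 hit/kb with
    mono-directional planted clusters at regular, well-separated positions."""
    gap = chrom_length // (n_clusters + 1)
    planted = tuple(
        PlantedCluster(
            chromosome="chr1",
            start=(i + 1) * gap,
            span=cluster_span,
            n_loci=loci_per_cluster,
        )
        for i in range(n_clusters)
    )
    return SimSpec(
        seed=seed,
        chromosomes=(("chr1", chrom_length),),
        background_hits=background_hits,
        planted=planted,
    )


def toy_spec(seed: int = 20120110) -> SimSpec:
    """A small worked example: one mono-directional cluster, one
    bi-directional cluster and one decoy (a uniform-strand accumulation of
    multi-copy loci that mimics cluster-like density without transcription).
    """
    return SimSpec(
        seed=seed,
        chromosomes=(("chr1", 1_000_000),),
        background_hits=30,
        background_length_range=(18, 25),  # atypical, so length enrichment scores
        planted=(
            PlantedCluster("chr1", 100_001, 3_000, 25, strand_mode="mono",
                           p_main=0.95, t1_prob=0.9),
            PlantedCluster("chr1", 500_001, 4_000, 25, strand_mode="bi",
                           p_main=0.95, t1_prob=0.9),
            PlantedCluster("chr1", 800_001, 2_000, 4, strand_mode="uniform",
                           t1_prob=0.25, multiplicity_choices=(5,),
                           copy_range=(1, 5)),
        ),
    )


def toy_fixture(out_dir: str | Path, seed: int = 20120110) -> SimResult:
    """Write the worked-example fixture used in docs and golden tests."""
    return simulate(toy_spec(seed), out_dir)
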