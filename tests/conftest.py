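"""Shared builders for synthetic reads, hits and candidates."""

from __future__ import annotations

import itertools

import pytest

from pirnaclust.detection import ClusterCandidate
from pirnaclust.io_eland3 import GenomicHit, MappedRead

_counter = itertools.count(1)


def make_read(seq: str = "T" * 28, copies: int = 1, hits: int = 1,
              rid: str | None = None) -> MappedRead:
    if rid is None:
        rid = f"read{next(_counter)}_x{copies}"
    return MappedRead(read_id=rid, sequence=seq, copy_number=copies,
                      genomic_hits=hits)


def make_hit(start: int, strand: str = "+", chrom: str = "chr1",
             seq: str = "T" * 28, read: MappedRead | None = None,
             hits: int = 1) -> GenomicHit:
    if read is None:
        read = make_read(seq=seq, hits=hits)
    return GenomicHit(chromosome=chrom, start=start,
                      end=start + len(read.sequence) - 1, strand=strand,
                      read=read)


def make_candidate(positions: list[int], strands: str | list[str] = "+",
                   chrom: str = "chr1", **hit_kwargs) -> ClusterCandidate:
    if isinstance(strands, str):
        strands = [strands] * len(positions)
    hits = [make_hit(p, s, chrom=chrom, **hit_kwargs)
            for p, s in zip(sorted(positions), strands)]
    return ClusterCandidate(chromosome=chrom, hits=hits)


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    """The worked-example fixture: mono + bi cluster and a decoy."""
    from pirnaclust.simulate import toy_fixture

    out = tmp_path_factory.mktemp("toy")
    return toy_fixture(out)
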