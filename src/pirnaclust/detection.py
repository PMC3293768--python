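"""Sliding-window cluster candidate detection and peripheral clipping.

Detection tags every window of ``min_loci`` consecutive hits whose spanned
region reaches the chromosome's minimum hit density; maximal runs of
contiguously tagged hits become cluster candidates.  Overlapping dense
sections can assemble into one large candidate that as a whole falls below
the minimum density; such candidates are refined by stepwise clipping of
peripheral hits, keeping the largest possible sub-cluster that satisfies
the density requirement.  Clipped-off hits may form clusters of their own
and re-enter the candidate queue once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_eland3 import GenomicHit


@dataclass
class ClusterCandidate:
    """A contiguous run of hits on one chromosome, spanning from the first
    hit start to the last hit end."""

    chromosome: str
    hits: list[GenomicHit]
    provenance: str = "primary"  # primary | clipped-remainder | rescue

    def __post_init__(self) -> None:
        if not self.hits:
            raise ValueError("cluster candidate must contain hits")

    @property
    def start(self) -> int:
        return self.hits[0].start

    @property
    def end(self) -> int:
        return max(h.end for h in self.hits)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def density(self) -> float:
        """Hit density in hits/kb over the hit-boundary span."""
        return len(self.hits) * 1000.0 / self.span


def hit_density(hits: Sequence[GenomicHit]) -> float:
    span = max(h.end for h in hits) - hits[0].start + 1
    return len(hits) * 1000.0 / span


def slide_and_tag(
    hits: Sequence[GenomicHit],
    min_loci: int,
    min_density: float,
) -> list[ClusterCandidate]:
    """Tag dense windows of ``min_loci`` consecutive hits, then assemble
    maximal runs of tagged hits into candidates.

    ``hits`` must be coordinate-sorted and on a single chromosome.
    """
    if min_loci < 1:
        raise ValueError("min_loci must be >= 1")
    if min_density <= 0:
        raise ValueError("min_density must be positive")
    n = len(hits)
    if n < min_loci:
        return []
    window_starts = [
        i for i in range(n - min_loci + 1)
        if hit_density(hits[i:i + min_loci]) >= min_density
    ]
    # contiguously tagged loci: chains of overlapping qualifying windows
    candidates: list[ClusterCandidate] = []
    run_start: int | None = None
    run_end = -1
    for i in window_starts:
        if run_start is None:
            run_start, run_end = i, i + min_loci - 1
        elif i <= run_end:
            run_end = i + min_loci - 1
        else:
            run = list(hits[run_start:run_end + 1])
            candidates.append(ClusterCandidate(run[0].chromosome, run))
            run_start, run_end = i, i + min_loci - 1
    if run_start is not None:
        run = list(hits[run_start:run_end + 1])
        candidates.append(ClusterCandidate(run[0].chromosome, run))
    return candidates


def clip_peripheral(
    candidate: ClusterCandidate,
    min_density: float,
    min_loci: int,
) -> tuple[ClusterCandidate | None, list[ClusterCandidate]]:
    """Clip peripheral hits until the remaining cluster reaches the density.

    A candidate already at the required density is returned unchanged.
    Otherwise, for a growing total clip count c = 1, 2, ..., every split of
    c into u upstream and d downstream removals is tried; the first c that
    admits a remainder with density >= ``min_density`` and >= ``min_loci``
    hits stops the search, keeping the cluster with the maximal number of
    hits.  Ties among equal-c splits are broken by higher density, then by
    fewer upstream removals.  The clipped-off hits are returned as separate
    candidates (provenance "clipped-remainder") for subsequent assessment.
    """
    hits = candidate.hits
    n = len(hits)
    if candidate.density >= min_density:
        return candidate, []
    for c in range(1, n - min_loci + 1):
        best: tuple[float, int] | None = None  # (density, u)
        for u in range(0, c + 1):
            d = c - u
            rem = hits[u:n - d]
            dens = hit_density(rem)
            if dens >= min_density:
                if best is None or dens > best[0] or (dens == best[0] and u < best[1]):
                    best = (dens, u)
        if best is not None:
            u = best[1]
            d = c - u
            core = ClusterCandidate(candidate.chromosome, list(hits[u:n - d]),
                                    provenance=candidate.provenance)
            remainder = []
            if u:
                remainder.append(ClusterCandidate(candidate.chromosome,
                                                  list(hits[:u]),
                                                  provenance="clipped-remainder"))
            if d:
                remainder.append(ClusterCandidate(candidate.chromosome,
                                                  list(hits[n - d:]),
                                                  provenance="clipped-remainder"))
            return core, remainder
    return None, []


def detect_candidates(
    hits_by_chromosome: dict[str, list[GenomicHit]],
    per_chromosome_density: dict[str, float],
    min_loci: int,
) -> list[ClusterCandidate]:
    """Run sliding-window tagging and clipping over every chromosome.

    Clipped-off remainders re-enter the queue once: a remainder's own
    remainders are not processed further, so each hit is handled at most
    twice.
    """
    final: list[ClusterCandidate] = []
    for chrom in sorted(hits_by_chromosome):
        k = per_chromosome_density.get(chrom)
        if k is None:
            continue
        queue: list[tuple[ClusterCandidate, int]] = [
            (c, 0) for c in slide_and_tag(hits_by_chromosome[chrom], min_loci, k)
        ]
        while queue:
            cand, generation = queue.pop(0)
            if len(cand.hits) < min_loci:
                continue
            core, remainder = clip_peripheral(cand, k, min_loci)
            if core is not None:
                final.append(core)
            if generation == 0:
                queue.extend((r, 1) for r in remainder)
    return final
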