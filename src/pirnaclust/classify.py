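"""Cluster verification, directionality, rescue and set-level error rates.

piRNA clusters are typically transcribed mono-directionally (one strand) or
bi-directionally (two divergent halves flanking a central promoter).  The
degree of mono-directionality is the proportion of hits on the main strand;
the degree of bi-directionality is the best pro-rata combination of the two
fragment-wise main-strand proportions over every admissible split point
(each fragment must hold at least 25% of the hits or at least 10 hits).

A candidate becomes a cluster when every enabled characteristic score
reaches its configured minimum.  Rejected candidates whose strand asymmetry
was distorted by frequently mapped reads can optionally be rescued by
re-evaluating only the loci of reads mapping at most a stated maximum
number of times.

Each accepted cluster carries the combined probability that its observed
deviations from the uniform null arose by chance (the product of its
per-criterion tail probabilities); from these, the probabilities of 0,
1-or-more and 2-or-more mistakenly annotated clusters in the reported set
are derived under an independent-Bernoulli model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dataset import DEFAULT_TYPICAL_LENGTH, DatasetProfile
from .detection import ClusterCandidate, hit_density
from .io_eland3 import GenomicHit
from .scoring import NtrValue, ScoreSet, main_strand, score_candidate

logger = logging.getLogger(__name__)

_MIN_COMBINED_P = 1e-300

#: Criterion keys in reporting order.
CRITERIA = ("strand_bias", "typical_length", "t1_or_a10", "ntr")


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = 5) -> float:
    """Per-test significance level for a family-wise level over n tests."""
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family_alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


@dataclass
class RunConfig:
    """All thresholds and options of a detection run.

    Defaults encode the recommended preset: hit-density significance
    alpha = 0.01 and minimum scores of 2.0, i.e. the Bonferroni-corrected
    per-test level for a family-wise alpha of 0.05 over the five tests
    (density plus four characteristic scores).
    """

    alpha: float = bonferroni_alpha(0.05, 5)
    min_score_strand: float | None = 2.0
    min_score_length: float | None = 2.0
    min_score_t1a10: float | None = 2.0
    min_score_ntr: float | None = 2.0
    typical_length: tuple[int, int] = DEFAULT_TYPICAL_LENGTH
    directionality_threshold: float = 0.75
    rescue_max_hits: int | None = None  # rescue pass off unless set
    composition_mode: str = "dataset"  # or "uniform"
    normalize_heights: bool = False
    max_mismatches: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0 + 1e-12:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        for name, value in self.min_scores.items():
            if value is not None and value < 0:
                raise ValueError(f"minimum score for {name} must be >= 0")
        if not 0.0 < self.directionality_threshold <= 1.0:
            raise ValueError("directionality threshold must be in (0, 1]")

    @property
    def min_scores(self) -> dict[str, float | None]:
        return {
            "strand_bias": self.min_score_strand,
            "typical_length": self.min_score_length,
            "t1_or_a10": self.min_score_t1a10,
            "ntr": self.min_score_ntr,
        }


@dataclass
class Cluster:
    """An accepted piRNA cluster with scores and directionality."""

    chromosome: str
    start: int
    end: int
    hits: list[GenomicHit]
    provenance: str
    scores: ScoreSet
    ntr: NtrValue
    directionality: str  # mono | bi | non
    degree_mono: float
    degree_bi: float
    split_point: int | None
    combined_chance_probability: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def main_strand(self) -> str:
        return main_strand(self.hits)[0]

    @property
    def single_copy_loci(self) -> int:
        return sum(1 for h in self.hits if h.read.genomic_hits == 1)


@dataclass
class RejectionRecord:
    """Diagnostics for a rejected candidate: which criteria failed."""

    candidate: ClusterCandidate
    scores: ScoreSet
    failed: list[str] = field(default_factory=list)


def degree_mono(hits: Sequence[GenomicHit]) -> float:
    """Proportion of hits on the main strand (always >= 0.5)."""
    if not hits:
        raise ValueError("empty cluster")
    _, m = main_strand(hits)
    return m / len(hits)


def _admissible(size: int, total: int) -> bool:
    return size >= 0.25 * total or size >= 10


def degree_bi(hits: Sequence[GenomicHit]) -> tuple[float, int | None]:
    """Best pro-rata two-fragment main-strand proportion and its split point.

    The cluster is split between every pair of consecutive hits yielding two
    fragments that each hold at least 25% of all hits or at least 10 hits;
    the fragment-wise main-strand proportions are combined weighted by
    fragment size.  Returns (0.0, None) when no split is admissible.
    """
    n = len(hits)
    if n < 2:
        return 0.0, None
    plus_prefix = [0] * (n + 1)
    for i, h in enumerate(hits):
        plus_prefix[i + 1] = plus_prefix[i] + (1 if h.strand == "+" else 0)
    best = 0.0
    best_split: int | None = None
    for s in range(1, n):
        left, right = s, n - s
        if not (_admissible(left, n) and _admissible(right, n)):
            continue
        plus_l = plus_prefix[s]
        plus_r = plus_prefix[n] - plus_prefix[s]
        mono_l = max(plus_l, left - plus_l) / left
        mono_r = max(plus_r, right - plus_r) / right
        value = (left / n) * mono_l + (right / n) * mono_r
        if value > best + 1e-12:
            best = value
            best_split = (hits[s - 1].end + hits[s].start) // 2
    return best, best_split


def assign_directionality(d_mono: float, d_bi: float, threshold: float) -> str:
    """Mono/bi/non classification; ties between equal degrees go to mono."""
    if d_mono >= threshold and d_mono >= d_bi:
        return "mono"
    if d_bi >= threshold and d_bi > d_mono:
        return "bi"
    return "non"


def combined_chance_probability(
    scores: ScoreSet, min_scores: dict[str, float | None]
) -> float:
    """Product of the enabled criteria's tail probabilities (floor 1e-300)."""
    log10_p = 0.0
    for key in CRITERIA:
        if min_scores.get(key) is None:
            continue
        log10_p += scores.log10_tails[key]
    return max(10.0 ** max(log10_p, math.log10(_MIN_COMBINED_P)), _MIN_COMBINED_P)


def verify(
    candidate: ClusterCandidate,
    profile: DatasetProfile,
    config: RunConfig,
) -> Cluster | RejectionRecord:
    """Score a candidate and accept it iff every enabled score passes.

    Strand asymmetry is scored with the main-strand count of the better of
    the two topologies (whole-cluster mono versus best admissible
    bi-directional split), so that genuinely bi-directional clusters pass
    the strand-bias criterion on their fragment-wise asymmetry.
    """
    if not candidate.hits:
        raise ValueError("empty cluster candidate")
    n = len(candidate.hits)
    d_mono = degree_mono(candidate.hits)
    d_bi, split = degree_bi(candidate.hits)
    strand_main_count = round(n * max(d_mono, d_bi))
    scores, ntr_value = score_candidate(
        candidate.hits, profile, config.typical_length, config.composition_mode,
        strand_main_count=strand_main_count,
    )
    failed = [
        key for key, minimum in config.min_scores.items()
        if minimum is not None and scores.as_dict()[key] < minimum
    ]
    if failed:
        return RejectionRecord(candidate=candidate, scores=scores, failed=failed)
    directionality = assign_directionality(
        d_mono, d_bi, config.directionality_threshold
    )
    return Cluster(
        chromosome=candidate.chromosome,
        start=candidate.start,
        end=candidate.end,
        hits=list(candidate.hits),
        provenance=candidate.provenance,
        scores=scores,
        ntr=ntr_value,
        directionality=directionality,
        degree_mono=d_mono,
        degree_bi=d_bi,
        split_point=split if directionality == "bi" else None,
        combined_chance_probability=combined_chance_probability(
            scores, config.min_scores
        ),
    )


def rescue(
    rejections: Iterable[RejectionRecord],
    profile: DatasetProfile,
    config: RunConfig,
    per_chromosome_density: dict[str, float],
    min_loci: int,
) -> list[Cluster]:
    """Re-evaluate strand-asymmetry rejections using infrequent reads only.

    Loci of reads with more than ``config.rescue_max_hits`` genomic hits are
    removed; the reduced candidate must still satisfy the chromosome's
    density and the minimum loci count, and is then re-verified.  Accepted
    clusters are flagged provenance "rescue".
    """
    if config.rescue_max_hits is None:
        return []
    out: list[Cluster] = []
    for rec in rejections:
        if "strand_bias" not in rec.failed:
            continue
        kept = [
            h for h in rec.candidate.hits
            if h.read.genomic_hits <= config.rescue_max_hits
        ]
        if len(kept) < min_loci:
            continue
        k = per_chromosome_density.get(rec.candidate.chromosome)
        if k is None or hit_density(kept) < k:
            continue
        reduced = ClusterCandidate(
            rec.candidate.chromosome, kept, provenance="rescue"
        )
        result = verify(reduced, profile, config)
        if isinstance(result, Cluster):
            out.append(result)
    return out


def set_error_probabilities(clusters: Iterable) -> tuple[float, float, float]:
    """Probabilities of 0, >=1 and >=2 mistakenly annotated clusters.

    Treats each reported cluster as an independent Bernoulli trial with its
    combined chance probability.  Accepts clusters or bare probabilities.
    """
    ps = [
        getattr(c, "combined_chance_probability", c) for c in clusters
    ]
    p0 = 1.0
    for p in ps:
        p0 *= 1.0 - p
    exactly_one = 0.0
    for j, pj in enumerate(ps):
        prod = pj
        for k, pk in enumerate(ps):
            if k != j:
                prod *= 1.0 - pk
        exactly_one += prod
    p_ge1 = 1.0 - p0
    p_ge2 = max(0.0, 1.0 - p0 - exactly_one)
    return p0, p_ge1, p_ge2
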