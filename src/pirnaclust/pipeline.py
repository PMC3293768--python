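"""End-to-end orchestration: parse -> profile -> thresholds -> detect ->
clip -> score -> classify -> rescue -> set-level error probabilities."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .classify import (Cluster, RejectionRecord, RunConfig, rescue,
                       set_error_probabilities, verify)
from .dataset import DatasetProfile, build_profile
from .density import DensityThresholds, compute_thresholds
from .detection import detect_candidates
from .io_eland3 import GenomicHit, MappedRead, parse_eland3, read_chrom_sizes

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    profile: DatasetProfile
    thresholds: DensityThresholds
    n_candidates: int
    accepted: list[Cluster]
    rejected: list[RejectionRecord]
    set_probabilities: tuple[float, float, float]


def split_by_chromosome(hits: Sequence[GenomicHit]) -> dict[str, list[GenomicHit]]:
    by_chrom: dict[str, list[GenomicHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chromosome, []).append(h)
    return by_chrom


def run_pipeline(
    hits: Sequence[GenomicHit],
    reads: Sequence[MappedRead],
    config: RunConfig,
    chrom_sizes: dict[str, int],
) -> PipelineResult:
    """Run the full detection workflow on a parsed mapping model."""
    profile = build_profile(hits, reads, config.typical_length)
    for line in profile.summary_lines():
        logger.info("profile: %s", line)
    thresholds = compute_thresholds(
        profile, chrom_sizes, config.alpha, config.min_scores,
        config.composition_mode,
    )
    lo, hi = thresholds.density_range()
    logger.info("min hit density %.1f-%.1f hits/kb, min loci per cluster %d",
                lo, hi, thresholds.min_loci)

    candidates = detect_candidates(
        split_by_chromosome(hits), thresholds.per_chromosome, thresholds.min_loci
    )
    logger.info("%d cluster candidates", len(candidates))

    accepted: list[Cluster] = []
    rejected: list[RejectionRecord] = []
    for cand in candidates:
        result = verify(cand, profile, config)
        if isinstance(result, Cluster):
            accepted.append(result)
        else:
            rejected.append(result)

    if config.rescue_max_hits is not None:
        rescued = rescue(rejected, profile, config,
                         thresholds.per_chromosome, thresholds.min_loci)
        logger.info("%d clusters rescued with reads mapping <= %d times",
                    len(rescued), config.rescue_max_hits)
        accepted.extend(rescued)

    probs = set_error_probabilities(accepted)
    logger.info("accepted %d clusters; P(0/>=1/>=2 mistaken) = %.4g/%.4g/%.4g",
                len(accepted), *probs)
    return PipelineResult(
        profile=profile,
        thresholds=thresholds,
        n_candidates=len(candidates),
        accepted=accepted,
        rejected=rejected,
        set_probabilities=probs,
    )


def run_files(
    eland3_path: str | Path,
    config: RunConfig,
    chrom_sizes_path: str | Path | None = None,
    count_pattern: str | None = None,
) -> PipelineResult:
    """Convenience wrapper: parse input files, then run the pipeline."""
    from .io_eland3 import DEFAULT_COUNT_PATTERN

    pattern = DEFAULT_COUNT_PATTERN if count_pattern is None else count_pattern
    hits, reads = parse_eland3(
        eland3_path, count_pattern=pattern, max_mismatches=config.max_mismatches
    )
    if not hits:
        raise ValueError(f"no mapped reads in {eland3_path}")
    sizes = read_chrom_sizes(chrom_sizes_path, hits)
    return run_pipeline(hits, reads, config, sizes)
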