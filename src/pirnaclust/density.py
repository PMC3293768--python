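"""Significance-based minimum hit density and minimum loci per cluster.

Under the null hypothesis that mapped reads fall uniformly over a
chromosome, the number of hits in a 1 kb window is Poisson with mean
``lam = hits_on_chromosome * 1000 / chromosome_length``.  The Poisson mass
is extended to positive rational hit numbers through the gamma function,

    f(x) = exp(-lam) * lam^x / Gamma(x + 1),

so that the upper-tail probability P(x >= k) can be evaluated on a 0.1-hit
grid: the minimum hit density of a chromosome is the smallest k in
{0.1, 0.2, ...} whose tail probability does not exceed the significance
level alpha.

The dataset-wide minimum number of loci per cluster is the smallest n for
which an ideal cluster of n loci (all on one strand, all typical length,
all 1T, all from the lowest-multiplicity read group) reaches every enabled
minimum score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

from .dataset import DatasetProfile
from .scoring import binom_tail_score, ntr_score

logger = logging.getLogger(__name__)

_REL_TOL = 1e-15
_MAX_TERMS = 100_000
LOG10_2 = math.log10(2.0)


@dataclass
class DensityThresholds:
    """Per-chromosome minimum hit densities (hits/kb) and minimum loci."""

    alpha: float
    per_chromosome: dict[str, float]
    min_loci: int

    def density_range(self) -> tuple[float, float]:
        values = list(self.per_chromosome.values())
        return (min(values), max(values)) if values else (0.0, 0.0)


def extended_pmf(x: float, lam: float) -> float:
    """Gamma-extended Poisson mass exp(-lam) * lam^x / Gamma(x+1)."""
    if lam <= 0:
        raise ValueError(f"expected hits per kb must be positive, got {lam}")
    if x < 0:
        raise ValueError(f"hit number must be non-negative, got {x}")
    return math.exp(-lam + x * math.log(lam) - math.lgamma(x + 1))


def tail_probability(k: float, lam: float) -> float:
    """P(x >= k): unit-step sum of the extended mass from k upward.

    Reduces to the exact Poisson upper tail at integer k.  Summation stops
    once a term beyond the mode falls below 1e-15 of the running sum.
    """
    if lam <= 0:
        raise ValueError(f"expected hits per kb must be positive, got {lam}")
    if k < 0:
        raise ValueError(f"hit number must be non-negative, got {k}")
    total = 0.0
    for j in range(_MAX_TERMS):
        x = k + j
        term = extended_pmf(x, lam)
        total += term
        if x > lam and total > 0.0 and term < _REL_TOL * total:
            break
    return min(total, 1.0)


def min_hit_density(chrom_hits: int, chrom_len: int, alpha: float) -> float:
    """Smallest density k (multiple of 0.1 hits/kb) with P(x >= k) <= alpha."""
    if chrom_hits < 1:
        raise ValueError("chromosome must have at least one hit")
    if chrom_len < 1000:
        raise ValueError("chromosome length must be at least 1 kb")
    if not 0.0 < alpha < 1.0 + 1e-12:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    lam = chrom_hits * 1000.0 / chrom_len
    step = 1
    while tail_probability(step / 10.0, lam) > alpha:
        step += 1
        if step > 100_000:  # pragma: no cover - defensive
            raise RuntimeError("minimum hit density search did not converge")
    return step / 10.0


def compute_thresholds(
    profile: DatasetProfile,
    chrom_sizes: Mapping[str, int],
    alpha: float,
    min_scores: Mapping[str, float | None],
    composition_mode: str = "dataset",
) -> DensityThresholds:
    """Derive per-chromosome densities and the minimum loci per cluster.

    Chromosomes without hits, or shorter than 1 kb, are skipped with a log
    entry (their density is undefined under the per-kb null).
    """
    per_chrom: dict[str, float] = {}
    for chrom, length in chrom_sizes.items():
        hits = profile.per_chromosome.get(chrom, 0)
        if hits == 0:
            logger.info("chromosome %s has no hits; density undefined, skipped", chrom)
            continue
        if length < 1000:
            logger.info("chromosome %s is shorter than 1 kb; skipped", chrom)
            continue
        k = min_hit_density(hits, length, alpha)
        per_chrom[chrom] = k
        logger.debug("chromosome %s: lam=%.4f hits/kb, min density %.1f hits/kb",
                     chrom, hits * 1000.0 / length, k)
    n = min_loci(profile, min_scores, composition_mode)
    return DensityThresholds(alpha=alpha, per_chromosome=per_chrom, min_loci=n)


def min_loci(
    profile: DatasetProfile,
    min_scores: Mapping[str, float | None],
    composition_mode: str = "dataset",
    max_n: int = 100_000,
) -> int:
    """Smallest cluster size able to reach every enabled minimum score.

    The best case per characteristic is a cluster whose n loci are all on
    one strand (tail 0.5^n), all of typical length (tail r^n), all 1T (or
    all 10A, whichever branch is stronger), and all from the read group with
    the lowest mean hit count.  Characteristics whose dataset ratio makes
    the threshold unattainable are excluded from the search with a warning.
    """
    requirements: list = []  # callables n -> best-case score

    thr_strand = min_scores.get("strand_bias") or 0.0
    if thr_strand > 0:
        requirements.append(lambda n: n * LOG10_2 >= thr_strand)

    thr_len = min_scores.get("typical_length") or 0.0
    if thr_len > 0:
        r = profile.ratio_typical_length
        if 0.0 < r < 1.0:
            requirements.append(lambda n: -n * math.log10(r) >= thr_len)
        else:
            logger.warning(
                "typical-length ratio %.3f makes the length threshold "
                "unattainable; excluded from the minimum-loci search", r,
            )

    thr_seq = min_scores.get("t1_or_a10") or 0.0
    if thr_seq > 0:
        if composition_mode == "uniform":
            branch_ratios = [0.25]
        else:
            branch_ratios = [r for r in (profile.ratio_1T, profile.ratio_10A)
                             if 0.0 < r < 1.0]
        if branch_ratios:
            r_best = min(branch_ratios)
            requirements.append(lambda n: -n * math.log10(r_best) >= thr_seq)
        else:
            logger.warning(
                "both 1T and 10A dataset ratios are degenerate; 1T/10A "
                "threshold excluded from the minimum-loci search",
            )

    thr_ntr = min_scores.get("ntr") or 0.0
    if thr_ntr > 0:
        best_ntr = 1.0 / profile.groups[0].mean_hits
        requirements.append(
            lambda n: ntr_score(n, best_ntr, profile.groups,
                                profile.total_reads)[0] >= thr_ntr
        )

    n = 1
    while not all(req(n) for req in requirements):
        n += 1
        if n > max_n:
            raise RuntimeError("minimum-loci search did not converge")
    return n
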