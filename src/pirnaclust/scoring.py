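"""Probabilistic characteristic scores for cluster candidates.

Every score is the base-10 logarithm of the reciprocal of a binomial tail
probability: for a cluster of ``n`` loci of which ``m`` show a property
that a random locus shows with probability ``r``,

    score = -log10( sum_{k=m..n} C(n,k) r^k (1-r)^(n-k) )

so a score of 2.0 corresponds to a tail probability of 0.01.  Tails are
summed in log space (log-sum-exp over log binomial terms) since ``r^k``
underflows for the cluster sizes encountered in practice.  Once a tail
probability falls below 1e-100 the score is reported as exactly 100; no
score exceeds this cap.

Four characteristics are scored: strand bias (r = 0.5), enrichment of loci
in the typical piRNA length range, enrichment of loci with T at position 1
or A at position 10 (whichever branch scores higher), and the
normalized-hits/total-hits ratio (NTR).  The NTR score uses the 8-group
read partition of :mod:`pirnaclust.dataset`: for each of the four group
pairs (i, i+4) the minimum number ``m_i`` of group-i reads needed to reach
the observed NTR (all remaining reads assumed from group i+4) enters a
binomial double sum with per-read probabilities r_i/R and r_{i+4}/R.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .dataset import DatasetProfile, HitGroup
from .io_eland3 import GenomicHit

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)

#: Score assigned once a tail probability drops below 1e-100.
SCORE_CAP = 100.0

#: log10 tail probability at which summation aborts (probability 1/10^100).
ABORT_LOG10 = -100.0


@dataclass
class ScoreSet:
    """The four characteristic scores of a cluster, with raw log10 tails."""

    strand_bias: float
    typical_length: float
    t1_or_a10: float
    ntr: float
    log10_tails: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.strand_bias + self.typical_length + self.t1_or_a10 + self.ntr

    def as_dict(self) -> dict[str, float]:
        return {
            "strand_bias": self.strand_bias,
            "typical_length": self.typical_length,
            "t1_or_a10": self.t1_or_a10,
            "ntr": self.ntr,
        }


@dataclass(frozen=True)
class NtrValue:
    """Normalized-hits/total-hits ratio of a set of loci.

    ``normalized_hits`` sums 1/genomic_hits over the loci; the ratio equals
    1 exactly iff every contributing read maps once genome-wide.
    """

    normalized_hits: float
    total_hits: int

    @property
    def ntr(self) -> float:
        return self.normalized_hits / self.total_hits


def compute_ntr(hits: Sequence[GenomicHit]) -> NtrValue:
    if not hits:
        raise ValueError("cannot compute NTR of an empty locus set")
    return NtrValue(
        normalized_hits=sum(1.0 / h.read.genomic_hits for h in hits),
        total_hits=len(hits),
    )


def _log10_binom_tail(n: int, m: int, r: float) -> float:
    """log10 of sum_{k=m..n} C(n,k) r^k (1-r)^(n-k), in log space."""
    k = np.arange(m, n + 1)
    log_terms = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * math.log(r) + (n - k) * math.log1p(-r)
    )
    return float(logsumexp(log_terms)) / LN10


def _score_from_log10(log10_tail: float) -> float:
    if log10_tail < ABORT_LOG10:
        return SCORE_CAP
    return min(SCORE_CAP, max(0.0, -log10_tail))


def binom_tail_score(n: int, m: int, r: float) -> float:
    """Score the event "at least m of n loci show a probability-r property"."""
    score, _ = binom_tail_score_with_tail(n, m, r)
    return score


def binom_tail_score_with_tail(n: int, m: int, r: float) -> tuple[float, float]:
    """Like :func:`binom_tail_score` but also return the log10 tail."""
    if not 0.0 < r < 1.0:
        raise ValueError(f"r must be in (0, 1), got {r}")
    if not 0 <= m <= n:
        raise ValueError(f"require 0 <= m <= n, got m={m}, n={n}")
    if m == 0:
        return 0.0, 0.0
    log10_tail = _log10_binom_tail(n, m, r)
    return _score_from_log10(log10_tail), log10_tail


def main_strand(hits: Sequence[GenomicHit]) -> tuple[str, int]:
    """The strand carrying the majority of hits (tie -> plus) and its count."""
    plus = sum(1 for h in hits if h.strand == "+")
    minus = len(hits) - plus
    return ("+", plus) if plus >= minus else ("-", minus)


def strand_bias_score(hits: Sequence[GenomicHit]) -> tuple[float, float]:
    """Strand-bias score: m = hits on the main strand, r = 0.5."""
    if not hits:
        raise ValueError("empty cluster")
    _, m = main_strand(hits)
    n, m = apply_large_cluster_cap(len(hits), m)
    return binom_tail_score_with_tail(n, m, 0.5)


def length_score(
    hits: Sequence[GenomicHit],
    profile: DatasetProfile,
    typical_length: tuple[int, int],
) -> tuple[float, float]:
    """Typical-length enrichment score against the dataset ratio.

    A degenerate dataset ratio (0 or 1) makes the binomial tail meaningless;
    the score is then 0 with a warning.
    """
    r = profile.ratio_typical_length
    if not 0.0 < r < 1.0:
        logger.warning("typical-length ratio %.3f is degenerate; length score disabled", r)
        return 0.0, 0.0
    lo, hi = typical_length
    m = sum(1 for h in hits if lo <= len(h.read.sequence) <= hi)
    n, m = apply_large_cluster_cap(len(hits), m)
    return binom_tail_score_with_tail(n, m, r)


def t1_a10_score(
    hits: Sequence[GenomicHit],
    profile: DatasetProfile,
    composition_mode: str = "dataset",
) -> tuple[float, float]:
    """1T-or-10A enrichment: the better of the two branches, never the sum.

    ``composition_mode`` "dataset" uses the dataset 1T/10A ratios; "uniform"
    assumes random base composition (r = 0.25 for both branches).
    """
    if composition_mode == "uniform":
        r_1t = r_10a = 0.25
    elif composition_mode == "dataset":
        r_1t, r_10a = profile.ratio_1T, profile.ratio_10A
    else:
        raise ValueError(f"unknown composition mode {composition_mode!r}")
    m_1t = sum(1 for h in hits if h.read.sequence[0] == "T")
    m_10a = sum(
        1 for h in hits if len(h.read.sequence) >= 10 and h.read.sequence[9] == "A"
    )
    best = (0.0, 0.0)
    for m, r in ((m_1t, r_1t), (m_10a, r_10a)):
        if not 0.0 < r < 1.0:
            logger.warning("1T/10A branch ratio %.3f is degenerate; branch disabled", r)
            continue
        n_c, m_c = apply_large_cluster_cap(len(hits), m)
        cand = binom_tail_score_with_tail(n_c, m_c, r)
        if cand[0] > best[0]:
            best = cand
    return best


def ntr_min_counts(
    n: int,
    ntr_obs: float,
    groups: Sequence[HitGroup],
) -> list[int | None]:
    """Minimum group-i read counts m_1..m_4 reaching the observed NTR.

    For pair (i, i+4), ``m_i`` is the smallest number of reads contributing
    1/a_i (all others contributing 1/a_{i+4}) whose model NTR reaches
    ``ntr_obs``:  m_i = ceil( n*(NTR - 1/a_{i+4}) / (1/a_i - 1/a_{i+4}) ).

    Returns one entry per pair: an integer in [0, n], or None when the pair
    cannot reach the observed NTR at all (including degenerate pairs with
    a_i == a_{i+4} whose common 1/a falls short).
    """
    if not 0.0 < ntr_obs <= 1.0 + 1e-12:
        raise ValueError(f"observed NTR must be in (0, 1], got {ntr_obs}")
    out: list[int | None] = []
    for i in range(4):
        a_lo, a_hi = groups[i].mean_hits, groups[i + 4].mean_hits
        inv_lo, inv_hi = 1.0 / a_lo, 1.0 / a_hi
        if math.isclose(a_lo, a_hi, rel_tol=1e-12):
            # degenerate pair: every read contributes 1/a_lo
            out.append(0 if inv_lo >= ntr_obs - 1e-12 else None)
            continue
        raw = n * (ntr_obs - inv_hi) / (inv_lo - inv_hi)
        m = math.ceil(raw - 1e-9)
        if m <= 0:
            out.append(0)
        elif m > n:
            out.append(None)
        else:
            out.append(m)
    return out


def ntr_score(
    n: int,
    ntr_obs: float,
    groups: Sequence[HitGroup],
    total_reads: int,
) -> tuple[float, float]:
    """Grouped-approximation NTR score.

    Evaluates -log10 of the double sum over the four group pairs (i, i+4):

        sum_i sum_{k=m_i..n} C(n,k) (r_i/R)^k (r_{i+4}/R)^(n-k)

    with ``m_i`` from :func:`ntr_min_counts`.  Pairs that cannot reach the
    observed NTR contribute nothing (their inner sum is empty).
    """
    ms = ntr_min_counts(n, ntr_obs, groups)
    R = total_reads
    pair_log_tails: list[float] = []
    for i, m in enumerate(ms):
        if m is None:
            continue
        p = groups[i].n_reads / R
        q = groups[i + 4].n_reads / R
        if p == 0.0 and q == 0.0:
            continue
        k = np.arange(m, n + 1)
        with np.errstate(divide="ignore"):
            log_p = np.log(p) if p > 0 else -np.inf
            log_q = np.log(q) if q > 0 else -np.inf
        # guard 0 * -inf for k == 0 or k == n
        term_p = np.where(k == 0, 0.0, k * log_p)
        term_q = np.where(k == n, 0.0, (n - k) * log_q)
        log_terms = (
            gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1) + term_p + term_q
        )
        pair_log_tails.append(float(logsumexp(log_terms)))
    if not pair_log_tails:
        return SCORE_CAP, -math.inf
    log10_tail = float(logsumexp(pair_log_tails)) / LN10
    return _score_from_log10(log10_tail), log10_tail


def apply_large_cluster_cap(n: int, m: int) -> tuple[int, int]:
    """Scale (n, m) down proportionally when a cluster exceeds 1000 loci.

    Keeps factorial computations bounded; may underestimate scores, which is
    harmless since such clusters saturate the score cap anyway.  Rounding is
    half-up.
    """
    if n <= 1000:
        return n, m
    scaled = math.floor(m * 1000 / n + 0.5)
    return 1000, min(1000, scaled)


def score_candidate(
    hits: Sequence[GenomicHit],
    profile: DatasetProfile,
    typical_length: tuple[int, int],
    composition_mode: str = "dataset",
    strand_main_count: int | None = None,
) -> tuple[ScoreSet, NtrValue]:
    """Compute all four characteristic scores for a candidate's loci.

    ``strand_main_count`` overrides the main-strand hit count entering the
    strand-bias score; the classifier passes the better of the mono reading
    and the best bi-directional split so that divergently transcribed
    clusters are not penalized for their balanced whole-cluster strand
    counts.
    """
    if not hits:
        raise ValueError("empty cluster candidate")
    if strand_main_count is None:
        s_strand, t_strand = strand_bias_score(hits)
    else:
        n_c, m_c = apply_large_cluster_cap(len(hits), strand_main_count)
        s_strand, t_strand = binom_tail_score_with_tail(n_c, m_c, 0.5)
    s_len, t_len = length_score(hits, profile, typical_length)
    s_seq, t_seq = t1_a10_score(hits, profile, composition_mode)
    ntr_value = compute_ntr(hits)
    n_cap, _ = apply_large_cluster_cap(len(hits), 0)
    s_ntr, t_ntr = ntr_score(n_cap, ntr_value.ntr, profile.groups, profile.total_reads)
    scores = ScoreSet(
        strand_bias=s_strand,
        typical_length=s_len,
        t1_or_a10=s_seq,
        ntr=s_ntr,
        log10_tails={
            "strand_bias": t_strand,
            "typical_length": t_len,
            "t1_or_a10": t_seq,
            "ntr": t_ntr,
        },
    )
    return scores, ntr_value
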