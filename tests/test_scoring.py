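"""Binomial-tail scores and the grouped NTR machinery against
arbitrary-precision and exhaustive oracles."""

import itertools
import math
from fractions import Fraction

import mpmath
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnaclust.dataset import HitGroup
from pirnaclust.scoring import (SCORE_CAP, apply_large_cluster_cap,
                                binom_tail_score, compute_ntr,
                                length_score, ntr_min_counts, ntr_score,
                                strand_bias_score, t1_a10_score)
from tests.conftest import make_hit


def mp_binom_tail(n: int, m: int, r: float) -> mpmath.mpf:
    with mpmath.workdps(60):
        rr = mpmath.mpf(r)
        return sum(
            mpmath.binomial(n, k) * rr ** k * (1 - rr) ** (n - k)
            for k in range(m, n + 1)
        )


def mp_score(n: int, m: int, r: float) -> float:
    if m == 0:
        return 0.0
    with mpmath.workdps(60):
        return float(-mpmath.log10(mp_binom_tail(n, m, r)))


class TestBinomTailScore:
    def test_probability_001_scores_two(self):
        # n=1, m=1, r=0.01: the direct binomial sum is exactly 0.01
        assert binom_tail_score(1, 1, 0.01) == pytest.approx(2.0, abs=1e-9)

    def test_m_zero_scores_zero(self):
        assert binom_tail_score(17, 0, 0.3) == 0.0

    def test_all_successes_closed_form(self):
        assert binom_tail_score(8, 8, 0.5) == pytest.approx(
            -math.log10(0.5 ** 8), abs=1e-9
        )

    def test_invalid_probability_raises(self):
        for r in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ValueError):
                binom_tail_score(5, 3, r)

    def test_tail_below_1e100_scores_exactly_100(self):
        assert binom_tail_score(400, 400, 0.5) == 100.0

    def test_score_decreasing_in_r_at_full_enrichment(self):
        scores = [binom_tail_score(20, 20, r) for r in (0.2, 0.4, 0.6, 0.8)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        n=st.integers(1, 50),
        m_frac=st.floats(0.0, 1.0),
        r=st.floats(0.02, 0.98),
    )
    def test_matches_arbitrary_precision_sum(self, n, m_frac, r):
        m = round(m_frac * n)
        assert binom_tail_score(n, m, r) == pytest.approx(
            mp_score(n, m, r), abs=1e-9
        )


class TestStrandBiasScore:
    def test_fully_biased_cluster(self):
        hits = [make_hit(100 * i + 1, "+") for i in range(10)]
        score, _ = strand_bias_score(hits)
        assert score == pytest.approx(-math.log10(0.5 ** 10), abs=1e-9)

    def test_balanced_cluster(self):
        hits = [make_hit(100 * i + 1, "+-"[i % 2]) for i in range(10)]
        score, _ = strand_bias_score(hits)
        assert score == pytest.approx(-math.log10(638 / 1024), abs=1e-9)

    def test_single_hit(self):
        score, _ = strand_bias_score([make_hit(1, "-")])
        assert score == pytest.approx(-math.log10(0.5), abs=1e-9)


class TestCompositionScores:
    def _profile(self, **kw):
        from pirnaclust.dataset import build_profile

        hits = []
        for i in range(40):
            first = "T" if i < 10 else "G"
            tenth = "A" if i % 4 == 0 else "C"
            seq = first + "GCGCGCGC" + tenth + "GC" * 9
            hits.append(make_hit(1000 * i + 1, seq=seq))
        return build_profile(hits, [h.read for h in hits])

    def test_uniform_composition_all_1t(self):
        seq = "T" + "G" * 27
        hits = [make_hit(100 * i + 1, seq=seq) for i in range(8)]
        score, _ = t1_a10_score(hits, self._profile(), "uniform")
        assert score == pytest.approx(-8 * math.log10(0.25), abs=1e-9)

    def test_no_enrichment_scores_zero(self):
        seq = "G" * 9 + "C" + "G" * 18  # neither 1T nor 10A
        hits = [make_hit(100 * i + 1, seq=seq) for i in range(8)]
        score, _ = t1_a10_score(hits, self._profile(), "uniform")
        assert score == 0.0

    def test_best_branch_is_taken_not_the_sum(self):
        profile = self._profile()
        seq_1t = "T" + "G" * 8 + "A" + "G" * 18  # both 1T and 10A
        hits = [make_hit(100 * i + 1, seq=seq_1t) for i in range(8)]
        score, _ = t1_a10_score(hits, profile, "uniform")
        assert score == pytest.approx(-8 * math.log10(0.25), abs=1e-9)

    def test_degenerate_length_ratio_disables_score(self):
        from pirnaclust.dataset import build_profile

        hits = [make_hit(100 * i + 1) for i in range(10)]  # all 28 nt
        profile = build_profile(hits, [h.read for h in hits])
        assert profile.ratio_typical_length == 1.0
        score, _ = length_score(hits, profile, (26, 32))
        assert score == 0.0


class TestLargeClusterCap:
    @pytest.mark.parametrize("n,m,expected", [
        (2000, 2000, (1000, 1000)),
        (2000, 1000, (1000, 500)),
        (1500, 1000, (1000, 667)),  # round half up
        (900, 900, (900, 900)),     # below the cap: unchanged
    ])
    def test_proportional_scaling(self, n, m, expected):
        assert apply_large_cluster_cap(n, m) == expected


def groups_from(counts_and_sizes):
    return tuple(HitGroup(n_reads=r, mean_hits=a) for r, a in counts_and_sizes)


class TestNtrMinCounts:
    def test_hand_arithmetic_example(self):
        groups = groups_from([(2, 1), (2, 1), (2, 1), (2, 1),
                              (2, 10), (2, 10), (2, 10), (2, 10)])
        ms = ntr_min_counts(10, 0.55, groups)
        assert ms[0] == 5  # ceil(10*(0.55-0.1)/(1-0.1))

    def test_observed_at_high_group_mean_needs_none(self):
        groups = groups_from([(2, 1), (2, 1), (2, 1), (2, 1),
                              (2, 4), (2, 4), (2, 4), (2, 4)])
        ms = ntr_min_counts(8, 0.25, groups)  # ntr_obs == 1/a_{i+4}
        assert ms == [0, 0, 0, 0]

    def test_perfect_ntr_needs_all_loci_from_group_one(self):
        groups = groups_from([(2, 1), (2, 1), (2, 1), (2, 1),
                              (2, 5), (2, 5), (2, 5), (2, 5)])
        assert ntr_min_counts(12, 1.0, groups) == [12, 12, 12, 12]

    def test_minimality_property(self):
        groups = groups_from([(3, 1), (3, 1.5), (3, 2), (3, 3),
                              (3, 5), (3, 8), (3, 13), (3, 21)])
        n = 17
        for ntr_obs in (0.2, 0.41, 0.73, 0.95):
            for i, m in enumerate(ntr_min_counts(n, ntr_obs, groups)):
                a_lo = groups[i].mean_hits
                a_hi = groups[i + 4].mean_hits
                model = lambda mm: (mm / a_lo + (n - mm) / a_hi) / n
                if m is None:
                    assert model(n) < ntr_obs - 1e-12
                else:
                    assert model(m) >= ntr_obs - 1e-9
                    if m > 0:
                        assert model(m - 1) < ntr_obs - 1e-9


def mp_ntr_score(n, ntr_obs, groups, R):
    """Independent arbitrary-precision evaluation of the grouped double sum.

    The minimal m_i per pair is found by brute-force search instead of the
    closed-form ceiling.
    """
    with mpmath.workdps(60):
        total = mpmath.mpf(0)
        any_pair = False
        for i in range(4):
            a_lo, a_hi = groups[i].mean_hits, groups[i + 4].mean_hits
            m = None
            for mm in range(0, n + 1):
                if (mm / a_lo + (n - mm) / a_hi) / n >= ntr_obs - 1e-12:
                    m = mm
                    break
            if m is None:
                continue
            any_pair = True
            p = mpmath.mpf(groups[i].n_reads) / R
            q = mpmath.mpf(groups[i + 4].n_reads) / R
            total += sum(
                mpmath.binomial(n, k) * p ** k * q ** (n - k)
                for k in range(m, n + 1)
            )
        if not any_pair or total == 0:
            return SCORE_CAP
        return float(min(mpmath.mpf(100), max(0, -mpmath.log10(total))))


class TestNtrScore:
    GROUPS = groups_from([(5, 1), (5, 1), (4, 2), (4, 2),
                          (4, 4), (4, 7), (3, 12), (3, 25)])
    R = 32

    @pytest.mark.parametrize("n", [3, 8, 21, 50])
    @pytest.mark.parametrize("ntr_obs", [0.1, 0.33, 0.62, 0.9, 1.0])
    def test_matches_arbitrary_precision_oracle(self, n, ntr_obs):
        score, _ = ntr_score(n, ntr_obs, self.GROUPS, self.R)
        assert score == pytest.approx(
            mp_ntr_score(n, ntr_obs, self.GROUPS, self.R), abs=1e-9
        )

    def test_all_unique_dataset_pair_masses(self):
        groups = groups_from([(2, 1)] * 8)
        n = 6
        score, _ = ntr_score(n, 1.0, groups, 16)
        expected = -math.log10(4 * (4 / 16) ** n)
        assert score == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_observed_ntr(self):
        scores = [ntr_score(15, x, self.GROUPS, self.R)[0]
                  for x in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)]
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))

    def test_degenerate_pairs_contribute_only_when_reachable(self):
        groups = groups_from([(2, 2)] * 8)  # every pair degenerate, 1/a = 0.5
        score_low, _ = ntr_score(5, 0.4, groups, 16)   # reachable: mass 4*(1/4)^5
        assert score_low == pytest.approx(-math.log10(4 * 0.25 ** 5), abs=1e-9)
        score_high, tail = ntr_score(5, 0.9, groups, 16)  # unreachable
        assert score_high == SCORE_CAP


def enumeration_score(n: int, ntr_obs: float, read_hit_counts: list[int]) -> float:
    """Exact P(NTR >= obs) for n uniform draws (with replacement) from the
    true per-read hit counts, by multinomial enumeration over count classes."""
    classes: dict[int, int] = {}
    for c in read_hit_counts:
        classes[c] = classes.get(c, 0) + 1
    values = sorted(classes)
    R = len(read_hit_counts)
    prob = Fraction(0)
    k = len(values)

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    for combo in compositions(n, k):
        ntr = sum(Fraction(c, v) for c, v in zip(combo, values)) / n
        if ntr < Fraction(ntr_obs).limit_denominator(10**6):
            continue
        weight = Fraction(math.factorial(n))
        for c in combo:
            weight /= math.factorial(c)
        for c, v in zip(combo, values):
            weight *= Fraction(classes[v], R) ** c
        prob += weight
    return float(-mpmath.log10(mpmath.mpf(prob.numerator) / prob.denominator)) \
        if prob > 0 else float(SCORE_CAP)


class TestNtrRankOrder:
    def test_grouped_score_ranks_like_full_enumeration(self):
        """At fixed cluster size the grouped approximation orders observed
        NTR values exactly as the exhaustive multinomial computation."""
        read_hit_counts = [1] * 8 + [2] * 4 + [10] * 4  # R = 16
        from pirnaclust.dataset import partition_groups
        from tests.conftest import make_read

        reads = [make_read(seq="TACG" * 6 + "GC" * i, hits=c)
                 for i, c in enumerate(read_hit_counts)]
        groups = partition_groups(reads)
        for n in (4, 6, 8):
            obs_ladder = [0.2, 0.4, 0.6, 0.8, 1.0]
            grouped = [ntr_score(n, o, groups, 16)[0] for o in obs_ladder]
            exact = [enumeration_score(n, o, read_hit_counts)
                     for o in obs_ladder]
            for (g1, e1), (g2, e2) in itertools.combinations(
                    zip(grouped, exact), 2):
                if abs(e1 - e2) > 1e-9:
                    assert (g1 - g2) * (e1 - e2) >= 0


class TestComputeNtr:
    def test_mixed_multiplicities(self):
        hits = [make_hit(1, hits=1), make_hit(100, hits=2),
                make_hit(200, hits=4)]
        value = compute_ntr(hits)
        assert value.normalized_hits == pytest.approx(1 + 0.5 + 0.25)
        assert value.ntr == pytest.approx((1 + 0.5 + 0.25) / 3)
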