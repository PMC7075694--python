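"""Dispersion-test unit tests, checked against independent brute-force
permutation oracles implemented here (enumeration only, no shared code with
the implementation)."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dendrosim import (
    conover_squared_ranks,
    siegel_tukey,
    siegel_tukey_ranks,
)


# ---------------------------------------------------------------- oracles

def brute_force_p(scores, n1, t_obs):
    """Exact two-sided permutation p for a score-sum statistic:
    2*min(P(T<=t), P(T>=t)) over all C(N, n1) assignments, capped at 1."""
    scores = np.asarray(scores, float)
    sums = [sum(scores[list(c)]) for c in combinations(range(len(scores)), n1)]
    sums = np.asarray(sums)
    eps = 1e-9 * max(1.0, abs(t_obs))
    lo = np.mean(sums <= t_obs + eps)
    hi = np.mean(sums >= t_obs - eps)
    return min(1.0, 2 * min(lo, hi))


def conover_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    dev = np.concatenate([np.abs(x - x.mean()), np.abs(y - y.mean())])
    scores = sps.rankdata(dev) ** 2
    t = scores[:len(x)].sum()
    return t, brute_force_p(scores, len(x), t)


# ---------------------------------------------------------------- conover

class TestConover:
    def test_identical_samples_p_one(self):
        res = conover_squared_ranks([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_against_brute_force(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [-10.0, 0.0, 10.0, 20.0]
        t, p = conover_oracle(x, y)
        res = conover_squared_ranks(x, y)
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_mode_matches_enumeration_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0, 3, 7)
        t, p = conover_oracle(x, y)
        res = conover_squared_ranks(x, y, exact=True)
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            conover_squared_ranks([1.0, 1.0, 1.0], [5.0, 5.0, 5.0])

    def test_detects_variance_difference(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 4, 40)
        assert conover_squared_ranks(x, y).p_value < 0.01

    def test_null_p_values_roughly_uniform(self):
        """Two same-distribution samples: p uniform on (0,1) under
        repetition (KS check at a generous level)."""
        rng = np.random.default_rng(1)
        ps = [conover_squared_ranks(rng.normal(13.5, 1.3, 20),
                                    rng.normal(13.5, 1.3, 20)).p_value
              for _ in range(400)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


# ------------------------------------------------------------ siegel-tukey

class TestSiegelTukeyRanks:
    def test_alternating_pattern_even(self):
        # sorted values 1..6: ranks 1 | 4 5 | 6 | 3 2 reading low->high
        ranks = siegel_tukey_ranks([1, 2, 3, 4, 5, 6])
        assert list(ranks) == [1, 4, 5, 6, 3, 2]

    def test_alternating_pattern_from_high(self):
        ranks = siegel_tukey_ranks([1, 2, 3, 4, 5, 6], rank_from_low=False)
        assert list(ranks) == [2, 3, 6, 5, 4, 1]

    def test_ties_get_mid_ranks(self):
        ranks = siegel_tukey_ranks([1.0, 1.0, 2.0, 3.0])
        assert ranks[0] == ranks[1] == pytest.approx((1 + 4) / 2)

    def test_rank_set_is_permutation(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=11)
        assert sorted(siegel_tukey_ranks(vals)) == list(range(1, 12))


class TestSiegelTukey:
    def test_identical_samples_p_one(self):
        res = siegel_tukey([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_pair_exact(self):
        # x holds both extremes after alignment; enumerate C(4,2)=6 splits
        res = siegel_tukey([-3.0, 3.0], [-1.0, 1.0])
        scores = siegel_tukey_ranks([-3.0, 3.0, -1.0, 1.0])
        p = brute_force_p(scores, 2, scores[:2].sum())
        assert res.p_value == pytest.approx(p)

    def test_reduces_to_rank_sum_on_alternating_ranks(self):
        """Siegel-Tukey == Wilcoxon rank-sum applied to the alternating
        ranks (independent implementation: scipy's exact Mann-Whitney)."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0, 2, 7)
        res = siegel_tukey(x, y, align_medians=False, exact=True)
        pooled = np.concatenate([x, y])
        ranks = siegel_tukey_ranks(pooled)
        mw = sps.mannwhitneyu(ranks[:6], ranks[6:], method="exact")
        assert res.p_value == pytest.approx(mw.pvalue, abs=1e-9)

    def test_exact_matches_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0, 3, 6)
        res = siegel_tukey(x, y, exact=True)
        xa = x - np.median(x)
        ya = y - np.median(y)
        scores = siegel_tukey_ranks(np.concatenate([xa, ya]))
        p = brute_force_p(scores, 5, scores[:5].sum())
        assert res.p_value == pytest.approx(p)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            siegel_tukey([2.0, 2.0], [2.0, 2.0])

    def test_detects_spread_difference_with_unequal_locations(self):
        rng = np.random.default_rng(5)
        x = rng.normal(50, 1, 30)
        y = rng.normal(0, 5, 30)
        assert siegel_tukey(x, y).p_value < 0.01


# ---------------------------------------------------------- shared properties

@st.composite
def two_samples(draw):
    n1 = draw(st.integers(3, 8))
    n2 = draw(st.integers(3, 8))
    rng = np.random.default_rng(draw(st.integers(0, 10_000)))
    return rng.normal(0, 1, n1), rng.normal(0, draw(st.floats(0.5, 3.0)), n2)


class TestInvariances:
    @given(two_samples(), st.floats(0.1, 50.0))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_scale_invariance(self, xy, c):
        x, y = xy
        for test in (conover_squared_ranks, siegel_tukey):
            assert test(x, y).p_value == pytest.approx(test(c * x, c * y).p_value)

    @given(two_samples())
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_swap_symmetry(self, xy):
        x, y = xy
        for test in (conover_squared_ranks, siegel_tukey):
            a, b = test(x, y), test(y, x)
            assert a.p_value == pytest.approx(b.p_value)
            assert (a.n1, a.n2) == (b.n2, b.n1)

    def test_power_against_sd_ratio_two(self):
        """Sanity floor: SD ratio 2 at n=25 per arm is detected more than
        half the time at alpha = 0.05 by both tests."""
        rng = np.random.default_rng(6)
        hits_c = hits_s = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(10, 1, 25)
            y = rng.normal(10, 2, 25)
            hits_c += conover_squared_ranks(x, y).p_value < 0.05
            hits_s += siegel_tukey(x, y).p_value < 0.05
        assert hits_c / reps > 0.5
        assert hits_s / reps > 0.5
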