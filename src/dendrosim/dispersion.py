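"""Rank-based two-sample tests for differences in dispersion.

Two classical nonparametric scale tests, both reducing to "sum a score over
sample 1 and compare against its permutation distribution":

* Conover squared-ranks test — scores are the squared mid-ranks of the
  pooled absolute deviations from each group's own mean.
* Siegel-Tukey test — scores are alternating extreme ranks (1 to the
  smallest, 2-3 to the two largest, 4-5 to the next two smallest, ...)
  assigned to the pooled sorted values, then the Wilcoxon rank-sum
  procedure is applied.  Because the test assumes equal location, each
  sample is shifted to zero median before ranking by default.

For combined sample sizes up to :data:`EXACT_THRESHOLD` the exact
permutation null is enumerated; above it a large-sample approximation
based on the exact finite-population moments of the score sum is used —
a Student t reference (N-2 df) for the skewed squared-rank scores, the
normal with continuity correction for Siegel-Tukey's integer ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TwoSampleResult",
    "conover_squared_ranks",
    "siegel_tukey",
    "siegel_tukey_ranks",
    "EXACT_THRESHOLD",
]

#: Largest combined sample size for which the exact permutation null is used.
EXACT_THRESHOLD = 14


@dataclass(frozen=True)
class TwoSampleResult:
    statistic: float
    p_value: float
    method: str  # "conover" | "siegel_tukey"
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {"method": self.method, "statistic": self.statistic,
                "p_value": self.p_value, "n1": self.n1, "n2": self.n2}


def _validate(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    return x, y


def _perm_moments(scores: np.ndarray, n1: int) -> tuple[float, float]:
    """Exact mean and variance of the sum of n1 scores drawn without
    replacement from the pooled scores (the permutation null)."""
    N = len(scores)
    n2 = N - n1
    sbar = scores.mean()
    pvar = scores.var()  # population variance, /N
    mean = n1 * sbar
    var = n1 * n2 * pvar / (N - 1)
    return mean, var


def _exact_p(scores: np.ndarray, n1: int, t_obs: float) -> float:
    """Two-sided exact permutation p-value: 2·min(P(T<=t), P(T>=t)), capped.

    Enumerates all C(N, n1) assignments of the pooled scores to sample 1.
    """
    N = len(scores)
    lo = hi = total = 0
    eps = 1e-9 * max(1.0, abs(t_obs))
    for idx in combinations(range(N), n1):
        t = scores[list(idx)].sum()
        total += 1
        if t <= t_obs + eps:
            lo += 1
        if t >= t_obs - eps:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def _score_sum_test(scores: np.ndarray, n1: int, method: str,
                    exact: bool | None, continuity: bool,
                    student_t: bool = False) -> TwoSampleResult:
    N = len(scores)
    n2 = N - n1
    t_obs = float(scores[:n1].sum())
    if exact is None:
        exact = N <= EXACT_THRESHOLD
    if exact:
        p = _exact_p(scores, n1, t_obs)
    else:
        mean, var = _perm_moments(scores, n1)
        if var <= 0:
            raise ValueError("degenerate sample: all pooled scores identical")
        d = t_obs - mean
        if continuity:
            d = math.copysign(max(abs(d) - 0.5, 0.0), d)
        z = d / math.sqrt(var)
        # Student t with N-2 df calibrates skewed score sums (squared
        # ranks) better than the normal at moderate sample sizes
        if student_t:
            p = 2.0 * stats.t.sf(abs(z), df=N - 2)
        else:
            p = 2.0 * stats.norm.sf(abs(z))
    return TwoSampleResult(statistic=t_obs, p_value=float(min(p, 1.0)),
                           method=method, n1=n1, n2=n2)


def conover_squared_ranks(x: Sequence[float], y: Sequence[float],
                          exact: bool | None = None) -> TwoSampleResult:
    """Conover squared-ranks test for equal variances.

    Absolute deviations from each group's own sample mean are pooled and
    mid-ranked; the statistic is the sum of squared ranks in sample 1.
    ``exact=None`` enumerates the permutation null when n1+n2 <= 14.
    """
    x, y = _validate(x, y)
    dev = np.concatenate([np.abs(x - x.mean()), np.abs(y - y.mean())])
    if np.ptp(dev) == 0:
        raise ValueError("degenerate sample: all pooled deviations identical")
    scores = stats.rankdata(dev) ** 2
    return _score_sum_test(scores, len(x), "conover", exact, continuity=False,
                           student_t=True)


def siegel_tukey_ranks(values: Sequence[float], rank_from_low: bool = True) -> np.ndarray:
    """Alternating extreme ranks of ``values``, in input order.

    With ``rank_from_low`` (the cited-reference convention) rank 1 goes to
    the minimum, ranks 2-3 to the two largest, 4-5 to the next two
    smallest, and so on; ``rank_from_low=False`` starts at the maximum.
    Tied values receive the mean of the ranks they span.
    """
    values = np.asarray(values, dtype=float)
    N = len(values)
    order = np.argsort(values, kind="stable")
    labels = np.empty(N, dtype=float)
    lo, hi = 0, N - 1
    rank = 1
    take_low = rank_from_low
    batch = 1  # first batch assigns a single rank, all later ones two
    while lo <= hi:
        for _ in range(min(batch, hi - lo + 1)):
            if take_low:
                labels[order[lo]] = rank
                lo += 1
            else:
                labels[order[hi]] = rank
                hi -= 1
            rank += 1
        take_low = not take_low
        batch = 2
    # mid-rank ties on equal values
    sorted_vals = values[order]
    i = 0
    while i < N:
        j = i
        while j + 1 < N and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            idx = order[i:j + 1]
            labels[idx] = labels[idx].mean()
        i = j + 1
    return labels


def siegel_tukey(x: Sequence[float], y: Sequence[float], *,
                 align_medians: bool = True, rank_from_low: bool = True,
                 exact: bool | None = None,
                 continuity: bool = True) -> TwoSampleResult:
    """Siegel-Tukey test for a difference in spread.

    The sample with the smaller spread concentrates near the pooled centre
    and collects the large alternating ranks; the Wilcoxon rank-sum
    procedure on those ranks yields the p-value.  ``align_medians`` shifts
    each sample to zero median first (the test assumes equal location).
    """
    x, y = _validate(x, y)
    if align_medians:
        x = x - np.median(x)
        y = y - np.median(y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate sample: all values identical")
    scores = siegel_tukey_ranks(pooled, rank_from_low=rank_from_low)
    return _score_sum_test(scores, len(x), "siegel_tukey", exact, continuity=continuity)
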