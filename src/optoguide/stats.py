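"""Statistics for live-cell assays: permutation, proportion, binomial, t tests.

All tests are two-sided by default and deterministic given their inputs and
seed.  The permutation test never reports p = 0: sampled nulls use the
add-one convention p = (1 + #{perm ≥ obs}) / (1 + n_perm), and exhaustive
enumeration (used automatically when the number of distinct group splits is
small) includes the observed labelling itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from .errors import InvalidArgumentError

__all__ = [
    "TestResult",
    "permutation_test_absdiff",
    "ztest_two_proportions",
    "binomial_symmetry_test",
    "one_sample_t",
]

EXHAUSTIVE_LIMIT = 100_000


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: int | None = None
    seed: int | None = None
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise InvalidArgumentError("p-value must lie in (0, 1]")


def permutation_test_absdiff(
    group_a, group_b, n_perm: int = 9999, seed: int | None = None
) -> TestResult:
    """Permutation test on the absolute difference of group means.

    The exchangeable unit is the cell; each value is a per-cell summary
    (e.g. the mean normalized response over a time window).  The null is
    built by permuting condition labels.  When the number of distinct
    splits C(n_a+n_b, n_a) is at most 10⁵ the null is enumerated
    exhaustively and p is the exact fraction of splits with statistic ≥
    observed; otherwise ``n_perm`` random permutations are drawn and the
    add-one convention applies.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    total = pooled.sum()

    n_splits = comb(n, na)
    if n_splits <= EXHAUSTIVE_LIMIT:
        count = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            stat = abs(sa / na - (total - sa) / (n - na))
            if stat >= observed - 1e-12:
                count += 1
        p = count / n_splits
        return TestResult(
            statistic=float(observed), p_value=float(p),
            method="permutation-absdiff (exhaustive)", n_permutations=n_splits,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:na].mean() - perm[na:].mean())
        if stat >= observed - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TestResult(
        statistic=float(observed), p_value=float(p),
        method="permutation-absdiff (sampled)", n_permutations=n_perm, seed=seed,
    )


def ztest_two_proportions(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-sample Z-test for proportions (pooled variance, two-sided)."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise InvalidArgumentError("require 0 <= x <= n and n > 0")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):  # identical extreme proportions: no evidence
        return TestResult(
            statistic=0.0, p_value=1.0,
            method="two-proportion z (pooled)", degenerate=True,
        )
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return TestResult(statistic=float(z), p_value=float(p), method="two-proportion z (pooled)")


def binomial_symmetry_test(k_toward_front: int, n: int) -> TestResult:
    """Exact two-sided binomial test against p₀ = 1/2.

    The p-value sums the probabilities of all outcomes no more likely than
    the observed count — the natural two-sided rule for the symmetric null
    that a cell is equally likely to respond to either stimulus.
    """
    if n <= 0:
        raise InvalidArgumentError("n must be positive")
    if not 0 <= k_toward_front <= n:
        raise InvalidArgumentError("require 0 <= k <= n")
    res = sps.binomtest(k_toward_front, n, p=0.5, alternative="two-sided")
    return TestResult(
        statistic=float(k_toward_front / n),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact binomial symmetry",
    )


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """One-sample two-sided t test for mean equal to ``mu0``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidArgumentError("need n >= 2")
    if np.ptp(v) == 0:
        return TestResult(
            statistic=0.0, p_value=1.0, method="one-sample t", degenerate=True,
        )
    t, p = sps.ttest_1samp(v, mu0)
    return TestResult(statistic=float(t), p_value=float(p), method="one-sample t")
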