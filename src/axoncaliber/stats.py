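"""Resampling and rank statistics, built from first principles.

Two tests back every comparison in the pipeline: a paired permutation
test (independent sign flips of the paired differences, exhaustive for
small n) for paired data, and the Mann-Whitney / Wilcoxon rank-sum test
for independent populations.  Both are implemented here directly so that
exhaustive enumeration can serve as the correctness oracle in tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "PairedSample",
    "TestResult",
    "paired_permutation_test",
    "rank_sum_test",
]


@dataclass
class PairedSample:
    """Paired observations (x_i, y_i); the test acts on d_i = x_i - y_i."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1D arrays")
        if len(self.x) < 2:
            raise ValueError("need at least 2 pairs")

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool
    n_permutations: int | None = None
    seed: int | None = None
    degenerate: bool = False


def _sign_matrix(k: int) -> np.ndarray:
    # all 2^k sign vectors, rows ordered by binary counting
    bits = (np.arange(2**k)[:, None] >> np.arange(k)) & 1
    return bits * 2.0 - 1.0


def _exhaustive_sign_flip_p(d: np.ndarray) -> float:
    """Two-sided p over all 2^n sign assignments of the statistic sum(d).

    Computed by a meet-in-the-middle split so n = 20 (1M assignments)
    stays cheap: sums over each half are combined by broadcasting.
    """
    n = len(d)
    k = n // 2
    s1 = _sign_matrix(k) @ d[:k] if k else np.zeros(1)
    s2 = _sign_matrix(n - k) @ d[k:] if n - k else np.zeros(1)
    sums = s1[:, None] + s2[None, :]
    obs = abs(float(d.sum()))
    tol = 1e-9 * max(obs, 1.0) + 1e-12
    count = int(np.count_nonzero(np.abs(sums) >= obs - tol))
    return count / sums.size


def paired_permutation_test(
    sample: PairedSample,
    n_perm: int = 10000,
    seed: int | None = None,
    exhaustive_threshold: int = 20,
) -> TestResult:
    """Two-sided paired permutation test with statistic mean(d).

    The null is generated by flipping the sign of each difference
    independently: exhaustive over all 2^n assignments when
    n <= ``exhaustive_threshold``, else Monte Carlo with the identity
    assignment included in the denominator (so p >= 1/(n_perm + 1)).
    All-zero differences give p = 1 with a degenerate flag, not an error.
    """
    d = sample.differences
    n = len(d)
    stat = float(d.mean())
    if np.all(d == 0):
        return TestResult(
            statistic=stat, p_value=1.0, method="paired_permutation",
            exact=True, degenerate=True, seed=seed,
        )
    if n <= exhaustive_threshold:
        p = _exhaustive_sign_flip_p(d)
        return TestResult(
            statistic=stat, p_value=p, method="paired_permutation",
            exact=True, n_permutations=2**n, seed=seed,
        )
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
    sums = signs @ d
    obs = abs(float(d.sum()))
    tol = 1e-9 * max(obs, 1.0) + 1e-12
    hits = int(np.count_nonzero(np.abs(sums) >= obs - tol))
    p = (1 + hits) / (n_perm + 1)
    return TestResult(
        statistic=stat, p_value=p, method="paired_permutation",
        exact=False, n_permutations=n_perm, seed=seed,
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def rank_sum_test(x, y) -> TestResult:
    """Two-sided Mann-Whitney rank-sum test.

    U is computed from midranks (ties allowed).  With n + m <= 12 and no
    ties the two-sided p comes from exact enumeration of all C(n+m, n)
    rank arrangements; otherwise a normal approximation with tie
    correction and a continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    rank_x = ranks[:n].sum()
    u = rank_x - n * (n + 1) / 2.0
    mid = n * m / 2.0
    dev = abs(u - mid)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n + m <= 12 and not has_ties:
        total = math.comb(n + m, n)
        all_ranks = np.arange(1, n + m + 1)
        count = 0
        for combo in itertools.combinations(range(n + m), n):
            u_c = all_ranks[list(combo)].sum() - n * (n + 1) / 2.0
            if abs(u_c - mid) >= dev - 1e-12:
                count += 1
        return TestResult(
            statistic=float(u), p_value=count / total, method="rank_sum",
            exact=True, n_permutations=total,
        )
    # normal approximation with tie correction
    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # every pooled value identical
        return TestResult(
            statistic=float(u), p_value=1.0, method="rank_sum",
            exact=False, degenerate=True,
        )
    z = max(dev - 0.5, 0.0) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return TestResult(statistic=float(u), p_value=p, method="rank_sum", exact=False)
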