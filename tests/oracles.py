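"""Brute-force enumeration oracles, independent of the implementations they check."""

from itertools import combinations
from math import comb


def rank_sum_p_exact(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments.

    Uses midranks, so it is exact for tied data too (permutation null on
    the U statistic's distance from its mean).
    """
    pooled = sorted(list(a) + list(b))
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        midrank = (i + 1 + j) / 2.0
        ranks[pooled[i]] = midrank
        i = j
    values = list(a) + list(b)
    n_a, n_b = len(a), len(b)
    all_ranks = [ranks[v] for v in values]
    mean_u = n_a * n_b / 2.0

    def u_stat(indices):
        r = sum(all_ranks[i] for i in indices)
        return r - n_a * (n_a + 1) / 2.0

    observed = abs(u_stat(range(n_a)) - mean_u)
    total = hits = 0
    for idx in combinations(range(n_a + n_b), n_a):
        total += 1
        if abs(u_stat(idx) - mean_u) >= observed - 1e-12:
            hits += 1
    return hits / total


def hypergeom_tail(k, n, K, N):
    """P(X >= k) for X hypergeometric(N, K, n), by direct summation."""
    denom = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(n, K) + 1)) / denom


def permutation_t_p(a, b):
    """Two-sided permutation p-value on the difference of means."""
    values = list(a) + list(b)
    n_a = len(a)
    observed = abs(sum(a) / n_a - sum(b) / len(b))
    total = hits = 0
    for idx in combinations(range(len(values)), n_a):
        total += 1
        grp_a = [values[i] for i in idx]
        grp_b = [values[i] for i in range(len(values)) if i not in set(idx)]
        diff = abs(sum(grp_a) / len(grp_a) - sum(grp_b) / len(grp_b))
        if diff >= observed - 1e-12:
            hits += 1
    return hits / total
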