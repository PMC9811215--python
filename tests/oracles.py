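"""Independent brute-force oracles used to check the analysis code.

Everything here is deliberately naive — full enumeration and direct
summation — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def exact_rank_sum_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled ranks to the two groups (no ties assumed)."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n = len(x), len(x) + len(y)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    center = n1 * (n - n1) / 2.0
    dist = []
    for combo in itertools.combinations(range(1, n + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        dist.append(abs(u - center))
    d_obs = abs(u_obs - center)
    return sum(d >= d_obs - 1e-12 for d in dist) / len(dist)


def permutation_kruskal_p(samples, n_max: int = 9) -> float:
    """Exact permutation p for the Kruskal-Wallis H statistic (no ties)."""
    sizes = [len(s) for s in samples]
    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    n = len(pooled)
    assert n <= n_max, "enumeration limited to small instances"
    order = pooled.argsort()
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)

    def h_stat(rank_groups):
        h = 0.0
        for r in rank_groups:
            h += sum(r) ** 2 / len(r)
        return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)

    idx = 0
    obs_groups = []
    for size in sizes:
        obs_groups.append(ranks[idx:idx + size])
        idx += size
    h_obs = h_stat(obs_groups)

    count = total = 0
    for perm in itertools.permutations(range(1, n + 1)):
        groups, idx = [], 0
        for size in sizes:
            groups.append(perm[idx:idx + size])
            idx += size
        total += 1
        if h_stat(groups) >= h_obs - 1e-12:
            count += 1
    return count / total


def kruskal_h_bruteforce(samples) -> float:
    """Kruskal-Wallis H from the textbook rank-sum formula (no ties)."""
    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    n = len(pooled)
    order = pooled.argsort()
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    h, idx = 0.0, 0
    for s in samples:
        r = ranks[idx:idx + len(s)]
        h += r.sum() ** 2 / len(s)
        idx += len(s)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def all_rank_partitions(n_total: int):
    """Yield (x_ranks, y_ranks) for every two-group split of 1..n_total
    with both groups nonempty."""
    universe = list(range(1, n_total + 1))
    for n1 in range(1, n_total):
        for combo in itertools.combinations(universe, n1):
            x = list(combo)
            y = [v for v in universe if v not in combo]
            yield x, y
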