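"""Independent brute-force oracles, written separately from the package
implementations they check (naive sums, explicit BFS, pair enumeration)."""

from collections import deque
from itertools import product

import numpy as np


def naive_skewness(values) -> float:
    x = list(map(float, values))
    n = len(x)
    m = sum(x) / n
    s2 = sum((v - m) ** 2 for v in x) / (n - 1)
    s3 = sum((v - m) ** 3 for v in x) / (n - 1)
    return s3 / s2**1.5


def naive_kurtosis(values, excess=False) -> float:
    x = list(map(float, values))
    n = len(x)
    m = sum(x) / n
    s2 = sum((v - m) ** 2 for v in x) / (n - 1)
    s4 = sum((v - m) ** 4 for v in x) / (n - 1)
    k = s4 / s2**2
    return k - 3.0 if excess else k


def naive_cyhelsky(values) -> float:
    x = list(map(float, values))
    m = sum(x) / len(x)
    below = sum(1 for v in x if v < m)
    above = sum(1 for v in x if v > m)
    return (below - above) / len(x)


def naive_pearson_median(values) -> float:
    x = sorted(map(float, values))
    n = len(x)
    m = sum(x) / n
    md = x[n // 2] if n % 2 else (x[n // 2 - 1] + x[n // 2]) / 2.0
    sd = (sum((v - m) ** 2 for v in x) / (n - 1)) ** 0.5
    return 3.0 * (m - md) / sd


def bfs_flood_fill(counts, seed, include_fraction, connectivity, absolute_floor=None):
    """Breadth-first flood fill from the seed under the inclusion rule."""
    counts = np.asarray(counts, dtype=float)
    cut = include_fraction * counts[seed]
    if absolute_floor is not None:
        cut = max(cut, absolute_floor)
    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offs = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    shape = counts.shape
    mask = np.zeros(shape, dtype=bool)
    if counts[seed] < cut:
        return mask
    mask[seed] = True
    queue = deque([seed])
    while queue:
        i, j, k = queue.popleft()
        for di, dj, dk in offs:
            p = (i + di, j + dj, k + dk)
            if not all(0 <= p[a] < shape[a] for a in range(3)):
                continue
            if not mask[p] and counts[p] >= cut:
                mask[p] = True
                queue.append(p)
    return mask


def pairwise_u(a, b) -> float:
    """Mann-Whitney U of `a` by direct pair enumeration (half-ties)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def concordant_pair_auc(pos_scores, neg_scores) -> float:
    """AUC as the fraction of concordant (pos > neg) pairs, half for ties."""
    return pairwise_u(pos_scores, neg_scores) / (len(pos_scores) * len(neg_scores))
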