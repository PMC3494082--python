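"""Independent brute-force oracles shared across test modules."""

from itertools import combinations

import numpy as np


def brute_force_two_partition(z):
    """Exhaustive minimum within-cluster sum of squares over all 2-partitions.

    Returns ``(objective, frozenset_of_left_indices)``.  Only feasible for a
    handful of points; used as the ground truth against Lloyd's algorithm.
    """
    n = z.shape[0]
    best = (np.inf, None)
    for r in range(1, n // 2 + 1):
        for left in combinations(range(n), r):
            left = list(left)
            right = [i for i in range(n) if i not in left]
            obj = 0.0
            for side in (left, right):
                c = z[side].mean(axis=0)
                obj += float(((z[side] - c) ** 2).sum())
            if obj < best[0]:
                best = (obj, frozenset(left))
    return best
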