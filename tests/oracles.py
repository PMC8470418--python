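"""Independent oracles used to validate the package's core numerics.

These deliberately avoid the code paths they check: Ward agglomeration is
recomputed from the *original* distance matrix with the closed-form
between-cluster criterion (no Lance-Williams recursion), and the
hypergeometric tail is obtained by exhaustively enumerating draws.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left

import numpy as np


def ward_between(A, B, S: np.ndarray) -> float:
    """Squared Ward.D2 distance between clusters from raw squared distances.

    Uses the centroid identity: ||cA - cB||^2 equals the mean cross-pair
    squared distance minus half the mean within-pair squared distance of
    each cluster; the Ward criterion is 2|A||B|/(|A|+|B|) times that.
    """
    A = list(A)
    B = list(B)
    cross = S[np.ix_(A, B)].sum()
    wA = S[np.ix_(A, A)].sum()
    wB = S[np.ix_(B, B)].sum()
    na, nb = len(A), len(B)
    centroid_sq = cross / (na * nb) - wA / (2 * na**2) - wB / (2 * nb**2)
    return (2.0 * na * nb / (na + nb)) * centroid_sq


def brute_force_ward(D: np.ndarray):
    """Greedy Ward.D2 agglomeration recomputed from scratch at every step.

    Returns a list of merges ``(members_a, members_b, height)`` with the
    same lexicographic tie rule as the implementation: among
    equal-criterion pairs, merge the one with the smallest
    (min member, max-of-min members) representative pair.
    """
    n = D.shape[0]
    S = D.astype(float) ** 2
    active = [frozenset([i]) for i in range(n)]
    merges = []
    while len(active) > 1:
        best = None
        best_val = None
        best_key = None
        for x, y in itertools.combinations(range(len(active)), 2):
            val = ward_between(active[x], active[y], S)
            ra, rb = min(active[x]), min(active[y])
            key = (min(ra, rb), max(ra, rb))
            if (
                best_val is None
                or val < best_val - 1e-9 * max(abs(best_val), 1.0)
                or (abs(val - best_val) <= 1e-9 * max(abs(best_val), 1.0)
                    and key < best_key)
            ):
                best, best_val, best_key = (x, y), val, key
        x, y = best
        merged = active[x] | active[y]
        merges.append((active[x], active[y], float(np.sqrt(max(best_val, 0.0)))))
        active = [c for i, c in enumerate(active) if i not in (x, y)] + [merged]
    return merges


def linkage_to_merges(Z: np.ndarray, n: int):
    """Reconstruct ``(members_a, members_b, height)`` from a linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k in range(n - 1):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        merges.append((members[a], members[b], float(Z[k, 2])))
        members[n + k] = members[a] | members[b]
    return merges


def hypergeom_tail_by_enumeration(N: int, K: int, n: int):
    """Upper-tail probabilities P(X >= k) for all k, by enumerating draws.

    The population is 0..N-1 with 0..K-1 annotated; every size-n draw is
    enumerated and the number of annotated members counted.
    """
    annotated_hist = np.zeros(min(n, K) + 1)
    total = 0
    marked = list(range(K))
    for draw in itertools.combinations(range(N), n):
        hits = bisect_left(draw, K)  # draws are sorted tuples
        annotated_hist[hits] += 1
        total += 1
    probs = annotated_hist / total
    # tail[k] = P(X >= k)
    return np.cumsum(probs[::-1])[::-1]
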