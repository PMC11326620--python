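"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive results by the most literal route available
(full prefix enumeration, O(n^3) agglomeration, direct summation) and share
no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_decompose(volumes, labels, relevant_share=0.99, dominant_share=0.80):
    """Enumerate every prefix of the descending-sorted entities.

    Returns (total, relevant, dominant, minor, pareto_index_percent).
    """
    pairs = [(v, l) for v, l in zip(volumes, labels) if v > 0]
    pairs.sort(key=lambda p: (-p[0], p[1]))
    total_vol = sum(v for v, _ in pairs)
    n = len(pairs)

    def smallest_prefix(target):
        acc = 0.0
        for k in range(1, n + 1):
            acc += pairs[k - 1][0]
            if acc >= target - 1e-9 * total_vol:
                return k
        return n

    relevant = smallest_prefix(relevant_share * total_vol)
    dominant = smallest_prefix(dominant_share * total_vol)
    return n, relevant, dominant, n - relevant, 100.0 * dominant / relevant


def shannon_direct(volumes):
    """Direct summation of −p ln p over positive volumes."""
    vs = [v for v in volumes if v > 0]
    tot = sum(vs)
    return -sum((v / tot) * math.log(v / tot) for v in vs)


def naive_ward_agglomerate(points: np.ndarray):
    """O(n^3) greedy Ward agglomeration over a row matrix.

    At each step merge the globally closest pair (ties: lexicographically
    smallest cluster-id pair) and update distances with the Lance-Williams
    Ward formula on Euclidean distances.  Returns scipy-style rows
    (id_a, id_b, height, size), new cluster ids n, n+1, ...
    """
    n = len(points)
    active = {i: (1, i) for i in range(n)}  # id -> (size, _)
    dist = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = float(np.linalg.norm(points[i] - points[j]))
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    ids = set(range(n))
    for _ in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b, h, sizes[a] + sizes[b]))
        ids.discard(a)
        ids.discard(b)
        new_dist = {}
        for k in ids:
            d_ak = dist[tuple(sorted((a, k)))]
            d_bk = dist[tuple(sorted((b, k)))]
            d_ab = h
            na, nb, nk = sizes[a], sizes[b], sizes[k]
            d2 = ((na + nk) * d_ak ** 2 + (nb + nk) * d_bk ** 2
                  - nk * d_ab ** 2) / (na + nb + nk)
            new_dist[(k, next_id)] = math.sqrt(max(d2, 0.0))
        dist = {pair: d for pair, d in dist.items()
                if a not in pair and b not in pair}
        dist.update({tuple(sorted(p)): d for p, d in new_dist.items()})
        sizes[next_id] = sizes[a] + sizes[b]
        ids.add(next_id)
        next_id += 1
    return merges
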