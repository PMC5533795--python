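"""Independent reference implementations used only to check the package.

Each oracle is written directly from the defining formula or by exhaustive
enumeration, deliberately avoiding the code paths it validates.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def welch_t_oracle(x1, x2) -> float:
    """Textbook Welch statistic computed with explicit loops."""
    n1, n2 = len(x1), len(x2)
    m1 = sum(x1) / n1
    m2 = sum(x2) / n2
    v1 = sum((v - m1) ** 2 for v in x1) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in x2) / (n2 - 1)
    return (m1 - m2) / math.sqrt(v1 / n1 + v2 / n2)


def bh_oracle(pvals):
    """Brute-force step-up definition: adj(i) = min over j with p(j) >= p(i)
    ranked at or after i of min(1, p(j)*m/rank(j))."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [0.0] * m
    for pos in range(m):
        candidates = [
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(pos, m)
        ]
        adj_sorted[pos] = min(candidates)
    out = [0.0] * m
    for pos, idx in enumerate(order):
        out[idx] = adj_sorted[pos]
    return out


def hypergeom_tail_oracle(overlap, query, term, background) -> float:
    """Exact upper-tail P(X >= overlap) as a sum of point masses."""
    total = math.comb(background, query)
    acc = 0
    for x in range(overlap, min(query, term) + 1):
        if query - x > background - term:
            continue
        acc += math.comb(term, x) * math.comb(background - term, query - x)
    return acc / total


def connected_subgraph_optimum(adjacency, abs_scores, seed_idx, method="norm_agg"):
    """Maximum module score over all connected subgraphs containing the seed.

    ``adjacency`` is a list of neighbor-index sets; exhaustive over all
    2^n subsets (intended for n <= 12), connectivity checked by bitmask BFS.
    """
    n = len(adjacency)
    adj_mask = [0] * n
    for i, nbrs in enumerate(adjacency):
        for j in nbrs:
            adj_mask[i] |= 1 << j
    best = -math.inf
    seed_bit = 1 << seed_idx
    for mask in range(1, 1 << n):
        if not mask & seed_bit:
            continue
        # BFS over the subset
        frontier = seed_bit
        reached = seed_bit
        while frontier:
            nxt = 0
            m = frontier
            while m:
                low = m & -m
                nxt |= adj_mask[low.bit_length() - 1]
                m ^= low
            nxt &= mask & ~reached
            reached |= nxt
            frontier = nxt
        if reached != mask:
            continue
        total = 0.0
        size = 0
        m = mask
        while m:
            low = m & -m
            total += abs_scores[low.bit_length() - 1]
            size += 1
            m ^= low
        score = total if method == "sum" else total / math.sqrt(size)
        if score > best:
            best = score
    return best


def knn_oracle(train_x, train_y, test_vec, k):
    """Reference KNN: explicit distance loop, majority vote, vote ties broken
    by the nearest tied-class neighbor, distance ties by sample order."""
    dists = []
    for i, row in enumerate(train_x):
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(row, test_vec)))
        dists.append((d, i))
    dists.sort()
    nearest = [i for _, i in dists[:k]]
    counts = {}
    for i in nearest:
        counts[train_y[i]] = counts.get(train_y[i], 0) + 1
    top = max(counts.values())
    tied = {c for c, v in counts.items() if v == top}
    if len(tied) == 1:
        return tied.pop()
    for i in nearest:
        if train_y[i] in tied:
            return train_y[i]
    raise AssertionError


def overlap_rate_oracle(sets):
    """Literal evaluation of the overlap-rate formula."""
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    denom = sum(len(s) for s in sets) - len(common)
    return 100.0 * len(common) / denom if denom else 0.0


def enumerate_pair_overlaps(sets):
    """All pairwise overlap rates by direct enumeration."""
    return [
        overlap_rate_oracle([a, b]) for a, b in combinations(sets, 2)
    ]


def random_connected_graph(n_nodes, edge_prob, rng):
    """Random graph (as adjacency sets) made connected with a random spanning
    tree; node scores drawn half-normal."""
    adjacency = [set() for _ in range(n_nodes)]
    order = list(range(n_nodes))
    rng.shuffle(order)
    for a, b in zip(order, order[1:]):
        adjacency[a].add(b)
        adjacency[b].add(a)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                adjacency[i].add(j)
                adjacency[j].add(i)
    scores = np.abs(rng.normal(0, 2, n_nodes))
    return adjacency, scores
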