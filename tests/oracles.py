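"""Independent brute-force oracles used only by the test suite.

These re-derive expected values by explicit enumeration, structured
differently from the library implementations they check.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def step_dissimilarity(a: int, b: int, motif: int) -> float:
    return 1.0 - 0.5 ** (abs(a - b) // motif)


def min_matching_distance(g1: tuple, g2: tuple, motif: int) -> float:
    """Equal-ploidy Bruvo distance by recursive minimum-cost perfect matching."""
    if not g1:
        return 0.0
    a, rest = g1[0], g1[1:]
    best = min(
        step_dissimilarity(a, g2[i], motif)
        + min_matching_distance(rest, g2[:i] + g2[i + 1 :], motif) * len(rest)
        for i in range(len(g2))
    )
    return best / len(g1)


def bruvo_bruteforce(g1, g2, motif, add=True, loss=True) -> float:
    """Bruvo distance by full enumeration of virtual-allele completions."""
    g1, g2 = tuple(sorted(g1)), tuple(sorted(g2))
    if len(g1) == len(g2):
        return min_matching_distance(g1, g2, motif)
    small, large = (g1, g2) if len(g1) < len(g2) else (g2, g1)
    d = len(large) - len(small)
    results = []
    for donor_pool in ([small] if add else []) + ([large] if loss else []):
        donors = sorted(set(donor_pool))
        vals = [
            min_matching_distance(tuple(sorted(small + extra)), large, motif)
            for extra in itertools.product(donors, repeat=d)
        ]
        results.append(sum(vals) / len(vals))
    return sum(results) / len(results)


def rarefaction_enumeration(copy_counts: dict, n: int) -> float:
    """Mean distinct-allele count over every size-n subsample (integer counts)."""
    pool = [a for a, c in copy_counts.items() for _ in range(int(c))]
    total = 0
    count = 0
    for subset in itertools.combinations(range(len(pool)), n):
        total += len({pool[i] for i in subset})
        count += 1
    assert count == comb(len(pool), n)
    return total / count


def random_additive_tree(rng, n_taxa: int):
    """A random binary tree with positive branch lengths, returned as
    (newick-free) pairwise tip distance matrix plus labels.

    Built by sequential taxon attachment: tip k joins a uniformly chosen
    existing edge, which is an independent construction from neighbor
    joining.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency: node -> list of (node, length); tips are 0..n-1
    next_node = n_taxa
    edges = {}

    def add_edge(u, v, w):
        edges.setdefault(u, []).append((v, w))
        edges.setdefault(v, []).append((u, w))

    def remove_edge(u, v):
        edges[u] = [(x, w) for x, w in edges[u] if x != v]
        edges[v] = [(x, w) for x, w in edges[v] if x != u]

    def blen():
        return float(rng.uniform(0.05, 1.0))

    add_edge(0, 1, blen())
    for tip in range(2, n_taxa):
        all_edges = sorted(
            {tuple(sorted((u, v))) for u in edges for v, _ in edges[u]}
        )
        u, v = all_edges[rng.integers(0, len(all_edges))]
        w = dict(edges[u])[v]
        mid = next_node
        next_node += 1
        remove_edge(u, v)
        cut = float(rng.uniform(0.2, 0.8)) * w
        add_edge(u, mid, cut)
        add_edge(mid, v, w - cut)
        add_edge(mid, tip, blen())

    # all-pairs tip distances by BFS
    n = n_taxa
    dist = np.zeros((n, n))
    for src in range(n):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in edges[node]:
                if nb not in seen:
                    seen[nb] = seen[node] + w
                    stack.append(nb)
        for dst in range(n):
            dist[src, dst] = seen[dst]
    return labels, dist
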