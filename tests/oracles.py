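"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — exhaustive enumeration, exact
rational arithmetic, BFS path counting — and shares no code with the
package paths it checks.
"""
from __future__ import annotations

import itertools
from bisect import bisect_left
from fractions import Fraction
from math import comb


def enumerate_overlap_counts(m: int, n: int, t: int) -> list:
    """Count, over all C(m, n) subsets of an m-element universe, how many
    contain exactly i of the first t elements; returns counts[0..min(n,t)].
    """
    counts = [0] * (min(n, t) + 1)
    for combo in itertools.combinations(range(m), n):
        counts[bisect_left(combo, t)] += 1
    return counts


def exact_tail_from_counts(counts: list, m: int, n: int, r: int) -> float:
    """P(X >= r) as an exact ratio of subset counts, evaluated in float."""
    total = comb(m, n)
    return sum(counts[r:]) / total


def literal_complement_tail(r: int, m: int, n: int, t: int) -> Fraction:
    """The complement form 1 - sum_{i=0}^{r-1} C(t,i) C(m-t,n-i) / C(m,n),
    evaluated in exact rational arithmetic.
    """
    denom = comb(m, n)
    acc = Fraction(0)
    for i in range(r):
        if i <= t and 0 <= n - i <= m - t:
            acc += Fraction(comb(t, i) * comb(m - t, n - i), denom)
    return 1 - acc


def brute_betweenness(nodes, edges) -> dict:
    """Unnormalized betweenness by explicit shortest-path enumeration.

    For every unordered node pair (s, t) all shortest s-t paths are listed
    by breadth-first layering; each interior node of each path accrues
    1 / (number of shortest s-t paths).
    """
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    bc = {v: 0.0 for v in nodes}
    nodes = list(nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            w = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += w
    return bc


def _all_shortest_paths(adj, s, t):
    # BFS distances from s, then DFS back from t along strictly decreasing
    # distance to enumerate every shortest path.
    dist = {s: 0}
    frontier = [s]
    while frontier and t not in dist:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if t not in dist:
        return []
    paths = []

    def walk(v, suffix):
        if v == s:
            paths.append([s] + suffix)
            return
        for u in adj[v]:
            if dist.get(u, -1) == dist[v] - 1:
                walk(u, [v] + suffix)

    walk(t, [])
    return paths


def brute_bh(pvals) -> list:
    """Benjamini-Hochberg by the literal definition:
    adj(p_(i)) = min_{j >= i} min(1, p_(j) * m / j), mapped back to input order.
    """
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    capped = [min(1.0, pvals[order[j]] * m / (j + 1)) for j in range(m)]
    out = [0.0] * m
    for rank_i, idx in enumerate(order):
        out[idx] = min(capped[rank_i:])
    return out
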