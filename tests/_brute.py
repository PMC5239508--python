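"""Independent brute-force oracles used only by the test suite.

Deliberately naive: all-pairs BFS with explicit shortest-path enumeration
for betweenness, the component-adjusted closeness formula written out, and
k-core by literal peeling.  Kept free of networkx centrality calls so the
oracle shares nothing with the code path it checks.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def brute_topology(edges: list[tuple], nodes: list) -> dict:
    """degree/betweenness/closeness(WF)/kcoreness for a small simple graph."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    n = len(nodes)
    dist = {s: bfs_distances(adj, s) for s in nodes}

    betweenness = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        paths: list[tuple] = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(tuple(path))
                return
            for w in adj[u]:
                if (
                    dist[s].get(w) == dist[s][u] + 1
                    and w in dist[t]
                    and dist[s][w] + dist[t][w] == d_st
                ):
                    extend(path + [w])

        extend([s])
        for path in paths:
            for v in path[1:-1]:
                betweenness[v] += 1.0 / len(paths)

    closeness = {}
    for v in nodes:
        reach = dist[v]
        r = len(reach)  # incl. self
        total = sum(reach.values())
        if total == 0 or n < 2:
            closeness[v] = 0.0
        else:
            closeness[v] = ((r - 1) / total) * ((r - 1) / (n - 1))

    coreness = {v: 0 for v in nodes}
    k = 1
    alive = set(nodes)
    while alive:
        # peel at level k: repeatedly drop nodes with degree < k
        current = set(alive)
        changed = True
        while changed:
            changed = False
            for v in list(current):
                if sum(1 for w in adj[v] if w in current) < k:
                    current.remove(v)
                    changed = True
        for v in current:
            coreness[v] = k
        alive = current
        k += 1

    degree = {v: len(adj[v]) for v in nodes}
    return {
        "degree": degree,
        "betweenness": betweenness,
        "closeness": closeness,
        "kcoreness": coreness,
    }


def hypergeom_tail_exact(k: int, n: int, big_k: int, big_n: int) -> Fraction:
    """Exact P(X ≥ k) as a rational, by summing the pmf."""
    from math import comb

    total = comb(big_n, n)
    acc = Fraction(0)
    for i in range(k, min(n, big_k) + 1):
        acc += Fraction(comb(big_k, i) * comb(big_n - big_k, n - i), total)
    return acc


def hypergeom_tail_by_enumeration(big_n: int) -> dict:
    """Overlap-tail distributions from literal enumeration of all draws.

    Iterates every subset of a ``big_n``-element universe; for each query
    size n and each pathway = the first K elements, tallies the overlap
    distribution.  Returns ``tails[(k, n, K)] = P(X >= k)`` as Fractions.
    """
    from math import comb

    counts: dict[tuple[int, int, int], int] = {}
    for mask in range(1 << big_n):
        n = bin(mask).count("1")
        for big_k in range(1, big_n + 1):
            overlap = bin(mask & ((1 << big_k) - 1)).count("1")
            counts[(n, big_k, overlap)] = counts.get((n, big_k, overlap), 0) + 1
    tails: dict[tuple[int, int, int], Fraction] = {}
    for n in range(1, big_n + 1):
        total = comb(big_n, n)
        for big_k in range(1, big_n + 1):
            upper = min(n, big_k)
            acc = 0
            for k in range(upper, -1, -1):
                acc += counts.get((n, big_k, k), 0)
                tails[(k, n, big_k)] = Fraction(acc, total)
    return tails
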