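"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive: exhaustive path enumeration,
rational arithmetic, direct double sums, full partition enumeration.
None of it shares code with the package.
"""

from __future__ import annotations

import random
from collections import deque
from fractions import Fraction
from math import comb

import numpy as np

from ppinet import Network


def net_from_edges(pairs, seeds=(), weights=None) -> Network:
    """Build a Network from (u, v) pairs with optional weights."""
    edges = {}
    nodes = set(seeds)
    for idx, (u, v) in enumerate(pairs):
        w = 1.0 if weights is None else weights[idx]
        key = (u, v) if u <= v else (v, u)
        edges[key] = w
        nodes.update(key)
    seed_set = set(seeds)
    return Network(edges=edges, seed_flags={u: u in seed_set for u in sorted(nodes)})


def random_connected_graph(rng: random.Random, n: int) -> list[tuple[str, str]]:
    """Random connected labeled graph: random spanning tree + extra edges."""
    names = [f"N{i}" for i in range(n)]
    pairs = set()
    order = names[:]
    rng.shuffle(order)
    for i in range(1, n):
        other = order[rng.randrange(i)]
        u, v = sorted((order[i], other))
        pairs.add((u, v))
    n_extra = rng.randrange(0, n)
    candidates = [
        (a, b) for i, a in enumerate(names) for b in names[i + 1 :]
        if (a, b) not in pairs
    ]
    rng.shuffle(candidates)
    pairs.update(candidates[:n_extra])
    return sorted(pairs)


def _adjacency(pairs) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for u, v in pairs:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def _all_shortest_paths(adj, s, t) -> list[list[str]]:
    """Every shortest s-t path, by BFS layering then DFS back-tracing."""
    dist = {s: 0}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if t not in dist:
        return []
    paths = []

    def back(node, path):
        if node == s:
            paths.append([s] + path[::-1])
        for p in adj[node]:
            if dist.get(p, -1) == dist[node] - 1:
                back(p, path + [node])

    back(t, [])
    return paths


def brute_betweenness(pairs, nodes) -> dict[str, float]:
    """Normalized betweenness from explicit enumeration of all shortest
    paths between every unordered pair (endpoints excluded)."""
    adj = {u: set() for u in nodes}
    for u, v in pairs:
        adj[u].add(v)
        adj[v].add(u)
    n = len(nodes)
    bc = {u: 0.0 for u in nodes}
    node_list = sorted(nodes)
    for i, s in enumerate(node_list):
        for t in node_list[i + 1 :]:
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / len(paths)
    if n > 2:
        norm = (n - 1) * (n - 2) / 2
        bc = {u: val / norm for u, val in bc.items()}
    return bc


def brute_closeness(pairs, nodes) -> dict[str, float]:
    adj = {u: set() for u in nodes}
    for u, v in pairs:
        adj[u].add(v)
        adj[v].add(u)
    n = len(nodes)
    out = {}
    for u in nodes:
        dist = {u: 0}
        queue = deque([u])
        while queue:
            x = queue.popleft()
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    queue.append(y)
        r = len(dist) - 1
        out[u] = 0.0 if r == 0 else (r / (n - 1)) * (r / sum(dist.values()))
    return out


def brute_clustering(pairs, nodes) -> dict[str, float]:
    adj = {u: set() for u in nodes}
    for u, v in pairs:
        adj[u].add(v)
        adj[v].add(u)
    out = {}
    for u in nodes:
        nbrs = sorted(adj[u])
        k = len(nbrs)
        if k < 2:
            out[u] = 0.0
            continue
        tri = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if nbrs[j] in adj[nbrs[i]]
        )
        out[u] = 2 * tri / (k * (k - 1))
    return out


def dense_eigenvector(pairs, nodes) -> dict[str, float]:
    """Dominant adjacency eigenvector via dense symmetric decomposition."""
    node_list = sorted(nodes)
    idx = {u: i for i, u in enumerate(node_list)}
    a = np.zeros((len(node_list), len(node_list)))
    for u, v in pairs:
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    vals, vecs = np.linalg.eigh(a)
    vec = vecs[:, np.argmax(vals)]
    if vec.sum() < 0:
        vec = -vec
    vec = vec / np.linalg.norm(vec)
    # Perron vector of a connected graph is strictly positive
    return {u: float(vec[idx[u]]) for u in node_list}


def modularity_double_sum(net: Network, assignment, gamma=1.0, weighted=True):
    """Q = sum_ij (A_ij - gamma k_i k_j / 2W) delta(c_i, c_j) / 2W."""
    nodes = sorted(net.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for (u, v), w in net.edges.items():
        w = w if weighted else 1.0
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    k = a.sum(axis=1)
    two_w = a.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[nodes[i]] == assignment[nodes[j]]:
                q += a[i, j] - gamma * k[i] * k[j] / two_w
    return q / two_w


def all_partitions(items):
    """Every set partition of `items` (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield smaller + [[first]]


def hypergeom_tail_rational(k, K, n, N) -> Fraction:
    """Exact P(X >= k) in rational arithmetic."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def bh_direct(pvalues):
    """Literal step-up: adj_(i) = min_{j>=i} p_(j) m / j, input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    out = [0.0] * m
    for rank_i in range(1, m + 1):
        idx = order[rank_i - 1]
        out[idx] = min(
            min(pvalues[order[rank_j - 1]] * m / rank_j for rank_j in range(rank_i, m + 1)),
            1.0,
        )
    return out
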