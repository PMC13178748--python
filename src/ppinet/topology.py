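"""Per-node centralities and global statistics, computed from scratch.

All metrics run on the unweighted graph (hop counts, edge multiplicity
one): the combined-score weights annotate confidence, not distance, and
the reported conventions are the standard hop-count ones.  Every value
is normalized to [0, 1]:

- degree centrality  C_D(u) = deg(u) / (n - 1)
- betweenness        C_B(u) = sum of pair-dependencies / ((n-1)(n-2)/2),
  endpoints excluded (Brandes accumulation)
- closeness          C_C(u) = (r / (n-1)) * (r / S) with r reachable
  nodes and S their total hop distance (component-corrected form;
  reduces to (n-1)/S on connected graphs)
- eigenvector        C_E = dominant adjacency eigenvector, Euclidean
  norm 1 over all nodes
- clustering         c_u = 2 * triangles(u) / (deg(u) * (deg(u) - 1))
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import TextIO

from .errors import ConvergenceError, DegenerateInputError
from .network_build import Network, connected_components


@dataclass(frozen=True)
class NodeMetrics:
    """All five normalized per-node values."""

    degree_centrality: float
    betweenness: float
    closeness: float
    eigenvector: float
    clustering: float


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-graph statistics; path metrics cover the largest connected
    component and are ``None`` when that component is a single node."""

    n_nodes: int
    n_edges: int
    density: float
    avg_clustering: float
    diameter_lcc: int | None
    avg_shortest_path_lcc: float | None


def degree_centrality(net: Network) -> dict[str, float]:
    if net.n_nodes < 2:
        raise DegenerateInputError(
            f"degree centrality needs >= 2 nodes, got {net.n_nodes}"
        )
    denom = net.n_nodes - 1
    return {u: net.degree(u) / denom for u in net.sorted_nodes()}


def _bfs_distances(net: Network, source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in net.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def betweenness_centrality(net: Network) -> dict[str, float]:
    """Brandes' algorithm over unweighted shortest paths.

    Raw pair-dependency sums are divided by (n-1)(n-2)/2, the number of
    unordered pairs a node can mediate; endpoints are excluded.
    """
    nodes = net.sorted_nodes()
    n = len(nodes)
    bc = {u: 0.0 for u in nodes}
    if n <= 2:
        return bc
    for s in nodes:
        # single-source shortest-path counts
        stack: list[str] = []
        preds: dict[str, list[str]] = {u: [] for u in nodes}
        sigma = {u: 0.0 for u in nodes}
        sigma[s] = 1.0
        dist = {u: -1 for u in nodes}
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in net.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation, leaves inward
        delta = {u: 0.0 for u in nodes}
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
        # each unordered pair is visited from both endpoints
    norm = (n - 1) * (n - 2)  # = 2 * (n-1)(n-2)/2, absorbing the double count
    return {u: bc[u] / norm for u in nodes}


def closeness_centrality(net: Network) -> dict[str, float]:
    nodes = net.sorted_nodes()
    n = len(nodes)
    out: dict[str, float] = {}
    for u in nodes:
        dist = _bfs_distances(net, u)
        r = len(dist) - 1
        if r == 0 or n < 2:
            out[u] = 0.0
            continue
        total = sum(dist.values())
        out[u] = (r / (n - 1)) * (r / total)
    return out


def eigenvector_centrality(
    net: Network, tol: float = 1e-6, max_iter: int = 1000
) -> dict[str, float]:
    """Dominant eigenvector of the unweighted adjacency by power iteration.

    Iterates on A + I (same eigenvectors; the identity shift prevents
    the sign oscillation pure A-iteration exhibits on bipartite graphs)
    from the uniform vector, Euclidean-normalizing each step, until the
    max per-node change drops below ``tol``.  On disconnected graphs the
    values of the component with the largest spectral radius dominate.
    """
    if net.n_edges < 1:
        raise DegenerateInputError("eigenvector centrality needs >= 1 edge")
    nodes = net.sorted_nodes()
    n = len(nodes)
    x = {u: 1.0 / math.sqrt(n) for u in nodes}
    for _ in range(max_iter):
        x_new = dict(x)  # the +I term
        for u in nodes:
            for v in net.neighbors(u):
                x_new[u] += x[v]
        norm = math.sqrt(sum(val * val for val in x_new.values()))
        x_new = {u: val / norm for u, val in x_new.items()}
        residual = max(abs(x_new[u] - x[u]) for u in nodes)
        x = x_new
        if residual < tol:
            return x
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations",
        residual=residual,
    )


def local_clustering(net: Network) -> dict[str, float]:
    out: dict[str, float] = {}
    for u in net.sorted_nodes():
        nbrs = set(net.neighbors(u))
        k = len(nbrs)
        if k < 2:
            out[u] = 0.0
            continue
        links = 0
        for v in nbrs:
            links += len(nbrs & set(net.neighbors(v)))
        # each triangle edge counted twice in the scan above
        out[u] = links / (k * (k - 1))
    return out


def compute_node_metrics(
    net: Network, tol: float = 1e-6, max_iter: int = 1000
) -> dict[str, NodeMetrics]:
    """All five per-node metrics in one table."""
    dc = degree_centrality(net)
    bc = betweenness_centrality(net)
    cc = closeness_centrality(net)
    ec = eigenvector_centrality(net, tol=tol, max_iter=max_iter)
    cl = local_clustering(net)
    return {
        u: NodeMetrics(dc[u], bc[u], cc[u], ec[u], cl[u])
        for u in net.sorted_nodes()
    }


def global_metrics(net: Network) -> GlobalMetrics:
    """Density and mean clustering over the whole graph; diameter and
    mean shortest path (unordered pairs, hops) over the largest
    connected component."""
    n = net.n_nodes
    if n < 2:
        raise DegenerateInputError(f"global metrics need >= 2 nodes, got {n}")
    density = 2.0 * net.n_edges / (n * (n - 1))
    clustering = local_clustering(net)
    avg_clustering = sum(clustering.values()) / n
    lcc = connected_components(net)[0]
    if len(lcc) < 2:
        return GlobalMetrics(n, net.n_edges, density, avg_clustering, None, None)
    diameter = 0
    total = 0
    pairs = 0
    for u in sorted(lcc):
        dist = _bfs_distances(net, u)
        diameter = max(diameter, max(dist.values()))
        total += sum(dist.values())
        pairs += len(dist) - 1
    # each unordered pair counted from both endpoints
    return GlobalMetrics(
        n, net.n_edges, density, avg_clustering, diameter, total / pairs
    )


def top_k(metrics: dict[str, float], k: int) -> list[tuple[str, float]]:
    """Top-k nodes by value, descending; ties broken lexicographically.

    Values stay at full precision — rounding happens only at
    presentation (4 decimals in the hub tables).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(metrics.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def write_node_metrics(
    net: Network,
    metrics: dict[str, NodeMetrics],
    assignment: dict[str, int] | None,
    stream: TextIO,
) -> None:
    """Per-node TSV, lexicographic order, full-precision values."""
    stream.write(
        "node\tis_seed\tdegree\tdegree_centrality\tbetweenness\t"
        "closeness\teigenvector\tclustering\tcommunity_id\n"
    )
    for u in net.sorted_nodes():
        m = metrics[u]
        cid = "" if assignment is None else str(assignment[u])
        stream.write(
            f"{u}\t{int(net.seed_flags[u])}\t{net.degree(u)}\t"
            f"{m.degree_centrality!r}\t{m.betweenness!r}\t{m.closeness!r}\t"
            f"{m.eigenvector!r}\t{m.clustering!r}\t{cid}\n"
        )
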