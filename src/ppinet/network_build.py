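"""Assembling the weighted, undirected analysis graph.

Parallel records for the same unordered pair collapse to a single edge
carrying the maximum combined score (STRING flat files emit each pair
once per direction; the maximum is lossless for a symmetric
confidence).  Isolated proteins — seeds with no high-confidence partner
— are pruned by default and recorded, mirroring how a high-confidence
interactome drops disconnected seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO
from xml.sax.saxutils import escape

from .interaction_source import InteractionRecord

logger = logging.getLogger(__name__)


@dataclass
class Network:
    """Deduplicated weighted undirected graph of seeds and partners.

    ``edges`` maps canonical (sorted) node pairs to weights in (0, 1];
    ``seed_flags`` covers every node; ``pruned_isolates`` records the
    isolate-pruning build step.
    """

    edges: dict[tuple[str, str], float]
    seed_flags: dict[str, bool]
    pruned_isolates: tuple[str, ...] = ()
    _adj: dict[str, dict[str, float]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        # canonicalize storage order so float accumulations downstream
        # are independent of input record order (byte-stable outputs)
        self.seed_flags = dict(sorted(self.seed_flags.items()))
        self.edges = dict(sorted(self.edges.items()))
        adj: dict[str, dict[str, float]] = {u: {} for u in self.seed_flags}
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in adj or v not in adj:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside nodes")
            if not 0.0 < w <= 1.0:
                raise ValueError(f"edge weight {w!r} outside (0, 1]")
            adj[u][v] = w
            adj[v][u] = w
        self._adj = adj

    @property
    def nodes(self) -> set[str]:
        return set(self.seed_flags)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.seed_flags)

    @property
    def n_nodes(self) -> int:
        return len(self.seed_flags)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: str) -> dict[str, float]:
        return self._adj[node]

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    def __contains__(self, node: str) -> bool:
        return node in self.seed_flags

    def __iter__(self) -> Iterator[str]:
        return iter(self.sorted_nodes())


def build_network(
    records: Iterable[InteractionRecord],
    seeds: Iterable[str] = (),
    prune_isolates: bool = True,
) -> Network:
    """Build the analysis graph from score-filtered records.

    Node set = all record endpoints plus the seed list; duplicate pairs
    keep the maximum score.  With ``prune_isolates`` degree-0 nodes are
    removed and logged (they remain listed on ``pruned_isolates``).  The
    result is independent of record order.
    """
    seeds = list(seeds)
    edges: dict[tuple[str, str], float] = {}
    nodes: set[str] = set(seeds)
    for rec in records:
        nodes.add(rec.a)
        nodes.add(rec.b)
        key = rec.pair
        prev = edges.get(key)
        if prev is None or rec.combined_score > prev:
            edges[key] = rec.combined_score
    pruned: tuple[str, ...] = ()
    if prune_isolates:
        connected = {u for pair in edges for u in pair}
        pruned = tuple(sorted(nodes - connected))
        if pruned:
            logger.info("pruned %d isolated node(s): %s", len(pruned), ", ".join(pruned))
        nodes = connected
    seed_set = set(seeds)
    seed_flags = {u: u in seed_set for u in sorted(nodes)}
    return Network(edges=edges, seed_flags=seed_flags, pruned_isolates=pruned)


def connected_components(net: Network) -> list[set[str]]:
    """All connected components, largest first; ties broken by the
    lexicographically smallest member."""
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in net.sorted_nodes():
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            u = frontier.pop()
            for v in net.neighbors(u):
                if v not in comp:
                    comp.add(v)
                    frontier.append(v)
        seen |= comp
        comps.append(comp)
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def largest_connected_component(net: Network) -> Network:
    """Induced subgraph on the largest component (empty graph passes through).

    Seed flags are preserved; the pruning record is reset since the
    subgraph is a fresh build step.
    """
    if net.n_nodes == 0:
        return net
    comp = connected_components(net)[0]
    if len(comp) == net.n_nodes:
        return net
    edges = {
        (u, v): w for (u, v), w in net.edges.items() if u in comp and v in comp
    }
    seed_flags = {u: net.seed_flags[u] for u in sorted(comp)}
    return Network(edges=edges, seed_flags=seed_flags)


def write_edge_list(net: Network, stream: TextIO) -> None:
    """TSV edge list (node_a, node_b, weight), sorted for byte-stable output."""
    stream.write("node_a\tnode_b\tweight\n")
    for (u, v), w in sorted(net.edges.items()):
        stream.write(f"{u}\t{v}\t{w!r}\n")


def write_graphml(net: Network, stream: TextIO) -> None:
    """Minimal deterministic GraphML: node seed flags + edge weights."""
    stream.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    stream.write(
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">\n'
        '  <key id="d0" for="node" attr.name="is_seed" attr.type="boolean"/>\n'
        '  <key id="d1" for="edge" attr.name="weight" attr.type="double"/>\n'
        '  <graph edgedefault="undirected">\n'
    )
    for u in net.sorted_nodes():
        flag = "true" if net.seed_flags[u] else "false"
        stream.write(
            f'    <node id="{escape(u)}"><data key="d0">{flag}</data></node>\n'
        )
    for (u, v), w in sorted(net.edges.items()):
        stream.write(
            f'    <edge source="{escape(u)}" target="{escape(v)}">'
            f'<data key="d1">{w!r}</data></edge>\n'
        )
    stream.write("  </graph>\n</graphml>\n")
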