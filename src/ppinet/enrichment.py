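"""Local gene-set over-representation analysis (ORA).

For a query gene list against a GMT library, each set is scored with
the one-sided Fisher / hypergeometric upper tail

    p = P(X >= k),   X ~ Hypergeom(N, K, n)

(N universe genes, K set members in the universe, n query genes in the
universe, k overlap), summed directly in log-space so the tail stays
exact at interactome-scale universes (N ~ 20,000).  P-values are
adjusted per library with the Benjamini-Hochberg step-up and ranked by
adjusted p.  Over-representation only: depletion (the lower tail) is
deliberately not tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .errors import DegenerateInputError, DuplicateTermError, MalformedInputError
from .interaction_source import normalize_symbol

#: Default adjusted-p significance level.
DEFAULT_ALPHA = 0.05


@dataclass
class GeneSetCollection:
    """An ordered GMT library: name -> (description, member genes)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self.sets:
            raise DuplicateTermError(f"duplicate gene-set name {name!r}")
        members = frozenset(genes)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = (description, members)

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def names(self) -> list[str]:
        return list(self.sets)

    def universe(self) -> frozenset[str]:
        """Union of all member genes — the default test background."""
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's overlap counts and (adjusted) p-values."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    overlap_genes: frozenset[str]
    significant: bool


def read_gmt(stream: TextIO | Iterable[str]) -> GeneSetCollection:
    """Standard GMT dialect: name, description, then one or more genes."""
    coll = GeneSetCollection()
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise MalformedInputError(
                f"GMT line needs >= 3 tab-separated fields, got {len(fields)}",
                lineno,
            )
        name, description = fields[0], fields[1]
        genes = {normalize_symbol(g, lineno) for g in fields[2:] if g.strip()}
        if not genes:
            raise MalformedInputError(f"gene set {name!r} has no genes", lineno)
        try:
            coll.add(name, description, genes)
        except DuplicateTermError:
            raise DuplicateTermError(
                f"duplicate gene-set name {name!r}", lineno
            ) from None
    return coll


def write_gmt(coll: GeneSetCollection, stream: TextIO) -> None:
    for name, (description, genes) in coll.sets.items():
        stream.write("\t".join([name, description, *sorted(genes)]) + "\n")


def _log_binom(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf  # zero ways
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_overrep(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Direct summation of the point masses in log-space; exact to within
    float rounding for any parameters, validated against a rational
    oracle at small N.
    """
    if N < 1:
        raise ValueError(f"universe size N must be >= 1, got {N}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    log_denom = _log_binom(N, n)
    log_terms = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - log_denom
        for i in range(k, min(K, n) + 1)
    ]
    log_terms = [t for t in log_terms if t > -math.inf]
    if not log_terms:
        return 0.0
    m = max(log_terms)
    tail = math.exp(m) * sum(math.exp(t - m) for t in log_terms)
    return min(tail, 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up, returned in the input order.

    adj_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, over the
    ascending order statistics.
    """
    m = len(pvalues)
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p!r} outside [0, 1]")
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        # at rank m the factor is exactly 1, so take p itself
        scaled = pvalues[idx] if rank == m else pvalues[idx] * m / rank
        running = min(running, scaled)
        adjusted[idx] = running
    return adjusted


def enrich(
    query: Iterable[str],
    library: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """One-sided ORA of a query list against every set in a library.

    Query and sets are intersected with the universe before counting;
    BH runs across the whole library (zero-overlap sets included) so
    the FDR family matches what is reported.  Results are sorted by
    (p_adj, p, term); significance is strict p_adj < alpha.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha!r}")
    uni = frozenset(universe)
    if not uni:
        raise DegenerateInputError("empty universe")
    q = frozenset(query) & uni
    if not q:
        raise DegenerateInputError("query is empty after universe intersection")
    N, n = len(uni), len(q)
    rows: list[tuple[str, int, int, frozenset[str]]] = []
    pvals: list[float] = []
    for name in library.names():
        members = library.genes(name) & uni
        overlap = q & members
        rows.append((name, len(overlap), len(members), overlap))
        pvals.append(fisher_overrep(len(overlap), len(members), n, N))
    padj = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            term=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p=p,
            p_adj=pa,
            overlap_genes=overlap,
            significant=pa < alpha,
        )
        for (name, k, K, overlap), p, pa in zip(rows, pvals, padj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p, r.term))
    return results


def write_enrichment_report(
    results: Sequence[EnrichmentResult], stream: TextIO
) -> None:
    """TSV report: term, overlap k/K, p, p_adj, significance, genes."""
    stream.write("term\toverlap\tp\tp_adj\tsignificant\toverlap_genes\n")
    for r in results:
        genes = ";".join(sorted(r.overlap_genes))
        stream.write(
            f"{r.term}\t{r.k}/{r.K}\t{r.p:.6e}\t{r.p_adj:.6e}\t"
            f"{int(r.significant)}\t{genes}\n"
        )


def plot_enrichment_bars(
    results: Sequence[EnrichmentResult], path: str, top_n: int = 10
) -> None:
    """Horizontal bars of -log10 adjusted p for the top terms
    (presentation only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = list(results[:top_n])[::-1]
    heights = [-math.log10(max(r.p_adj, 1e-300)) for r in top]
    fig, ax = plt.subplots(figsize=(8, 0.4 * max(len(top), 4) + 1.5))
    ax.barh([r.term for r in top], heights, color="#4878a8")
    ax.set_xlabel("-log10 adjusted p")
    ax.set_title("Top enriched terms")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
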